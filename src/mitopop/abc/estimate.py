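"""ABC parameter estimation, RMAE validation and goodness-of-fit.

Parameter estimation follows the local linear regression adjustment:
parameters are mapped onto the real line with a logit transform over
their prior bounds (log-scaled first for log-uniform priors, which also
guarantees adjusted values stay inside the prior), regressed on the
centred normalized statistics with Epanechnikov weights, and the
regression-adjusted draws are summarized by weighted quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitopop.abc.coalescent import simulate_var
from mitopop.abc.modelchoice import _epanechnikov
from mitopop.abc.reftable import ReferenceTable
from mitopop.abc.scenario import Prior, PriorSpec, Scenario, draw_parameters
from mitopop.abc.sumstats import SummaryStatsVector, summary_stats_from_var


class EstimationError(ValueError):
    pass


@dataclass
class ParameterPosterior:
    symbol: str
    samples: np.ndarray            # adjusted, back-transformed draws
    weights: np.ndarray            # normalized kernel weights
    median: float
    q025: float
    q975: float
    rmae: float | None = None


@dataclass
class PosteriorEstimate:
    scenario_id: str
    parameters: dict[str, ParameterPosterior]
    n_retained: int
    warnings: list[str] = field(default_factory=list)

    def medians(self) -> dict[str, float]:
        return {s: p.median for s, p in self.parameters.items()}


def weighted_quantile(
    values: np.ndarray, weights: np.ndarray, q: float | np.ndarray
) -> np.ndarray:
    """Quantiles of a weighted sample (inverse weighted CDF, midpoint rule)."""
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, v)


def _to_logit(theta: np.ndarray, prior: Prior) -> np.ndarray:
    lo, hi = prior.low, prior.high
    if lo == hi:
        return np.zeros_like(np.asarray(theta, dtype=float))
    if prior.family == "loguniform":
        x = (np.log(theta) - np.log(lo)) / (np.log(hi) - np.log(lo))
    else:
        x = (theta - lo) / (hi - lo)
    x = np.clip(x, 1e-12, 1 - 1e-12)
    return np.log(x / (1 - x))


def _from_logit(phi: np.ndarray, prior: Prior) -> np.ndarray:
    lo, hi = prior.low, prior.high
    if lo == hi:
        return np.full_like(np.asarray(phi, dtype=float), lo)
    x = 1.0 / (1.0 + np.exp(-phi))
    if prior.family == "loguniform":
        return np.exp(np.log(lo) + x * (np.log(hi) - np.log(lo)))
    return lo + x * (hi - lo)


def estimate_parameters(
    rt: ReferenceTable,
    winner: str,
    observed: SummaryStatsVector | np.ndarray,
    priors: PriorSpec,
    tolerance: float = 0.01,
    min_rows: int = 50,
) -> PosteriorEstimate:
    """Weighted local-linear posterior for the winner scenario's parameters."""
    obs = observed.values if isinstance(observed, SummaryStatsVector) else np.asarray(observed, float)
    rows = rt.rows_for(winner)
    if len(rows) < min_rows:
        raise EstimationError(
            f"only {len(rows)} reference rows for scenario {winner!r}; need {min_rows}"
        )
    dist = rt.distances_to(obs)[rows]
    n_keep = max(int(np.ceil(tolerance * len(rows))), min(min_rows, len(rows)))
    order = rows[np.argsort(dist, kind="stable")[:n_keep]]
    w = _epanechnikov(np.sort(dist, kind="stable")[:n_keep])
    z = (rt.stats[order] - obs) / rt.norm
    keep_cols = z.std(axis=0) > 0
    zk = z[:, keep_cols]
    design = np.hstack([np.ones((n_keep, 1)), zk])
    sw = np.sqrt(w)

    warnings: list[str] = []
    symbols = [
        c for c in rt.params.columns if np.isfinite(rt.params[c].to_numpy()[order]).all()
    ]
    params: dict[str, ParameterPosterior] = {}
    wn = w / w.sum()
    for sym in symbols:
        prior = priors[sym]
        theta = rt.params[sym].to_numpy()[order]
        phi = _to_logit(theta, prior)
        try:
            beta, *_ = np.linalg.lstsq(design * sw[:, None], phi * sw, rcond=None)
        except np.linalg.LinAlgError:
            warnings.append(f"singular regression for {sym}; ridge fallback")
            a = design * sw[:, None]
            beta = np.linalg.solve(
                a.T @ a + 1e-8 * np.eye(a.shape[1]), a.T @ (phi * sw)
            )
        adjusted_phi = phi - zk @ beta[1:]
        adjusted = _from_logit(adjusted_phi, prior)
        med, lo, hi = weighted_quantile(adjusted, wn, np.array([0.5, 0.025, 0.975]))
        params[sym] = ParameterPosterior(
            sym, adjusted, wn.copy(), float(med), float(lo), float(hi)
        )
    return PosteriorEstimate(winner, params, n_keep, warnings)


def parameter_rmae(
    scenario: Scenario,
    priors: PriorSpec,
    n_pods: int,
    seed: int,
    rt: ReferenceTable | None = None,
    tolerance: float = 0.01,
    estimator=None,
    rmae_threshold: float = 0.2,
    samples: dict[str, int] | None = None,
    L: int | None = None,
) -> dict[str, dict]:
    """Relative median absolute error of the point estimates.

    For each pseudo-observed dataset with known truth, the (default ABC)
    estimator produces posterior medians; RMAE(param) is the median over
    pods of |estimate - truth| / truth.  Estimates with RMAE above
    ``rmae_threshold`` are flagged as not fully reliable.  A custom
    ``estimator(stats_vector, truth) -> {symbol: value}`` may be
    injected (used by the validation oracles; ``truth`` lets a perfect
    estimator be expressed).
    """
    if n_pods <= 0:
        raise EstimationError("n_pods must be positive")
    if estimator is None:
        if rt is None:
            raise EstimationError("either a reference table or an estimator is needed")

        def estimator(ss, _truth):  # noqa: F811 - default ABC estimator
            est = estimate_parameters(
                rt, scenario.scenario_id, ss, priors, tolerance
            )
            return est.medians()

    rng = np.random.default_rng(seed)
    if samples is None:
        samples = rt.samples if rt is not None else None
    if L is None:
        L = rt.L if rt is not None else None
    if samples is None or L is None:
        raise EstimationError(
            "sample sizes and locus length are required (via rt or directly)"
        )
    pops = rt.pops if rt is not None else list(samples)
    errors: dict[str, list[float]] = {}
    skipped: set[str] = set()
    for _ in range(n_pods):
        truth = draw_parameters(scenario, priors, rng)
        var, _, pol = simulate_var(scenario, truth, samples, L, rng)
        ss = summary_stats_from_var(var, pol, pops)
        est = estimator(ss, truth)
        for sym, value in est.items():
            if sym not in truth:
                continue
            if truth[sym] == 0:
                skipped.add(sym)
                continue
            errors.setdefault(sym, []).append(
                abs(value - truth[sym]) / abs(truth[sym])
            )
    out: dict[str, dict] = {}
    for sym, errs in errors.items():
        rmae = float(np.median(errs))
        out[sym] = {"rmae": rmae, "reliable": rmae <= rmae_threshold}
    for sym in skipped:
        out.setdefault(sym, {"rmae": None, "reliable": None})
    return out


def goodness_of_fit(
    scenario: Scenario,
    posterior: PosteriorEstimate,
    observed: SummaryStatsVector | np.ndarray,
    n_ppc: int,
    seed: int,
    rt: ReferenceTable,
    priors: PriorSpec | None = None,
) -> dict[str, float]:
    """Posterior-predictive two-sided tail probability per statistic.

    Parameters are resampled (with weights) from the adjusted posterior
    draws; ``n_ppc`` datasets are simulated and each observed statistic
    is located in its predictive distribution.
    """
    if n_ppc <= 0:
        raise EstimationError("n_ppc must be positive")
    if not posterior.parameters:
        raise EstimationError("posterior sample is empty")
    obs = observed.values if isinstance(observed, SummaryStatsVector) else np.asarray(observed, float)
    rng = np.random.default_rng(seed)
    symbols = list(posterior.parameters)
    any_param = posterior.parameters[symbols[0]]
    n_draws = len(any_param.samples)
    weights = any_param.weights
    sims = np.zeros((n_ppc, len(rt.stat_names)))
    from mitopop.abc.coalescent import SimulationError

    for r in range(n_ppc):
        # per-parameter adjustment can break joint ordering constraints;
        # resample until a feasible vector comes up
        for _ in range(1000):
            idx = int(rng.choice(n_draws, p=weights))
            params = {
                sym: float(posterior.parameters[sym].samples[idx]) for sym in symbols
            }
            params.setdefault("mu", priors["mu"].median() if priors else 5e-8)
            if all(params.get(a, 1) > params.get(b, 0) for a, b in scenario.constraints):
                break
        else:
            raise EstimationError(
                "could not draw a constraint-satisfying posterior vector"
            )
        try:
            var, _, pol = simulate_var(scenario, params, rt.samples, rt.L, rng)
        except SimulationError as exc:
            raise EstimationError(f"posterior-predictive simulation failed: {exc}")
        sims[r] = summary_stats_from_var(var, pol, rt.pops).values
    out: dict[str, float] = {}
    for j, name in enumerate(rt.stat_names):
        lo = float((sims[:, j] <= obs[j]).mean())
        hi = float((sims[:, j] >= obs[j]).mean())
        out[name] = min(1.0, 2.0 * min(lo, hi))
    return out
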
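"""ABC model choice: rejection + weighted polychotomous logistic regression.

The closest ``tolerance`` fraction of the reference table (Euclidean
distance on MAD-normalized statistics) is retained; a multinomial
logistic regression of the scenario indicator on the centred statistics
(SS - observed), weighted by an Epanechnikov kernel of the distances,
is fitted and evaluated at SS = observed (the intercept point).  95%
confidence intervals come from the asymptotic covariance of the fitted
linear predictors via the delta method.  On separation or optimizer
failure the estimator falls back to retained-set class frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from mitopop.abc.coalescent import simulate_var
from mitopop.abc.reftable import ReferenceTable
from mitopop.abc.scenario import PriorSpec, Scenario, draw_parameters
from mitopop.abc.sumstats import SummaryStatsVector, summary_stats_from_var


class ModelChoiceError(ValueError):
    pass


@dataclass
class ModelChoiceResult:
    scenarios: list[str]
    posterior: dict[str, float]
    ci: dict[str, tuple[float, float]]
    winner: str
    n_retained: int
    method_used: str                       # "logistic" or "frequency"
    warnings: list[str] = field(default_factory=list)
    predictive_error: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "scenarios": [
                {
                    "scenario": s,
                    "posterior_probability": self.posterior[s],
                    "ci95": list(self.ci[s]),
                    "winner": s == self.winner,
                }
                for s in self.scenarios
            ],
            "winner": self.winner,
            "n_retained": self.n_retained,
            "method": self.method_used,
            "warnings": self.warnings,
            "predictive_error": self.predictive_error,
        }


def _epanechnikov(dist: np.ndarray) -> np.ndarray:
    """Kernel weights with bandwidth = max retained distance."""
    h = dist.max()
    if h == 0:
        return np.ones_like(dist)
    w = 1.0 - (dist / h) ** 2
    # the farthest point would get weight 0; keep it marginally positive
    return np.clip(w, 1e-8, None)


def _fit_multinomial(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, n_class: int, ridge: float = 1e-6
):
    """Weighted softmax regression; last class is the baseline.

    Returns (coef matrix (n_class-1, d+1), covariance of the flattened
    coefficients) or raises FloatingPointError on failure/separation.
    """
    m, d = x.shape
    xd = np.hstack([np.ones((m, 1)), x])
    kk = n_class - 1
    p_dim = kk * (d + 1)

    def unpack(theta):
        return theta.reshape(kk, d + 1)

    def nll_grad(theta):
        b = unpack(theta)
        eta = xd @ b.T                       # (m, kk)
        eta_full = np.hstack([eta, np.zeros((m, 1))])
        eta_full -= eta_full.max(axis=1, keepdims=True)
        ex = np.exp(eta_full)
        p = ex / ex.sum(axis=1, keepdims=True)
        ll = np.log(np.clip(p[np.arange(m), y], 1e-300, None))
        nll = -(w * ll).sum() + 0.5 * ridge * (theta**2).sum()
        ind = np.zeros((m, kk))
        for k in range(kk):
            ind[:, k] = (y == k).astype(float)
        grad = ((w[:, None] * (p[:, :kk] - ind)).T @ xd).reshape(-1) + ridge * theta
        return nll, grad

    theta0 = np.zeros(p_dim)
    res = minimize(nll_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        raise FloatingPointError(f"multinomial fit failed: {res.message}")
    theta = res.x

    # observed information at the optimum
    b = unpack(theta)
    eta = xd @ b.T
    eta_full = np.hstack([eta, np.zeros((m, 1))])
    eta_full -= eta_full.max(axis=1, keepdims=True)
    ex = np.exp(eta_full)
    p = ex / ex.sum(axis=1, keepdims=True)
    # complete separation: every retained point classified with certainty
    if p[np.arange(m), y].min() > 1 - 1e-8:
        raise FloatingPointError("separation in logistic regression")
    h = np.zeros((p_dim, p_dim))
    for k in range(kk):
        for l in range(kk):
            coef = w * p[:, k] * ((k == l) - p[:, l])
            block = (xd * coef[:, None]).T @ xd
            h[k * (d + 1):(k + 1) * (d + 1), l * (d + 1):(l + 1) * (d + 1)] = block
    h += ridge * np.eye(p_dim)
    cov = np.linalg.pinv(h)
    return b, cov


def model_choice(
    rt: ReferenceTable,
    observed: SummaryStatsVector | np.ndarray,
    tolerance: float = 0.01,
    method: str = "logistic",
) -> ModelChoiceResult:
    """Posterior scenario probabilities at the observed statistics."""
    if not 0 < tolerance <= 1:
        raise ModelChoiceError("tolerance must be in (0, 1]")
    obs = observed.values if isinstance(observed, SummaryStatsVector) else np.asarray(observed, float)
    n_class = len(rt.scenarios)
    dist = rt.distances_to(obs)
    n_keep = max(int(np.ceil(tolerance * rt.n_rows)), 1)
    if n_keep < 10 * n_class and method == "logistic":
        raise ModelChoiceError(
            f"retained count {n_keep} < 10 x {n_class} scenarios; "
            "increase tolerance or the reference table size"
        )
    order = np.argsort(dist, kind="stable")[:n_keep]
    w = _epanechnikov(dist[order])
    y = rt.scenario_of_row[order]
    z = (rt.stats[order] - obs) / rt.norm

    warnings: list[str] = []
    missing = [s for k, s in enumerate(rt.scenarios) if not (y == k).any()]
    if missing:
        warnings.append(
            f"scenarios absent from retained set (probability 0, degenerate CI): "
            f"{missing}"
        )

    probs = None
    cov_int = None
    used = method
    if method == "logistic" and not missing:
        # drop constant columns to keep the design full-rank
        keep_cols = z.std(axis=0) > 0
        try:
            b, cov = _fit_multinomial(z[:, keep_cols], y, w, n_class)
            d1 = int(keep_cols.sum()) + 1
            intercepts = b[:, 0]
            eta = np.append(intercepts, 0.0)
            eta -= eta.max()
            ex = np.exp(eta)
            probs = ex / ex.sum()
            idx = [k * d1 for k in range(n_class - 1)]
            cov_int = cov[np.ix_(idx, idx)]
            used = "logistic"
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            warnings.append(f"logistic fit failed ({exc}); frequency fallback")
            probs = None
    elif method == "logistic" and missing:
        warnings.append("frequency fallback because of empty scenarios")

    if probs is None or method == "frequency":
        used = "frequency"
        counts = np.array([(y == k).sum() for k in range(n_class)], dtype=float)
        probs = counts / counts.sum()
        # binomial-style normal approximation on the retained draw
        se = np.sqrt(np.clip(probs * (1 - probs) / n_keep, 0, None))
        ci = {
            s: (max(probs[k] - 1.96 * se[k], 0.0), min(probs[k] + 1.96 * se[k], 1.0))
            for k, s in enumerate(rt.scenarios)
        }
    else:
        # delta method: dp_j/da_k = p_j (delta_jk - p_k), baseline fixed
        ci = {}
        for jcl, s in enumerate(rt.scenarios):
            g = np.array(
                [probs[jcl] * ((jcl == k) - probs[k]) for k in range(n_class - 1)]
            )
            var = float(g @ cov_int @ g)
            sd = np.sqrt(max(var, 0.0))
            ci[s] = (
                max(probs[jcl] - 1.96 * sd, 0.0),
                min(probs[jcl] + 1.96 * sd, 1.0),
            )

    posterior = {s: float(probs[k]) for k, s in enumerate(rt.scenarios)}
    winner = max(posterior, key=posterior.get)
    return ModelChoiceResult(
        list(rt.scenarios), posterior, ci, winner, n_keep, used, warnings
    )


def scenario_choice_error(
    scenarios: list[Scenario],
    priors: PriorSpec,
    rt: ReferenceTable,
    n_test: int = 1000,
    seed: int = 0,
    tolerance: float = 0.01,
) -> float:
    """Prior-based predictive (misclassification) error of model choice.

    Simulates ``n_test`` pseudo-observed datasets with the generating
    scenario drawn uniformly and parameters from the priors, then counts
    how often model choice picks a different scenario.
    """
    if n_test <= 0:
        raise ModelChoiceError("n_test must be positive")
    ids = {s.scenario_id: s for s in scenarios}
    if set(ids) != set(rt.scenarios):
        raise ModelChoiceError("scenario list does not match the reference table")
    rng = np.random.default_rng(seed)
    wrong = 0
    for _ in range(n_test):
        true_id = rt.scenarios[int(rng.integers(len(rt.scenarios)))]
        scen = ids[true_id]
        params = draw_parameters(scen, priors, rng)
        var, _, pol = simulate_var(scen, params, rt.samples, rt.L, rng)
        ss = summary_stats_from_var(var, pol, rt.pops)
        try:
            res = model_choice(rt, ss, tolerance=tolerance)
        except ModelChoiceError:
            res = model_choice(rt, ss, tolerance=tolerance, method="frequency")
        if res.winner != true_id:
            wrong += 1
    return wrong / n_test
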
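"""Reference tables of simulated (scenario, parameters, summary stats).

Statistics are normalized by their per-statistic MAD (median absolute
deviation) over the whole table — a robust DIYABC-style scaling — and
compared to the observed vector by Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mitopop.abc.coalescent import simulate_var
from mitopop.abc.scenario import PriorSpec, Scenario, draw_parameters
from mitopop.abc.sumstats import SummaryStatsVector, stat_names, summary_stats_from_var


class ReferenceTableError(ValueError):
    pass


@dataclass
class ReferenceTable:
    scenarios: list[str]               # unique scenario ids, fixed order
    scenario_of_row: np.ndarray        # (n_rows,) index into ``scenarios``
    params: pd.DataFrame               # one column per symbol, NaN if unused
    stats: np.ndarray                  # (n_rows, n_stats)
    stat_names: list[str]
    norm: np.ndarray                   # per-statistic MAD (zeros replaced by 1)
    samples: dict[str, int]
    L: int
    pops: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def rows_for(self, scenario_id: str) -> np.ndarray:
        try:
            k = self.scenarios.index(scenario_id)
        except ValueError:
            raise ReferenceTableError(f"unknown scenario {scenario_id!r}") from None
        return np.flatnonzero(self.scenario_of_row == k)

    def normalized(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) / self.norm

    def distances_to(self, observed: SummaryStatsVector | np.ndarray) -> np.ndarray:
        obs = observed.values if isinstance(observed, SummaryStatsVector) else observed
        if len(obs) != len(self.stat_names):
            raise ReferenceTableError(
                f"observed vector has {len(obs)} stats, table has {len(self.stat_names)}"
            )
        z = (self.stats - np.asarray(obs, dtype=float)) / self.norm
        return np.sqrt((z**2).sum(axis=1))

    def to_tsv(self, path: str | Path) -> None:
        df = self.params.copy()
        df.insert(0, "scenario", [self.scenarios[k] for k in self.scenario_of_row])
        for i, name in enumerate(self.stat_names):
            df[name] = self.stats[:, i]
        header = (
            f"# samples={','.join(f'{p}:{n}' for p, n in self.samples.items())} "
            f"L={self.L} pops={','.join(self.pops)}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ReferenceTableError("missing reference-table header line")
            meta = dict(tok.split("=", 1) for tok in header[1:].split())
            df = pd.read_csv(fh, sep="\t")
        samples = {
            p: int(n)
            for p, n in (item.split(":") for item in meta["samples"].split(","))
        }
        pops = meta["pops"].split(",")
        snames = stat_names(pops)
        scen_col = df.pop("scenario").tolist()
        scenarios = list(dict.fromkeys(scen_col))
        scenario_of_row = np.array([scenarios.index(s) for s in scen_col])
        stats = df[snames].to_numpy(dtype=float)
        params = df.drop(columns=snames)
        return cls(
            scenarios,
            scenario_of_row,
            params,
            stats,
            snames,
            _mad(stats),
            samples,
            int(meta["L"]),
            pops,
        )


def _mad(stats: np.ndarray) -> np.ndarray:
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    mad[mad == 0] = 1.0
    return mad


def build_reference_table(
    scenarios: list[Scenario],
    priors: PriorSpec,
    n_per_scenario: int,
    samples: dict[str, int],
    L: int,
    seed: int,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and summarize.

    Fully reproducible from ``seed``; scenarios are simulated in order.
    """
    if len(scenarios) < 2:
        raise ReferenceTableError("need >= 2 scenarios for model choice")
    if n_per_scenario <= 0:
        raise ReferenceTableError("n_per_scenario must be positive")
    pops = list(scenarios[0].pops)
    for s in scenarios[1:]:
        if list(s.pops) != pops:
            raise ReferenceTableError(
                "all scenarios must share the same sampled populations"
            )
    rng = np.random.default_rng(seed)
    snames = stat_names(pops)
    n_total = n_per_scenario * len(scenarios)
    stats = np.zeros((n_total, len(snames)))
    scenario_of_row = np.zeros(n_total, dtype=np.int64)
    param_rows: list[dict[str, float]] = []
    row = 0
    for k, scen in enumerate(scenarios):
        for i in range(n_per_scenario):
            params = draw_parameters(scen, priors, rng)
            var, _, pop_of_leaf = simulate_var(scen, params, samples, L, rng)
            ss = summary_stats_from_var(var, pop_of_leaf, pops)
            stats[row] = ss.values
            scenario_of_row[row] = k
            param_rows.append(params)
            row += 1
            if progress and (i + 1) % 1000 == 0:
                print(f"[reftable] {scen.scenario_id}: {i + 1}/{n_per_scenario}")
    params_df = pd.DataFrame(param_rows)
    return ReferenceTable(
        [s.scenario_id for s in scenarios],
        scenario_of_row,
        params_df,
        stats,
        snames,
        _mad(stats),
        dict(samples),
        L,
        pops,
    )


@dataclass
class PcaCheck:
    outside_cloud: bool
    mahalanobis: float
    threshold: float          # 99th percentile of simulated radii
    explained_variance: np.ndarray
    dropped_stats: list[str] = field(default_factory=list)


def preevaluate_pca(
    rt: ReferenceTable, observed: SummaryStatsVector | np.ndarray
) -> PcaCheck:
    """PCA similarity pre-check of the observed point against the cloud.

    The observed vector is projected onto the first two principal
    components of the normalized simulated statistics and flagged when
    its Mahalanobis radius exceeds the cloud's 99th percentile.
    """
    from sklearn.decomposition import PCA

    obs = observed.values if isinstance(observed, SummaryStatsVector) else observed
    z = rt.stats / rt.norm
    keep = z.std(axis=0) > 0
    dropped = [n for n, k in zip(rt.stat_names, keep) if not k]
    z = z[:, keep]
    if z.shape[1] < 2:
        raise ReferenceTableError("need >= 2 statistics with nonzero variance")
    zobs = (np.asarray(obs, dtype=float) / rt.norm)[keep]
    n_comp = min(2, z.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(z)
    obs_score = pca.transform(zobs[None, :])[0]
    cov = np.cov(scores, rowvar=False)
    cov = np.atleast_2d(cov)
    inv = np.linalg.pinv(cov)
    centred = scores - scores.mean(axis=0)
    radii = np.sqrt(np.einsum("ij,jk,ik->i", centred, inv, centred))
    oc = obs_score - scores.mean(axis=0)
    md = float(np.sqrt(oc @ inv @ oc))
    thr = float(np.percentile(radii, 99))
    return PcaCheck(md > thr, md, thr, pca.explained_variance_ratio_, dropped)
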
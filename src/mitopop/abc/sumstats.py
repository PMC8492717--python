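"""DIYABC-style summary statistics.

Per population: mean pairwise differences; mean and variance (over
segregating sites) of the rarest-nucleotide count, i.e. the number of
gene copies carrying the least frequent base at a segregating site
(ties resolved to the minimum count).  Per population pair: mean
pairwise differences across populations (the uncorrected "(B)" variant)
and Phi_ST.  Statistics undefined because a population has no
segregating sites are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitopop.alignment import Alignment, MissingPolicy, PopLevel
from mitopop.popgen import PopgenError, amova_from_distances


@dataclass
class SummaryStatsVector:
    names: list[str]
    values: np.ndarray
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def stat_names(pops: list[str]) -> list[str]:
    names = []
    for p in pops:
        names += [f"pi_{p}", f"mean_rare_{p}", f"var_rare_{p}"]
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            names += [f"piB_{pops[i]}_{pops[j]}", f"fst_{pops[i]}_{pops[j]}"]
    return names


def _pairwise_diff_matrix_var(var: np.ndarray) -> np.ndarray:
    """Hamming distances between rows of an integer site matrix."""
    if var.shape[1] == 0:
        return np.zeros((var.shape[0], var.shape[0]), dtype=np.int64)
    return (var[:, None, :] != var[None, :, :]).sum(axis=2)


def _site_counts(sub: np.ndarray, n_states: int = 4) -> np.ndarray:
    """(n_states, S) per-site base counts of an integer matrix."""
    S = sub.shape[1]
    out = np.zeros((n_states, S), dtype=np.int64)
    for b in range(n_states):
        out[b] = (sub == b).sum(axis=0)
    return out


def summary_stats_from_var(
    var: np.ndarray,
    pop_of_leaf: np.ndarray,
    pops: list[str],
) -> SummaryStatsVector:
    """Summary statistics from a (n, S) integer matrix of variable sites.

    ``pop_of_leaf`` holds population indices into ``pops``.
    """
    names = stat_names(pops)
    values = np.zeros(len(names))
    flags: list[str] = []
    pop_rows = {i: np.flatnonzero(pop_of_leaf == i) for i in range(len(pops))}
    for i, rows in pop_rows.items():
        if len(rows) < 2:
            raise PopgenError(
                f"population {pops[i]!r} needs >= 2 samples for one-sample stats"
            )

    d = _pairwise_diff_matrix_var(var)
    pos = 0
    for i, p in enumerate(pops):
        rows = pop_rows[i]
        npop = len(rows)
        sub = d[np.ix_(rows, rows)]
        pi = sub[np.triu_indices(npop, k=1)].mean()
        counts = _site_counts(var[rows])
        present = counts > 0
        seg = present.sum(axis=0) >= 2
        if seg.any():
            seg_counts = np.where(present[:, seg], counts[:, seg], np.iinfo(np.int64).max)
            rare = seg_counts.min(axis=0).astype(float)
            mean_rare = float(rare.mean())
            var_rare = float(rare.var())  # population variance (ddof=0)
        else:
            mean_rare = var_rare = 0.0
            flags.append(f"mean_rare_{p}")
            flags.append(f"var_rare_{p}")
        values[pos : pos + 3] = (pi, mean_rare, var_rare)
        pos += 3

    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ri, rj = pop_rows[i], pop_rows[j]
            pib = float(d[np.ix_(ri, rj)].mean())
            rows = np.concatenate([ri, rj])
            labels = np.concatenate(
                [np.repeat(pops[i], len(ri)), np.repeat(pops[j], len(rj))]
            )
            d2 = d[np.ix_(rows, rows)].astype(float) ** 2
            if d2.sum() == 0:
                fst = 0.0
                flags.append(f"fst_{pops[i]}_{pops[j]}")
            else:
                fst = amova_from_distances(d2, labels).phi_st
            values[pos : pos + 2] = (pib, fst)
            pos += 2
    return SummaryStatsVector(names, values, flags)


_BASE_TO_INT = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}


def summary_stats(
    a: Alignment,
    pop_level: PopLevel = "metapopulation",
    pops: list[str] | None = None,
    missing_policy: MissingPolicy = "exclude_site",
) -> SummaryStatsVector:
    """Summary statistics of an alignment at the given population level."""
    if pops is None:
        pops = a.populations(pop_level)
    labels = np.asarray(a.pop_labels(pop_level))
    missing = [p for p in pops if p not in set(labels)]
    if missing:
        raise PopgenError(f"populations absent from alignment: {missing}")
    pop_of_leaf = np.full(a.n, -1, dtype=np.int64)
    for i, p in enumerate(pops):
        pop_of_leaf[labels == p] = i
    keep = pop_of_leaf >= 0
    sites = a.retained_sites(missing_policy)
    sub = a.seqs[np.ix_(np.flatnonzero(keep), sites)]
    var = np.zeros(sub.shape, dtype=np.int8)
    for base, code in _BASE_TO_INT.items():
        var[sub == base] = code
    # non-ACGT under pairwise policy would need masking; restrict to valid
    if missing_policy == "pairwise":
        valid_cols = np.flatnonzero(
            np.isin(sub, list(_BASE_TO_INT)).all(axis=0)
        )
        var = var[:, valid_cols]
    variable = np.flatnonzero((var != var[0]).any(axis=0))
    return summary_stats_from_var(var[:, variable], pop_of_leaf[keep], pops)
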
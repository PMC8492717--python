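"""Diversity statistics, mismatch distributions, AMOVA and pairwise Phi_ST.

AMOVA follows the classical nested sums-of-squared-deviations
decomposition of a pairwise distance matrix (Excoffier-style), with the
squared inter-individual distance entering the sums.  The default
distance is the number of differing retained sites (pairwise sequence
difference); a haplotype-identity (0/1) mode is provided for
sensitivity checks.

Negative variance components are reported raw; percentages and Phi
statistics are computed with negative components floored at zero, which
is how published AMOVA tables are normally read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from mitopop.alignment import Alignment, AlignmentError, MissingPolicy, PopLevel

Distance = Literal["pairwise_difference", "haplotype_identity"]


class PopgenError(ValueError):
    pass


@dataclass
class DiversityResult:
    """Nei's haplotype (gene) diversity with its standard error."""

    n: int
    k: int
    h: float
    se_h: float

    def __str__(self) -> str:  # Table-1 style presentation
        return f"{self.h:.4f} ± {self.se_h:.4f}"


@dataclass
class AmovaComponent:
    name: str
    df: int
    ss: float
    variance: float
    percentage: float


@dataclass
class AmovaResult:
    components: list[AmovaComponent]
    phi_st: float
    phi_ct: float | None = None
    phi_sc: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def total_df(self) -> int:
        return sum(c.df for c in self.components)

    def to_rows(self) -> list[dict]:
        return [
            {
                "source": c.name,
                "df": c.df,
                "sum_of_squares": c.ss,
                "variance": c.variance,
                "percentage": c.percentage,
            }
            for c in self.components
        ]


@dataclass
class FstMatrix:
    populations: list[str]
    values: np.ndarray
    p_values: np.ndarray | None = None
    flagged: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("population\t" + "\t".join(self.populations) + "\n")
            for name, row in zip(self.populations, self.values):
                fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def haplotype_diversity(counts: Sequence[int] | np.ndarray, n: int | None = None) -> DiversityResult:
    """Nei's unbiased gene diversity and its sampling standard error.

    h = n/(n-1) * (1 - sum p_i^2)
    V(h) = 2/[n(n-1)] * {2(n-2)[sum p_i^3 - (sum p_i^2)^2] + sum p_i^2 - (sum p_i^2)^2}
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    total = int(round(c.sum()))
    if n is None:
        n = total
    elif n != total:
        raise PopgenError(f"n={n} does not match sum of counts={total}")
    if n < 2:
        raise PopgenError("haplotype diversity requires n >= 2")
    p = c / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - s2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return DiversityResult(n=n, k=int(len(c)), h=h, se_h=float(np.sqrt(max(var, 0.0))))


def diff_matrix(a: Alignment, missing_policy: MissingPolicy = "exclude_site") -> np.ndarray:
    """(n, n) matrix of pairwise sequence differences over retained sites.

    Under ``pairwise`` missing policy a site contributes to a pair only
    when both bases are unambiguous.
    """
    if missing_policy == "exclude_site":
        sub = a.seqs[:, a.retained_sites("exclude_site")]
        n = sub.shape[0]
        d = np.zeros((n, n), dtype=np.int64)
        # chunk rows to bound the n*n*L boolean intermediate
        view = sub.view(np.uint8)
        step = max(1, int(2e8 // max(1, n * sub.shape[1])))
        for i0 in range(0, n, step):
            block = view[i0 : i0 + step]
            d[i0 : i0 + step] = (block[:, None, :] != view[None, :, :]).sum(axis=2)
        return d
    valid = a.valid_mask()
    view = a.seqs.view(np.uint8)
    n = a.n
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid
        d[i] = ((view[i] != view) & both).sum(axis=1)
    return d


def _pop_indices(a: Alignment, pop_level: PopLevel) -> dict[str, np.ndarray]:
    labels = np.asarray(a.pop_labels(pop_level))
    return {p: np.flatnonzero(labels == p) for p in a.populations(pop_level)}


def mean_pairwise_differences(
    a: Alignment,
    within: str | tuple[str, str],
    pop_level: PopLevel = "breed",
    missing_policy: MissingPolicy = "exclude_site",
) -> float:
    """Mean pairwise differences within one population, or across two.

    For a population pair the statistic averages over all cross-population
    pairs (the uncorrected "(B)" variant, not net of within-population
    diversity).
    """
    d = diff_matrix(a, missing_policy)
    idx = _pop_indices(a, pop_level)
    if isinstance(within, tuple):
        p1, p2 = within
        for p in (p1, p2):
            if p not in idx:
                raise PopgenError(f"population {p!r} absent")
        i, j = idx[p1], idx[p2]
        if len(i) < 1 or len(j) < 1:
            raise PopgenError("each population needs >= 1 sequence")
        return float(d[np.ix_(i, j)].mean())
    if within not in idx:
        raise PopgenError(f"population {within!r} absent")
    i = idx[within]
    if len(i) < 2:
        raise PopgenError(f"population {within!r} has fewer than 2 sequences")
    sub = d[np.ix_(i, i)]
    m = len(i)
    return float(sub[np.triu_indices(m, k=1)].mean())


def mismatch_distribution(
    a: Alignment,
    population: str | None = None,
    pop_level: PopLevel = "breed",
    missing_policy: MissingPolicy = "exclude_site",
) -> dict[int, int]:
    """Histogram of pairwise difference counts within a population."""
    if population is not None:
        a = a.restrict_to_population(population, pop_level)
    if a.n < 2:
        raise PopgenError("mismatch distribution requires n >= 2")
    d = diff_matrix(a, missing_policy)
    vals = d[np.triu_indices(a.n, k=1)]
    return dict(sorted(Counter(int(v) for v in vals).items()))


# --- AMOVA ----------------------------------------------------------------

def _ssd_total(d2: np.ndarray, rows: np.ndarray) -> float:
    """SSD of a set of individuals: sum_{i<j} d2_ij / n."""
    sub = d2[np.ix_(rows, rows)]
    return float(sub.sum() / (2.0 * len(rows)))


def _clamp(x: float) -> float:
    return x if x > 0.0 else 0.0


def amova_from_distances(
    d2: np.ndarray,
    pops: Sequence[str],
    groups: Mapping[str, str] | None = None,
) -> AmovaResult:
    """Nested AMOVA decomposition from a squared-distance matrix.

    ``pops`` gives the population of each row; ``groups`` optionally maps
    population -> group for the two-level design.
    """
    pops = np.asarray(pops)
    names = list(dict.fromkeys(pops.tolist()))
    if len(names) < 2:
        raise PopgenError("AMOVA requires >= 2 populations")
    N = len(pops)
    pop_rows = {p: np.flatnonzero(pops == p) for p in names}
    n_p = {p: len(r) for p, r in pop_rows.items()}

    ssd_t = _ssd_total(d2, np.arange(N))
    ssd_wp = sum(_ssd_total(d2, r) for r in pop_rows.values())

    if groups is None:
        P = len(names)
        ssd_ap = ssd_t - ssd_wp
        df_ap, df_wp = P - 1, N - P
        if df_wp <= 0:
            raise PopgenError("AMOVA needs at least one population with n >= 2")
        sigma_c = ssd_wp / df_wp
        n_coef = (N - sum(v**2 for v in n_p.values()) / N) / (P - 1)
        sigma_a = (ssd_ap / df_ap - sigma_c) / n_coef
        tot = _clamp(sigma_a) + _clamp(sigma_c)
        phi_st = _clamp(sigma_a) / tot if tot > 0 else 0.0
        comps = [
            AmovaComponent("among_populations", df_ap, ssd_ap, sigma_a,
                           100.0 * _clamp(sigma_a) / tot if tot > 0 else 0.0),
            AmovaComponent("within_populations", df_wp, ssd_wp, sigma_c,
                           100.0 * _clamp(sigma_c) / tot if tot > 0 else 0.0),
        ]
        return AmovaResult(comps, phi_st=phi_st)

    group_of = dict(groups)
    missing = [p for p in names if p not in group_of]
    if missing:
        raise PopgenError(f"populations without group assignment: {missing}")
    gnames = list(dict.fromkeys(group_of[p] for p in names))
    G, P = len(gnames), len(names)
    if G < 2:
        raise PopgenError("two-level AMOVA requires >= 2 groups")
    grp_rows = {
        g: np.concatenate([pop_rows[p] for p in names if group_of[p] == g])
        for g in gnames
    }
    N_g = {g: len(r) for g, r in grp_rows.items()}
    ssd_groups = sum(_ssd_total(d2, r) for r in grp_rows.values())
    ssd_ag = ssd_t - ssd_groups
    ssd_apwg = ssd_groups - ssd_wp
    df_ag, df_apwg, df_wp = G - 1, P - G, N - P

    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in names if group_of[p] == g) / N_g[g] for g in gnames
    )
    sum_np2_over_n = sum(v**2 for v in n_p.values()) / N
    sum_ng2_over_n = sum(v**2 for v in N_g.values()) / N
    n1 = (N - sum_np2_over_ng) / df_apwg
    n2 = (sum_np2_over_ng - sum_np2_over_n) / df_ag
    n3 = (N - sum_ng2_over_n) / df_ag

    sigma_c = ssd_wp / df_wp
    sigma_b = (ssd_apwg / df_apwg - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    a_, b_, c_ = _clamp(sigma_a), _clamp(sigma_b), _clamp(sigma_c)
    tot = a_ + b_ + c_
    comps = [
        AmovaComponent("among_groups", df_ag, ssd_ag, sigma_a,
                       100.0 * a_ / tot if tot > 0 else 0.0),
        AmovaComponent("among_populations_within_groups", df_apwg, ssd_apwg,
                       sigma_b, 100.0 * b_ / tot if tot > 0 else 0.0),
        AmovaComponent("within_populations", df_wp, ssd_wp, sigma_c,
                       100.0 * c_ / tot if tot > 0 else 0.0),
    ]
    phi_st = (a_ + b_) / tot if tot > 0 else 0.0
    phi_ct = a_ / tot if tot > 0 else 0.0
    phi_sc = b_ / (b_ + c_) if (b_ + c_) > 0 else 0.0
    return AmovaResult(comps, phi_st=phi_st, phi_ct=phi_ct, phi_sc=phi_sc)


def _distance_sq(a: Alignment, distance: Distance, missing_policy: MissingPolicy) -> np.ndarray:
    if distance == "pairwise_difference":
        d = diff_matrix(a, missing_policy).astype(float)
    elif distance == "haplotype_identity":
        d = (diff_matrix(a, missing_policy) > 0).astype(float)
    else:
        raise PopgenError(f"unknown distance {distance!r}")
    return d**2


def amova(
    a: Alignment,
    pop_level: PopLevel = "breed",
    groups: Mapping[str, str] | None = None,
    n_perm: int = 0,
    distance: Distance = "pairwise_difference",
    missing_policy: MissingPolicy = "exclude_site",
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA on an alignment, with optional permutation p-values.

    One level (populations) by default; pass ``groups`` (population ->
    group) for the two-level design.  Permutations shuffle samples among
    populations (Phi_ST) and, in the two-level design, whole populations
    among groups (Phi_CT) and samples among populations within groups
    (Phi_SC).
    """
    d2 = _distance_sq(a, distance, missing_policy)
    pops = a.pop_labels(pop_level)
    result = amova_from_distances(d2, pops, groups)
    if n_perm > 0:
        if seed is None:
            raise PopgenError("a seed is required for permutation tests")
        rng = np.random.default_rng(seed)
        pops_arr = np.asarray(pops)
        exceed_st = 0
        exceed_ct = 0
        exceed_sc = 0
        names = list(dict.fromkeys(pops))
        for _ in range(n_perm):
            perm = rng.permutation(len(pops_arr))
            r = amova_from_distances(d2, pops_arr[perm], groups)
            if r.phi_st >= result.phi_st - 1e-12:
                exceed_st += 1
            if groups is not None:
                # populations among groups
                gperm = dict(zip(names, (groups[p] for p in rng.permutation(names))))
                r_ct = amova_from_distances(d2, pops_arr, gperm)
                if r_ct.phi_ct is not None and result.phi_ct is not None \
                        and r_ct.phi_ct >= result.phi_ct - 1e-12:
                    exceed_ct += 1
                # samples among populations within groups
                within = pops_arr.copy()
                for g in set(groups[p] for p in names):
                    rows = np.flatnonzero(
                        np.isin(pops_arr, [p for p in names if groups[p] == g])
                    )
                    within[rows] = within[rows][rng.permutation(len(rows))]
                r_sc = amova_from_distances(d2, within, groups)
                if r_sc.phi_sc is not None and result.phi_sc is not None \
                        and r_sc.phi_sc >= result.phi_sc - 1e-12:
                    exceed_sc += 1
        result.p_values["phi_st"] = (exceed_st + 1) / (n_perm + 1)
        if groups is not None:
            result.p_values["phi_ct"] = (exceed_ct + 1) / (n_perm + 1)
            result.p_values["phi_sc"] = (exceed_sc + 1) / (n_perm + 1)
    return result


def phi_st_from_d2(d2: np.ndarray, pops: Sequence[str]) -> float:
    """Two-(or more-)population Phi_ST straight from squared distances."""
    return amova_from_distances(d2, pops).phi_st


def pairwise_fst(
    a: Alignment,
    pop_level: PopLevel = "breed",
    n_perm: int = 0,
    distance: Distance = "pairwise_difference",
    missing_policy: MissingPolicy = "exclude_site",
    seed: int | None = None,
) -> FstMatrix:
    """Matrix of two-population AMOVA Phi_ST values.

    Populations with fewer than 2 samples are still computed but listed
    in ``flagged``.
    """
    names = a.populations(pop_level)
    if len(names) < 2:
        raise PopgenError("pairwise F_ST requires >= 2 populations")
    d2 = _distance_sq(a, distance, missing_policy)
    pops_arr = np.asarray(a.pop_labels(pop_level))
    idx = {p: np.flatnonzero(pops_arr == p) for p in names}
    flagged = [p for p in names if len(idx[p]) < 2]
    k = len(names)
    vals = np.zeros((k, k))
    pvals = np.full((k, k), np.nan) if n_perm > 0 else None
    rng = np.random.default_rng(seed) if n_perm > 0 else None
    for i in range(k):
        for j in range(i + 1, k):
            rows = np.concatenate([idx[names[i]], idx[names[j]]])
            sub = d2[np.ix_(rows, rows)]
            labels = pops_arr[rows]
            try:
                phi = phi_st_from_d2(sub, labels)
            except PopgenError:
                phi = np.nan
            vals[i, j] = vals[j, i] = phi
            if rng is not None and np.isfinite(phi):
                exceed = 0
                for _ in range(n_perm):
                    perm_labels = labels[rng.permutation(len(labels))]
                    if phi_st_from_d2(sub, perm_labels) >= phi - 1e-12:
                        exceed += 1
                pvals[i, j] = pvals[j, i] = (exceed + 1) / (n_perm + 1)
    return FstMatrix(names, vals, pvals, flagged)


def diversity_table(
    a: Alignment,
    pop_level: PopLevel = "breed",
    missing_policy: MissingPolicy = "exclude_site",
) -> list[dict]:
    """Per-population sample size, haplotype count and diversity rows."""
    from mitopop.alignment import collapse_haplotypes

    rows = []
    for pop in a.populations(pop_level):
        sub = a.restrict_to_population(pop, pop_level)
        ht = collapse_haplotypes(sub, missing_policy, pop_level)
        div = haplotype_diversity(ht.total_counts())
        rows.append(
            {
                "population": pop,
                "n": div.n,
                "haplotypes": div.k,
                "h": div.h,
                "se_h": div.se_h,
            }
        )
    return rows
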
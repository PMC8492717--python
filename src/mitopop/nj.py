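"""Distance models, neighbour-joining trees, bootstrap and lineage assignment.

The "composite-likelihood" distance mode mimics MEGA's maximum composite
likelihood setting: a TN93-form distance whose rate composition (the
split of differences into the two transition types and transversions)
and base frequencies are estimated jointly from all sequence pairs, with
a per-pair TN93 fallback when the joint estimate is unusable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from mitopop.alignment import Alignment, MissingPolicy

Model = Literal["p", "k2p", "tn93", "mcl"]

#: distance assigned to saturated pairs (log of a non-positive argument)
SATURATION_CEILING = 5.0

_PURINES = (b"A", b"G")
_PYRIMIDINES = (b"C", b"T")


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray
    model: str
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.names)}\n")
            for name, row in zip(self.names, self.values):
                fh.write(name + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")


@dataclass
class Edge:
    u: str
    v: str
    length: float          # clamped at 0 for presentation
    raw_length: float      # raw NJ estimate (may be negative)
    support: float | None = None


@dataclass
class Tree:
    """Unrooted tree as an explicit edge list; leaves carry taxon names."""

    leaves: list[str]
    edges: list[Edge]

    def adjacency(self) -> dict[str, list[tuple[str, float, Edge]]]:
        adj: dict[str, list[tuple[str, float, Edge]]] = {}
        for e in self.edges:
            adj.setdefault(e.u, []).append((e.v, e.length, e))
            adj.setdefault(e.v, []).append((e.u, e.length, e))
        return adj

    def _side(self, e: Edge) -> frozenset[str]:
        """Leaf set reachable from e.u without crossing e."""
        adj = self.adjacency()
        seen = {e.u}
        stack = [e.u]
        blocked = {(e.u, e.v), (e.v, e.u)}
        while stack:
            node = stack.pop()
            for nxt, _, _ in adj[node]:
                if (node, nxt) in blocked or nxt in seen:
                    continue
                seen.add(nxt)
                stack.append(nxt)
        return frozenset(x for x in seen if x in set(self.leaves))

    def bipartitions(self) -> dict[frozenset[str], Edge]:
        """Internal-edge bipartitions, canonicalized to the side without
        the lexicographically smallest leaf."""
        ref = min(self.leaves)
        out: dict[frozenset[str], Edge] = {}
        leafset = set(self.leaves)
        for e in self.edges:
            if e.u in leafset or e.v in leafset:
                continue
            side = self._side(e)
            if ref in side:
                side = frozenset(leafset - side)
            if side:
                out[side] = e
        return out

    def leaf_path_lengths(self, source: str) -> dict[str, float]:
        adj = self.adjacency()
        dist = {source: 0.0}
        stack = [source]
        while stack:
            node = stack.pop()
            for nxt, ln, _ in adj[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + ln
                    stack.append(nxt)
        return {leaf: dist[leaf] for leaf in self.leaves}

    def newick(self) -> str:
        adj = self.adjacency()
        internal = [n for n in adj if n not in set(self.leaves)]
        root = internal[-1] if internal else self.leaves[0]

        def fmt(node: str, parent: str | None, inc: Edge | None) -> str:
            children = [
                (nxt, e) for nxt, _, e in adj[node] if nxt != parent
            ]
            if not children:  # leaf
                assert inc is not None
                return f"{node}:{inc.length:.10g}"
            inner = ",".join(fmt(nxt, node, e) for nxt, e in children)
            if parent is None:
                return f"({inner});"
            sup = "" if inc is None or inc.support is None else f"{inc.support:.6g}"
            ln = 0.0 if inc is None else inc.length
            return f"({inner}){sup}:{ln:.10g}"

        return fmt(root, None, None)


@dataclass
class LineageAssignment:
    labels: dict[str, str]
    method: str
    ambiguous: set[str] = field(default_factory=set)
    diagnostics: dict[str, str] = field(default_factory=dict)

    def proportions(self) -> dict[str, float]:
        n = len(self.labels)
        out: dict[str, float] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0.0) + 1.0
        return {k: v / n for k, v in sorted(out.items())}


# --- distance models -------------------------------------------------------

def _pair_counts(si: np.ndarray, sj: np.ndarray, vi: np.ndarray, vj: np.ndarray):
    """(sites compared, A<->G transitions, C<->T transitions, transversions)."""
    both = vi & vj
    m = int(both.sum())
    if m == 0:
        return 0, 0, 0, 0
    x, y = si[both], sj[both]
    diff = x != y
    is_pur_x = (x == b"A") | (x == b"G")
    is_pur_y = (y == b"A") | (y == b"G")
    ts = diff & (is_pur_x == is_pur_y)
    p1 = int((ts & is_pur_x).sum())
    p2 = int((ts & ~is_pur_x).sum())
    q = int((diff & (is_pur_x != is_pur_y)).sum())
    return m, p1, p2, q


def _base_freqs(a: Alignment) -> dict[bytes, float]:
    valid = a.valid_mask()
    flat = a.seqs[valid]
    total = flat.size
    if total == 0:
        raise PhyloError("no unambiguous bases in alignment")
    return {b: float((flat == b).sum()) / total for b in (b"A", b"C", b"G", b"T")}


def _tn93(p1: float, p2: float, q: float, g: dict[bytes, float]) -> float:
    gA, gC, gG, gT = g[b"A"], g[b"C"], g[b"G"], g[b"T"]
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        raise PhyloError("TN93 requires all four bases present")
    w1 = 2 * gA * gG / gR
    w2 = 2 * gC * gT / gY
    a1_arg = 1 - p1 / w1 - q / (2 * gR)
    a2_arg = 1 - p2 / w2 - q / (2 * gY)
    b_arg = 1 - q / (2 * gR * gY)
    if a1_arg <= 0 or a2_arg <= 0 or b_arg <= 0:
        raise FloatingPointError("saturated pair")
    b = -math.log(b_arg)
    return (
        w1 * (-math.log(a1_arg))
        + w2 * (-math.log(a2_arg))
        + 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * b
    )


def distance_matrix(
    a: Alignment,
    model: Model = "p",
    missing_policy: MissingPolicy = "pairwise",
) -> DistanceMatrix:
    """Pairwise distances under p, K2P, TN93 or composite-likelihood."""
    if a.n < 2:
        raise PhyloError("distance matrix requires >= 2 sequences")
    if missing_policy == "exclude_site":
        sites = a.retained_sites("exclude_site")
        seqs = a.seqs[:, sites]
        valid = np.ones(seqs.shape, dtype=bool)
    else:
        seqs = a.seqs
        valid = a.valid_mask()

    n = a.n
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    freqs = _base_freqs(a) if model in ("tn93", "mcl") else None

    pooled = None
    if model == "mcl":
        tot_m = tot_p1 = tot_p2 = tot_q = 0
        for i in range(n):
            for j in range(i + 1, n):
                m, p1, p2, q = _pair_counts(seqs[i], seqs[j], valid[i], valid[j])
                tot_m += m
                tot_p1 += p1
                tot_p2 += p2
                tot_q += q
        diff_tot = tot_p1 + tot_p2 + tot_q
        if diff_tot > 0:
            pooled = (tot_p1 / diff_tot, tot_p2 / diff_tot, tot_q / diff_tot)

    for i in range(n):
        for j in range(i + 1, n):
            m, p1, p2, q = _pair_counts(seqs[i], seqs[j], valid[i], valid[j])
            if m == 0:
                raise PhyloError(
                    f"no shared unambiguous sites for pair "
                    f"({a.sample_ids[i]}, {a.sample_ids[j]})"
                )
            p_p1, p_p2, p_q = p1 / m, p2 / m, q / m
            try:
                if model == "p":
                    val = p_p1 + p_p2 + p_q
                elif model == "k2p":
                    P, Q = p_p1 + p_p2, p_q
                    a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
                    if a1 <= 0 or a2 <= 0:
                        raise FloatingPointError("saturated pair")
                    val = -0.5 * math.log(a1) - 0.25 * math.log(a2)
                elif model == "tn93":
                    val = _tn93(p_p1, p_p2, p_q, freqs)
                elif model == "mcl":
                    pd = p_p1 + p_p2 + p_q
                    if pooled is None or pd == 0:
                        val = 0.0 if pd == 0 else _tn93(p_p1, p_p2, p_q, freqs)
                    else:
                        try:
                            val = _tn93(
                                pooled[0] * pd, pooled[1] * pd, pooled[2] * pd, freqs
                            )
                        except FloatingPointError:
                            # joint composition unusable for this pair
                            val = _tn93(p_p1, p_p2, p_q, freqs)
                else:
                    raise PhyloError(f"unknown model {model!r}")
            except FloatingPointError:
                val = SATURATION_CEILING
                saturated.append((a.sample_ids[i], a.sample_ids[j]))
            d[i, j] = d[j, i] = val
    return DistanceMatrix(list(a.sample_ids), d, model, saturated)


# --- neighbour joining -----------------------------------------------------

def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei agglomeration with the Studier-Keppler criterion.

    Ties in Q are broken by the lexicographically smallest (sorted)
    taxon-name pair, making the output deterministic.
    """
    names = list(d.names)
    if len(names) < 3:
        raise PhyloError("NJ requires >= 3 taxa")
    if len(set(names)) != len(names):
        raise PhyloError("duplicate taxon names")
    mat = {
        (a, b): float(d.values[i, j])
        for i, a in enumerate(names)
        for j, b in enumerate(names)
    }
    active = list(names)
    edges: list[Edge] = []
    counter = 0

    def dist(a: str, b: str) -> float:
        return mat[(a, b)]

    while len(active) > 2:
        r = len(active)
        row_sums = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                qv = (r - 2) * dist(a, b) - row_sums[a] - row_sums[b]
                key = (qv, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lb = dab - la
        new = f"__nj{counter}"
        counter += 1
        edges.append(Edge(new, a, max(la, 0.0), la))
        edges.append(Edge(new, b, max(lb, 0.0), lb))
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            mat[(new, c)] = mat[(c, new)] = duc
        mat[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]

    a, b = active
    edges.append(Edge(a, b, max(dist(a, b), 0.0), dist(a, b)))
    return Tree(leaves=names, edges=edges)


def bootstrap_support(
    a: Alignment,
    model: Model = "p",
    B: int = 2000,
    seed: int | None = None,
    missing_policy: MissingPolicy = "pairwise",
) -> Tree:
    """NJ tree with bootstrap support over site resampling.

    Only retained sites (after the missing-data policy) are resampled.
    Support is the percentage of replicates containing each internal
    bipartition.
    """
    if B <= 0:
        raise PhyloError("bootstrap requires B > 0")
    if a.n < 4:
        raise PhyloError("bootstrap support requires >= 4 taxa")
    rng = np.random.default_rng(seed)
    tree = nj_tree(distance_matrix(a, model, missing_policy))
    biparts = tree.bipartitions()
    counts = {bp: 0 for bp in biparts}
    sites = a.retained_sites(missing_policy)
    for _ in range(B):
        cols = rng.choice(sites, size=len(sites), replace=True)
        rep = Alignment(list(a.sample_ids), a.seqs[:, cols], dict(a.labels))
        try:
            rep_tree = nj_tree(distance_matrix(rep, model, "pairwise"))
        except PhyloError:
            continue
        rep_biparts = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_biparts:
                counts[bp] += 1
    for bp, edge in biparts.items():
        edge.support = 100.0 * counts[bp] / B
    return tree


def assign_lineage(
    a: Alignment,
    refs: Alignment,
    ref_labels: dict[str, str] | None = None,
    method: Literal["nj_clade", "min_distance"] = "nj_clade",
    model: Model = "p",
    missing_policy: MissingPolicy = "pairwise",
    tolerance: float = 0.0,
) -> LineageAssignment:
    """Label each sample with the lineage of the matching references.

    ``nj_clade`` builds a joint NJ tree and gives each sample the label
    of the smallest uniformly-labelled reference clade it falls into;
    ``min_distance`` assigns the nearest reference's label and flags
    samples whose best-vs-second-best margin is below ``tolerance``.
    """
    if ref_labels is None:
        ref_labels = {sid: refs.labels[sid].breed for sid in refs.sample_ids}
    if a.L != refs.L:
        raise PhyloError(
            f"sample alignment length {a.L} != reference length {refs.L}"
        )
    overlap = set(a.sample_ids) & set(refs.sample_ids)
    if overlap:
        raise PhyloError(f"sample/reference id collision: {sorted(overlap)[:3]}")
    joint = Alignment(
        list(a.sample_ids) + list(refs.sample_ids),
        np.vstack([a.seqs, refs.seqs]),
        {**a.labels, **refs.labels},
    )
    result = LineageAssignment({}, method)

    if method == "min_distance":
        dm = distance_matrix(joint, model, missing_policy)
        n = a.n
        for i, sid in enumerate(a.sample_ids):
            dist_to_refs = sorted(
                (dm.values[i, n + j], ref_labels[rid])
                for j, rid in enumerate(refs.sample_ids)
            )
            best, second = dist_to_refs[0], dist_to_refs[1]
            result.labels[sid] = best[1]
            if second[0] - best[0] < tolerance or (
                second[0] == best[0] and second[1] != best[1]
            ):
                result.ambiguous.add(sid)
                result.diagnostics[sid] = (
                    f"margin {second[0] - best[0]:.6g} to {second[1]}"
                )
        return result

    if method != "nj_clade":
        raise PhyloError(f"unknown assignment method {method!r}")

    tree = nj_tree(distance_matrix(joint, model, missing_policy))
    ref_set = set(refs.sample_ids)

    # root between the two most distant differently-labelled references,
    # then read each sample's smallest uniformly-labelled ancestor clade
    best_pair = None
    for r1 in refs.sample_ids:
        paths = tree.leaf_path_lengths(r1)
        for r2 in refs.sample_ids:
            if ref_labels[r1] == ref_labels[r2]:
                continue
            key = (paths[r2], *sorted((r1, r2)))
            if best_pair is None or key > best_pair[0]:
                best_pair = (key, r1, r2)

    adj = tree.adjacency()

    def path_nodes(src: str, dst: str) -> list[tuple[str, float]]:
        """Nodes along src -> dst with cumulative distance at each node."""
        prev: dict[str, tuple[str, float]] = {src: ("", 0.0)}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, ln, _ in adj[x]:
                if y not in prev:
                    prev[y] = (x, prev[x][1] + ln)
                    stack.append(y)
        out = []
        cur = dst
        while cur:
            out.append((cur, prev[cur][1]))
            cur = prev[cur][0]
        return out[::-1]

    if best_pair is not None:
        _, r1, r2 = best_pair
        nodes = path_nodes(r1, r2)
        half = nodes[-1][1] / 2.0
        root_edge = None
        for (u, du), (v, _dv) in zip(nodes, nodes[1:]):
            if du <= half:
                root_edge = (u, v)
        root_u, root_v = root_edge
    else:  # all references share one label
        root_u = refs.sample_ids[0]
        root_v = adj[root_u][0][0]

    # parent pointers away from the root edge
    parent: dict[str, str | None] = {root_u: None, root_v: None}
    order = [root_u, root_v]
    stack = [(root_u, root_v), (root_v, root_u)]
    while stack:
        node, avoid = stack.pop()
        for nxt, _, _ in adj[node]:
            if nxt == avoid or nxt in parent:
                continue
            parent[nxt] = node
            order.append(nxt)
            stack.append((nxt, node))

    desc_refs: dict[str, set[str]] = {n: set() for n in parent}
    for rid in refs.sample_ids:
        cur: str | None = rid
        while cur is not None:
            desc_refs[cur].add(rid)
            cur = parent[cur]

    path_cache: dict[str, dict[str, float]] = {}
    for sid in a.sample_ids:
        label = None
        cur = parent[sid]
        while cur is not None:
            labs = {ref_labels[r] for r in desc_refs[cur]}
            if len(labs) == 1:
                label = labs.pop()
                break
            if labs:
                break  # mixed clade: stop ascending
            cur = parent[cur]
        if label is None and cur is None:
            # reached a side root with no references below: other side
            top = root_v if sid in _descendants(parent, root_v) else root_u
            labs = {ref_labels[r] for r in desc_refs[top]}
            if len(labs) == 1:
                label = labs.pop()
        if label is not None:
            result.labels[sid] = label
            continue
        # mixed clade right away: nearest reference by tree path length
        if sid not in path_cache:
            path_cache[sid] = tree.leaf_path_lengths(sid)
        dists = sorted(
            (path_cache[sid][rid], ref_labels[rid]) for rid in refs.sample_ids
        )
        result.labels[sid] = dists[0][1]
        result.diagnostics[sid] = "no uniform reference clade; used path distance"
        if len(dists) > 1 and dists[1][0] == dists[0][0] and dists[1][1] != dists[0][1]:
            result.ambiguous.add(sid)
    return result


def _descendants(parent: dict[str, str | None], top: str) -> set[str]:
    out = set()
    for node in parent:
        cur: str | None = node
        while cur is not None:
            if cur == top:
                out.add(node)
                break
            cur = parent[cur]
    return out
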
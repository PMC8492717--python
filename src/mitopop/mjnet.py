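"""Median-joining haplotype networks.

Implements the iterative median-joining procedure: build the
minimum-spanning network (all links within ``epsilon`` of the minimal
connection cost), enumerate triplet consensus (quasi-median) candidates,
add the cheapest new medians, repeat to a fixpoint, then purge obsolete
medians (unlabelled nodes of degree <= 2).  All sites carry weight 1;
ties are broken by canonical (lexicographic) node order so the network
is independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from mitopop.alignment import HaplotypeTable


class NetworkError(ValueError):
    pass


@dataclass
class NetNode:
    name: str                    # "H<i>" for observed, "mv<i>" for medians
    seq: str                     # string over the variable sites
    is_median: bool
    counts: np.ndarray           # per-population carrier counts (zeros for medians)

    @property
    def frequency(self) -> int:
        return int(self.counts.sum())


@dataclass
class NetEdge:
    u: str
    v: str
    weight: int
    sites: tuple[int, ...]       # 0-based original alignment columns


@dataclass
class HaploNetwork:
    nodes: list[NetNode]
    edges: list[NetEdge]
    populations: list[str]
    variable_sites: np.ndarray   # original columns underlying node.seq
    converged: bool = True

    def node(self, name: str) -> NetNode:
        for nd in self.nodes:
            if nd.name == name:
                return nd
        raise KeyError(name)

    def degree(self, name: str) -> int:
        return sum(1 for e in self.edges if name in (e.u, e.v))

    def median_count(self) -> int:
        return sum(1 for nd in self.nodes if nd.is_median)

    def is_connected(self) -> bool:
        if not self.nodes:
            return True
        adj: dict[str, set[str]] = {nd.name: set() for nd in self.nodes}
        for e in self.edges:
            adj[e.u].add(e.v)
            adj[e.v].add(e.u)
        seen = {self.nodes[0].name}
        stack = [self.nodes[0].name]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == len(self.nodes)

    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges)

    def to_gml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        for nd in self.nodes:
            g.add_node(
                nd.name,
                seq=nd.seq,
                median=int(nd.is_median),
                frequency=nd.frequency,
                **{f"n_{p}": int(c) for p, c in zip(self.populations, nd.counts)},
            )
        for e in self.edges:
            g.add_edge(e.u, e.v, weight=e.weight, sites=",".join(map(str, e.sites)))
        nx.write_gml(g, str(path))

    def edge_list_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node1\tnode2\tweight\tsites\n")
            for e in self.edges:
                fh.write(
                    f"{e.u}\t{e.v}\t{e.weight}\t{','.join(map(str, e.sites))}\n"
                )

    def node_table_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tmedian\tfrequency\t" + "\t".join(self.populations) + "\n")
            for nd in self.nodes:
                fh.write(
                    f"{nd.name}\t{int(nd.is_median)}\t{nd.frequency}\t"
                    + "\t".join(str(int(c)) for c in nd.counts)
                    + "\n"
                )


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _msn_edges(seqs: list[str], epsilon: int) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network links among sequences (canonical order).

    A link (i, j) of weight w is feasible when i and j are not already
    connected using links of weight < w - epsilon; at epsilon=0 this is
    the union of all minimum spanning trees.
    """
    k = len(seqs)
    pairs = sorted(
        ((_hamming(seqs[i], seqs[j]), i, j) for i, j in combinations(range(k), 2))
    )
    out: list[tuple[int, int, int]] = []
    uf = _UnionFind(range(k))
    ptr = 0
    idx = 0
    while idx < len(pairs):
        w = pairs[idx][0]
        # connectivity from all strictly cheaper links (minus the slack)
        while ptr < len(pairs) and pairs[ptr][0] < w - epsilon:
            uf.union(pairs[ptr][1], pairs[ptr][2])
            ptr += 1
        while idx < len(pairs) and pairs[idx][0] == w:
            _, i, j = pairs[idx]
            if uf.find(i) != uf.find(j):
                out.append((i, j, w))
            idx += 1
    return out


def _consensus_median(u: str, v: str, w: str) -> str:
    """Per-site majority of a triple; three-way-distinct sites keep the
    state of the first (canonically smallest) sequence."""
    out = []
    for x, y, z in zip(u, v, w):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def median_joining(
    h: HaplotypeTable,
    epsilon: int = 0,
    max_median_rounds: int = 25,
) -> HaploNetwork:
    """Median-joining network of the haplotypes in ``h``."""
    if h.k < 2:
        raise NetworkError("median-joining needs >= 2 haplotypes")

    mat = np.frombuffer(
        "".join(h.haplotypes).encode("ascii"), dtype="S1"
    ).reshape(h.k, -1)
    var_cols = np.flatnonzero([len(np.unique(mat[:, j])) > 1 for j in range(mat.shape[1])])
    var_sites = h.retained_sites[var_cols] if len(h.retained_sites) else var_cols
    observed = {
        mat[i, var_cols].tobytes().decode("ascii"): i for i in range(h.k)
    }
    if len(observed) != h.k:
        raise NetworkError("haplotypes are not pairwise distinct")

    node_seqs = set(observed)
    converged = True
    for _ in range(max_median_rounds):
        seqs = sorted(node_seqs)
        links = _msn_edges(seqs, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
        for i, j, _w in links:
            adj[i].add(j)
            adj[j].add(i)
        # candidate triples: nodes mutually reachable through shared links
        candidates: dict[str, int] = {}
        for i in range(len(seqs)):
            for j, k in combinations(sorted(adj[i] | {i}), 2):
                if j == i or k == i:
                    continue
                m = _consensus_median(seqs[min(i, j, k)], *[
                    seqs[x] for x in sorted((i, j, k))[1:]
                ])
                if m in node_seqs:
                    continue
                cost = (
                    _hamming(seqs[i], m)
                    + _hamming(seqs[j], m)
                    + _hamming(seqs[k], m)
                )
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        new = {m for m, c in candidates.items() if c <= lam + epsilon}
        node_seqs |= new
    else:
        converged = False

    # purge: drop median nodes of degree <= 2, rebuild, repeat
    while True:
        seqs = sorted(node_seqs)
        links = _msn_edges(seqs, epsilon)
        deg = {i: 0 for i in range(len(seqs))}
        for i, j, _w in links:
            deg[i] += 1
            deg[j] += 1
        drop = {
            seqs[i]
            for i in range(len(seqs))
            if seqs[i] not in observed and deg[i] <= 2
        }
        if not drop:
            break
        node_seqs -= drop

    seqs = sorted(node_seqs)
    links = _msn_edges(seqs, epsilon)
    names: dict[str, str] = {}
    nodes: list[NetNode] = []
    mv = 0
    npop = h.counts.shape[1]
    for s in seqs:
        if s in observed:
            idx = observed[s]
            names[s] = f"H{idx + 1}"
            nodes.append(NetNode(names[s], s, False, h.counts[idx].copy()))
        else:
            mv += 1
            names[s] = f"mv{mv}"
            nodes.append(NetNode(names[s], s, True, np.zeros(npop, dtype=np.int64)))
    edges = []
    for i, j, w in links:
        diff_sites = tuple(
            int(var_sites[p]) for p in range(len(seqs[i])) if seqs[i][p] != seqs[j][p]
        )
        edges.append(NetEdge(names[seqs[i]], names[seqs[j]], w, diff_sites))
    return HaploNetwork(nodes, edges, list(h.populations), var_sites, converged)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_observed: int
    n_medians: int
    n_edges: int
    n_singletons: int
    max_frequency: int
    total_samples: int
    star_index: dict[str, int] = field(default_factory=dict)


def network_summary(net: HaploNetwork) -> NetworkSummary:
    """Counts of nodes/medians/singletons and per-node star indices.

    The star index of a node is its degree counting weight-1 edges only.
    """
    star: dict[str, int] = {nd.name: 0 for nd in net.nodes}
    for e in net.edges:
        if e.weight == 1:
            star[e.u] += 1
            star[e.v] += 1
    freqs = [nd.frequency for nd in net.nodes if not nd.is_median]
    return NetworkSummary(
        n_nodes=len(net.nodes),
        n_observed=sum(1 for nd in net.nodes if not nd.is_median),
        n_medians=net.median_count(),
        n_edges=len(net.edges),
        n_singletons=sum(1 for f in freqs if f == 1),
        max_frequency=max(freqs) if freqs else 0,
        total_samples=int(sum(freqs)),
        star_index=star,
    )
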
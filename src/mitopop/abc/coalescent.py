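"""Single-locus haploid coalescent under a scenario's event program.

Genealogy: constant effective size per population epoch (gene copies),
instantaneous splits (backwards in time the derived population's
lineages move into the source), optional size changes.  Mutations are
Poisson with rate mu per site per generation, placed uniformly over
sites (finite-sites, recurrent hits possible) with the replacement base
drawn from HKY relative rates (transition/transversion ratio ``kappa``,
stationary base frequencies ``freqs``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mitopop.alignment import Alignment, SampleLabel
from mitopop.abc.scenario import ResizeEvent, Scenario, SplitEvent

_BASES = np.frombuffer(b"ACGT", dtype="S1")
DEFAULT_FREQS = (0.25, 0.25, 0.25, 0.25)


class SimulationError(RuntimeError):
    pass


@dataclass
class Genealogy:
    """Coalescent tree: node i < n_leaves is a sample; parent[root] = -1."""

    n_leaves: int
    parent: np.ndarray       # int array of length 2n-1
    time: np.ndarray         # node times in generations
    pop_of_leaf: np.ndarray  # population index per leaf

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl


def _resolve_samples(scenario: Scenario, samples: dict[str, int]) -> list[tuple[str, int]]:
    out = []
    for pop in scenario.pops:
        k = int(samples.get(pop, 0))
        if k < 0:
            raise SimulationError(f"negative sample size for {pop}")
        out.append((pop, k))
    total = sum(k for _, k in out)
    if total == 0:
        raise SimulationError("zero samples in total")
    extra = set(samples) - set(scenario.pops)
    if extra:
        raise SimulationError(f"samples given for unknown populations {sorted(extra)}")
    return out


def simulate_genealogy(
    scenario: Scenario,
    params: dict[str, float],
    samples: dict[str, int],
    rng: np.random.Generator,
) -> Genealogy:
    """Run the structured coalescent for one scenario realization."""
    per_pop = _resolve_samples(scenario, samples)
    for a, b in scenario.constraints:
        if not params[a] > params[b]:
            raise SimulationError(f"constraint {a} > {b} violated by params")

    n = sum(k for _, k in per_pop)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    pop_of_leaf = np.zeros(n, dtype=np.int64)

    lineages: dict[str, list[int]] = {}
    node = 0
    for pi, (pop, k) in enumerate(per_pop):
        lineages[pop] = list(range(node, node + k))
        pop_of_leaf[node : node + k] = pi
        node += k

    ne = {pop: float(params[sym]) for pop, sym in scenario.ne.items()}
    for pop, size in ne.items():
        if size <= 0:
            raise SimulationError(f"non-positive effective size for {pop}")

    events = sorted(scenario.events, key=lambda ev: params[ev.time_symbol])
    next_node = n
    t = 0.0
    ev_idx = 0

    def total_lineages() -> int:
        return sum(len(v) for v in lineages.values())

    while total_lineages() > 1:
        rates = {
            pop: len(lin) * (len(lin) - 1) / (2.0 * ne[pop])
            for pop, lin in lineages.items()
            if len(lin) >= 2
        }
        total_rate = sum(rates.values())
        next_event_t = (
            params[events[ev_idx].time_symbol] if ev_idx < len(events) else np.inf
        )
        if total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
        else:
            wait = np.inf
        if t + wait >= next_event_t:
            if not np.isfinite(next_event_t):
                raise SimulationError(
                    f"scenario {scenario.scenario_id}: lineages stranded in "
                    f"{sorted(p for p, l in lineages.items() if l)} with no "
                    "remaining events"
                )
            t = next_event_t
            ev = events[ev_idx]
            ev_idx += 1
            if isinstance(ev, SplitEvent):
                moved = lineages.pop(ev.derived, [])
                lineages.setdefault(ev.source, []).extend(moved)
                ne.pop(ev.derived, None)
            elif isinstance(ev, ResizeEvent):
                if ev.pop in ne:
                    new_size = float(params[ev.size_symbol])
                    if new_size <= 0:
                        raise SimulationError("non-positive resize value")
                    ne[ev.pop] = new_size
            continue
        t += wait
        # choose the population, then a uniform pair within it
        pops_r = list(rates)
        probs = np.array([rates[p] for p in pops_r]) / total_rate
        pop = pops_r[rng.choice(len(pops_r), p=probs)]
        lin = lineages[pop]
        i, j = rng.choice(len(lin), size=2, replace=False)
        a, b = lin[int(i)], lin[int(j)]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        lin[:] = [x for x in lin if x not in (a, b)] + [next_node]
        next_node += 1

    return Genealogy(n, parent, time, pop_of_leaf)


def _hky_transition_targets(base: int, kappa: float, freqs: np.ndarray) -> np.ndarray:
    """Relative HKY rates from ``base`` to each of ACGT (self rate 0)."""
    # transitions: A<->G (0,2), C<->T (1,3)
    rates = freqs.copy()
    rates[base] = 0.0
    partner = {0: 2, 1: 3, 2: 0, 3: 1}[base]
    rates[partner] *= kappa
    return rates / rates.sum()


def mutate_genealogy(
    g: Genealogy,
    L: int,
    mu: float,
    rng: np.random.Generator,
    kappa: float = 2.0,
    freqs: tuple[float, float, float, float] = DEFAULT_FREQS,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop mutations on the genealogy.

    Returns ``(var, cols)``: an (n_leaves, S) int matrix of leaf states
    (0..3) at the S distinct mutated sites and the site indices.
    Columns that ended up monomorphic (recurrent/back mutation) are kept.
    """
    freqs_arr = np.asarray(freqs, dtype=float)
    freqs_arr = freqs_arr / freqs_arr.sum()
    bl = g.branch_lengths()
    n_mut_per_branch = rng.poisson(mu * L * bl)
    total = int(n_mut_per_branch.sum())
    if total == 0:
        return np.zeros((g.n_leaves, 0), dtype=np.int8), np.zeros(0, dtype=np.int64)

    sites = rng.integers(0, L, size=total)
    cols, col_of_mut = np.unique(sites, return_inverse=True)
    S = len(cols)

    # per-branch mutation lists with a position along the branch so that
    # multiple hits on one branch apply in time order (old -> young)
    branch_of_mut = np.repeat(np.arange(g.n_nodes), n_mut_per_branch)
    pos = rng.random(total)  # 0 = parent end (older)

    muts_by_branch: dict[int, list[tuple[float, int]]] = {}
    for m in range(total):
        muts_by_branch.setdefault(int(branch_of_mut[m]), []).append(
            (float(pos[m]), int(col_of_mut[m]))
        )
    for v in muts_by_branch.values():
        v.sort()

    children: dict[int, list[int]] = {}
    root = int(np.flatnonzero(g.parent < 0)[0])
    for child, par in enumerate(g.parent):
        if par >= 0:
            children.setdefault(int(par), []).append(child)

    root_state = rng.choice(4, size=S, p=freqs_arr).astype(np.int8)
    var = np.zeros((g.n_leaves, S), dtype=np.int8)
    stack: list[tuple[int, np.ndarray]] = [(root, root_state)]
    while stack:
        node, state = stack.pop()
        if node in muts_by_branch:
            state = state.copy()
            for _, col in muts_by_branch[node]:
                state[col] = int(
                    rng.choice(4, p=_hky_transition_targets(int(state[col]), kappa, freqs_arr))
                )
        if node < g.n_leaves:
            var[node] = state
        for ch in children.get(node, []):
            stack.append((ch, state))
    return var, cols


def simulate_var(
    scenario: Scenario,
    params: dict[str, float],
    samples: dict[str, int],
    L: int,
    rng: np.random.Generator,
    freqs: tuple[float, float, float, float] = DEFAULT_FREQS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast path: simulate and return only the mutated-site leaf matrix.

    Returns ``(var, cols, pop_of_leaf)``.
    """
    g = simulate_genealogy(scenario, params, samples, rng)
    kappa = float(params.get("kappa", 2.0))
    var, cols = mutate_genealogy(g, L, float(params["mu"]), rng, kappa, freqs)
    return var, cols, g.pop_of_leaf


def simulate_dataset(
    scenario: Scenario,
    params: dict[str, float],
    samples: dict[str, int],
    L: int,
    rng_seed: int | np.random.Generator,
    freqs: tuple[float, float, float, float] = DEFAULT_FREQS,
) -> Alignment:
    """Simulate one aligned dataset labelled by population.

    Sample ids are ``<pop>_<i>``; the population name is stored in both
    the breed and metapopulation label fields.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    var, cols, pop_of_leaf = simulate_var(scenario, params, samples, L, rng, freqs)
    n = var.shape[0]
    freqs_arr = np.asarray(freqs, dtype=float)
    freqs_arr = freqs_arr / freqs_arr.sum()
    background = rng.choice(4, size=L, p=freqs_arr)
    seqs = np.tile(_BASES[background], (n, 1))
    if len(cols):
        seqs[:, cols] = _BASES[var]
    per_pop = _resolve_samples(scenario, samples)
    ids: list[str] = []
    labels: dict[str, SampleLabel] = {}
    counters = {pop: 0 for pop, _ in per_pop}
    for leaf in range(n):
        pop = per_pop[pop_of_leaf[leaf]][0]
        counters[pop] += 1
        sid = f"{pop}_{counters[pop]}"
        ids.append(sid)
        labels[sid] = SampleLabel(breed=pop, metapopulation=pop)
    return Alignment(ids, seqs, labels)
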
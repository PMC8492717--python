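"""Demographic scenarios and prior specifications.

A scenario is a backwards-in-time event program over named populations
(e.g. ME / MP / IS metapopulations): ``split`` events merge a derived
population into its source, ``resize`` events change a population's
effective size (in gene copies — mtDNA is haploid and maternally
inherited, so sizes here are NOT 2N).  Times are in generations.

Parameter symbols (effective sizes, event times, the mutation rate
``mu`` and the transition/transversion ratio ``kappa``) are drawn from
the prior; ordering constraints among time symbols are honoured by
rejection re-draws.

Text format (one block per scenario)::

    scenario 1_ME
      pops ME MP IS
      ne ME NME
      ne MP NMP
      ne IS NIS
      split IS MP @ t2
      split MP ME @ t1
      constraint t1 > t2

Priors file::

    prior NME loguniform 1000 100000
    prior t1 uniform 100 20000
    prior mu loguniform 1e-8 1e-7
    prior kappa uniform 2 20
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class SplitEvent:
    """Backwards in time: lineages of ``derived`` merge into ``source``."""

    derived: str
    source: str
    time_symbol: str


@dataclass(frozen=True)
class ResizeEvent:
    """Backwards in time: ``pop`` takes effective size ``size_symbol``
    for epochs older than ``time_symbol``."""

    pop: str
    size_symbol: str
    time_symbol: str


Event = SplitEvent | ResizeEvent


@dataclass
class Scenario:
    scenario_id: str
    pops: list[str]
    ne: dict[str, str]                      # population -> size symbol
    events: list[Event] = field(default_factory=list)
    constraints: list[tuple[str, str]] = field(default_factory=list)  # (a, b): a > b

    def __post_init__(self) -> None:
        for p in self.pops:
            if p not in self.ne:
                raise ScenarioError(
                    f"scenario {self.scenario_id}: population {p} has no size symbol"
                )
        self._check_coalesces()

    def _check_coalesces(self) -> None:
        alive = set(self.pops)
        for ev in self.events:
            if isinstance(ev, SplitEvent):
                if ev.derived not in alive:
                    raise ScenarioError(
                        f"scenario {self.scenario_id}: split of inactive "
                        f"population {ev.derived}"
                    )
                if ev.source not in alive:
                    raise ScenarioError(
                        f"scenario {self.scenario_id}: split into inactive "
                        f"population {ev.source}"
                    )
                alive.discard(ev.derived)
        if len(alive) != 1:
            raise ScenarioError(
                f"scenario {self.scenario_id}: event program leaves "
                f"{sorted(alive)} unmerged; all lineages must coalesce"
            )

    @property
    def symbols(self) -> list[str]:
        """All parameter symbols used by this scenario (excluding mu/kappa)."""
        out: dict[str, None] = {}
        for s in self.ne.values():
            out.setdefault(s, None)
        for ev in self.events:
            out.setdefault(ev.time_symbol, None)
            if isinstance(ev, ResizeEvent):
                out.setdefault(ev.size_symbol, None)
        for a, b in self.constraints:
            out.setdefault(a, None)
            out.setdefault(b, None)
        return list(out)


@dataclass(frozen=True)
class Prior:
    family: str          # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ScenarioError("prior bounds must be finite")
        if self.low > self.high:
            raise ScenarioError(f"empty prior [{self.low}, {self.high}]")
        if self.family == "loguniform" and self.low <= 0:
            raise ScenarioError("log-uniform prior requires positive bounds")
        if self.family not in ("uniform", "loguniform"):
            raise ScenarioError(f"unknown prior family {self.family!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.low == self.high:  # point mass (degenerate prior)
            return float(self.low)
        if self.family == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))

    def median(self) -> float:
        if self.family == "uniform":
            return 0.5 * (self.low + self.high)
        return float(np.sqrt(self.low * self.high))


@dataclass
class PriorSpec:
    priors: dict[str, Prior]

    def __getitem__(self, symbol: str) -> Prior:
        try:
            return self.priors[symbol]
        except KeyError:
            raise ScenarioError(f"no prior declared for symbol {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.priors

    def require(self, symbols: Iterable[str]) -> None:
        missing = [s for s in symbols if s not in self.priors]
        if missing:
            raise ScenarioError(f"priors missing for symbols: {missing}")


#: substitution-model symbols every simulation draws in addition to the
#: scenario's demographic symbols
MODEL_SYMBOLS = ("mu", "kappa")


def draw_parameters(
    scenario: Scenario,
    priors: PriorSpec,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> dict[str, float]:
    """Draw one parameter vector honouring the scenario's constraints."""
    symbols = scenario.symbols + [s for s in MODEL_SYMBOLS if s in priors]
    priors.require(scenario.symbols)
    if "mu" not in priors:
        raise ScenarioError("a prior for the mutation rate 'mu' is required")
    for _ in range(max_tries):
        params = {s: priors[s].draw(rng) for s in symbols}
        ok = all(params[a] > params[b] for a, b in scenario.constraints)
        if ok:
            return params
    bad = [
        f"{a} > {b}"
        for a, b in scenario.constraints
    ]
    raise ScenarioError(
        f"could not satisfy constraints {bad} for scenario "
        f"{scenario.scenario_id} after {max_tries} draws"
    )


# --- text-format parsing ---------------------------------------------------

def parse_scenarios(text_or_path: str | Path) -> list[Scenario]:
    """Parse the scenario definition format (see module docstring)."""
    text = _read(text_or_path)
    scenarios: list[Scenario] = []
    cur: dict | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None:
            scenarios.append(
                Scenario(
                    cur["id"], cur["pops"], cur["ne"], cur["events"], cur["constraints"]
                )
            )
            cur = None

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kw = tok[0].lower()
        if kw == "scenario":
            flush()
            if len(tok) != 2:
                raise ScenarioError(f"line {lineno}: 'scenario <id>' expected")
            cur = {"id": tok[1], "pops": [], "ne": {}, "events": [], "constraints": []}
            continue
        if cur is None:
            raise ScenarioError(f"line {lineno}: directive before any 'scenario'")
        if kw == "pops":
            cur["pops"] = tok[1:]
        elif kw == "ne":
            if len(tok) != 3:
                raise ScenarioError(f"line {lineno}: 'ne <pop> <symbol>' expected")
            cur["ne"][tok[1]] = tok[2]
        elif kw == "split":
            if len(tok) != 5 or tok[3] != "@":
                raise ScenarioError(
                    f"line {lineno}: 'split <derived> <source> @ <time>' expected"
                )
            cur["events"].append(SplitEvent(tok[1], tok[2], tok[4]))
        elif kw == "resize":
            if len(tok) != 5 or tok[3] != "@":
                raise ScenarioError(
                    f"line {lineno}: 'resize <pop> <size-symbol> @ <time>' expected"
                )
            cur["events"].append(ResizeEvent(tok[1], tok[2], tok[4]))
        elif kw == "constraint":
            if len(tok) != 4 or tok[2] != ">":
                raise ScenarioError(f"line {lineno}: 'constraint <a> > <b>' expected")
            cur["constraints"].append((tok[1], tok[3]))
        else:
            raise ScenarioError(f"line {lineno}: unknown directive {kw!r}")
    flush()
    if not scenarios:
        raise ScenarioError("no scenarios defined")
    return scenarios


def parse_priors(text_or_path: str | Path) -> PriorSpec:
    text = _read(text_or_path)
    priors: dict[str, Prior] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0].lower() != "prior" or len(tok) != 5:
            raise ScenarioError(
                f"line {lineno}: 'prior <symbol> <family> <low> <high>' expected"
            )
        priors[tok[1]] = Prior(tok[2].lower(), float(tok[3]), float(tok[4]))
    if not priors:
        raise ScenarioError("no priors defined")
    return PriorSpec(priors)


def _read(text_or_path: str | Path) -> str:
    if isinstance(text_or_path, Path):
        return text_or_path.read_text()
    if "\n" not in text_or_path and Path(text_or_path).exists():
        return Path(text_or_path).read_text()
    return text_or_path


# --- shipped scenario presets ----------------------------------------------

def lineage_a_scenarios() -> list[Scenario]:
    """Second-round colonization hypotheses for the dominant lineage:
    a Middle-East source chain versus an Indian-subcontinent source."""
    ne = {"ME": "NME", "MP": "NMP", "IS": "NIS"}
    s1_me = Scenario(
        "1_ME",
        ["ME", "MP", "IS"],
        dict(ne),
        [SplitEvent("IS", "MP", "t2"), SplitEvent("MP", "ME", "t1")],
        [("t1", "t2")],
    )
    s4_is = Scenario(
        "4_IS",
        ["ME", "MP", "IS"],
        dict(ne),
        [SplitEvent("MP", "IS", "t2"), SplitEvent("ME", "IS", "t1")],
        [("t1", "t2")],
    )
    return [s1_me, s4_is]


def lineage_b_scenarios() -> list[Scenario]:
    """Inland-route chain versus an independent (sea-route) colonization.

    The second scenario gives the IS split its own unconstrained time
    symbol ``t4`` because the branching order is unknown.
    """
    ne = {"ME": "NME", "MP": "NMP", "IS": "NIS"}
    inland = Scenario(
        "inland",
        ["ME", "MP", "IS"],
        dict(ne),
        [SplitEvent("IS", "MP", "t2"), SplitEvent("MP", "ME", "t1")],
        [("t1", "t2")],
    )
    sea = Scenario(
        "sea",
        ["ME", "MP", "IS"],
        dict(ne),
        [SplitEvent("IS", "ME", "t4"), SplitEvent("MP", "ME", "t1")],
        [],
    )
    return [inland, sea]


def default_priors() -> PriorSpec:
    """Documented placeholder priors (the study's exact bounds are in its
    supplementary material and are accepted as user overrides)."""
    return PriorSpec(
        {
            "NME": Prior("loguniform", 10_000, 1_000_000),
            "NMP": Prior("loguniform", 10_000, 1_000_000),
            "NIS": Prior("loguniform", 10_000, 1_000_000),
            "t1": Prior("uniform", 5_000, 100_000),
            "t2": Prior("uniform", 1_000, 100_000),
            "t4": Prior("uniform", 1_000, 100_000),
            "mu": Prior("loguniform", 1e-8, 1e-7),
            "kappa": Prior("uniform", 2.0, 20.0),
        }
    )
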
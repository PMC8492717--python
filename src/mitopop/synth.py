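"""Synthetic multi-breed haplotype datasets with known ground truth.

Generates aligned sequence sets with 2-3 divergent lineages, star-like
expansion within lineages (small ancestral / large current effective
size through the coalescent simulator), unequal lineage frequencies
across breeds, and singleton-rich haplotype spectra — the structure the
downstream analyses assume — plus a small labelled reference panel for
lineage assignment.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mitopop.alignment import Alignment, SampleLabel
from mitopop.abc.coalescent import _BASES, simulate_var
from mitopop.abc.scenario import Prior, PriorSpec, ResizeEvent, Scenario

LINEAGE_LETTERS = string.ascii_uppercase


class SynthError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_breeds: int = 3
    samples_per_breed: int | Sequence[int] = 20
    L: int = 612
    n_lineages: int = 2
    divergence: int = 20           # expected mutations between lineage founders
    mixture: Sequence[Sequence[float]] | None = None  # (n_breeds, n_lineages)
    current_ne: float = 50_000.0   # large current size -> star-like expansion
    ancestral_ne: float = 500.0
    t_expansion: float = 2_000.0
    mu: float = 5e-8
    kappa: float = 4.0
    seed: int = 0

    def sample_counts(self) -> list[int]:
        if isinstance(self.samples_per_breed, int):
            return [self.samples_per_breed] * self.n_breeds
        counts = list(self.samples_per_breed)
        if len(counts) != self.n_breeds:
            raise SynthError("samples_per_breed must match n_breeds")
        return counts

    def mixture_matrix(self) -> np.ndarray:
        if self.mixture is None:
            # dominant first lineage, the rest sharing a small remainder
            w = np.full(self.n_lineages, 0.08 / max(self.n_lineages - 1, 1))
            w[0] = 0.92 if self.n_lineages > 1 else 1.0
            m = np.tile(w, (self.n_breeds, 1))
        else:
            m = np.asarray(self.mixture, dtype=float)
        if m.shape != (self.n_breeds, self.n_lineages):
            raise SynthError(
                f"mixture must be ({self.n_breeds}, {self.n_lineages}), got {m.shape}"
            )
        if not np.allclose(m.sum(axis=1), 1.0):
            raise SynthError("per-breed mixture weights must sum to 1")
        if (m < 0).any():
            raise SynthError("mixture weights must be non-negative")
        return m


@dataclass
class TruthRecord:
    lineage_of_sample: dict[str, str]
    breed_of_sample: dict[str, str]
    lineage_counts: dict[str, int]
    per_breed_counts: dict[str, dict[str, int]]
    founder_seqs: dict[str, str]
    min_founder_distance: int
    overlap_warning: bool
    seed: int

    def proportions(self) -> dict[str, float]:
        total = sum(self.lineage_counts.values())
        return {k: v / total for k, v in sorted(self.lineage_counts.items())}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "lineage_of_sample": self.lineage_of_sample,
                    "breed_of_sample": self.breed_of_sample,
                    "lineage_counts": self.lineage_counts,
                    "per_breed_counts": self.per_breed_counts,
                    "min_founder_distance": self.min_founder_distance,
                    "overlap_warning": self.overlap_warning,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )


def _expansion_scenario(lineage: str) -> tuple[Scenario, dict[str, float]]:
    scen = Scenario(
        f"expansion_{lineage}",
        ["P"],
        {"P": "Ncur"},
        [ResizeEvent("P", "Nanc", "texp")],
    )
    return scen, {}


def _random_seq(L: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=L)]


def _make_founders(
    root: np.ndarray, n_lineages: int, divergence: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Founders with ``divergence // 2`` private mutations each at disjoint
    sites, so pairwise founder distances equal 2*(divergence // 2)."""
    L = len(root)
    per = max(divergence // 2, 0)
    needed = per * n_lineages
    if needed > L:
        raise SynthError("divergence too large for locus length")
    sites = rng.choice(L, size=needed, replace=False)
    founders = []
    for i in range(n_lineages):
        f = root.copy()
        for s in sites[i * per : (i + 1) * per]:
            cur = f[s]
            choices = [b for b in _BASES if b != cur]
            f[s] = choices[int(rng.integers(3))]
        founders.append(f)
    return founders


def generate_breeds(
    cfg: GeneratorConfig,
    founders: list[np.ndarray] | None = None,
    breed_names: list[str] | None = None,
) -> tuple[Alignment, TruthRecord]:
    """Generate a multi-breed alignment plus its ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.sample_counts()
    if any(c <= 0 for c in counts):
        raise SynthError("all breed sample counts must be positive")
    mix = cfg.mixture_matrix()
    if breed_names is None:
        breed_names = [f"Breed{i + 1:02d}" for i in range(cfg.n_breeds)]
    lineages = [LINEAGE_LETTERS[i] for i in range(cfg.n_lineages)]

    root = _random_seq(cfg.L, rng)
    if founders is None:
        founders = _make_founders(root, cfg.n_lineages, cfg.divergence, rng)
    elif len(founders) != cfg.n_lineages:
        raise SynthError("founders must match n_lineages")
    founders = [np.asarray(f, dtype="S1") for f in founders]

    # realized lineage membership per breed (bookkeeping is exact)
    per_breed = [rng.multinomial(c, m) for c, m in zip(counts, mix)]
    n_per_lineage = np.sum(per_breed, axis=0)

    # simulate within-lineage variation via the expansion coalescent
    lineage_seqs: dict[int, list[np.ndarray]] = {}
    params = {
        "Ncur": cfg.current_ne,
        "Nanc": cfg.ancestral_ne,
        "texp": cfg.t_expansion,
        "mu": cfg.mu,
        "kappa": cfg.kappa,
    }
    within_max = 0
    for li in range(cfg.n_lineages):
        n_l = int(n_per_lineage[li])
        if n_l == 0:
            lineage_seqs[li] = []
            continue
        if n_l == 1:
            lineage_seqs[li] = [founders[li].copy()]
            continue
        scen, _ = _expansion_scenario(lineages[li])
        var, cols, _pol = simulate_var(scen, params, {"P": n_l}, cfg.L, rng)
        seqs = []
        for k in range(n_l):
            s = founders[li].copy()
            if len(cols):
                s[cols] = _BASES[var[k]]
            seqs.append(s)
        if len(cols):
            d = (var[:, None, :] != var[None, :, :]).sum(axis=2)
            within_max = max(within_max, int(d.max()))
        lineage_seqs[li] = seqs

    ids: list[str] = []
    labels: dict[str, SampleLabel] = {}
    rows: list[np.ndarray] = []
    lineage_of_sample: dict[str, str] = {}
    breed_of_sample: dict[str, str] = {}
    per_breed_counts: dict[str, dict[str, int]] = {}
    used = {li: 0 for li in range(cfg.n_lineages)}
    for b, breed in enumerate(breed_names):
        per_breed_counts[breed] = {}
        for li, lineage in enumerate(lineages):
            k = int(per_breed[b][li])
            if k:
                per_breed_counts[breed][lineage] = k
            for j in range(k):
                sid = f"{breed}_s{sum(per_breed[b][:li]) + j + 1}"
                ids.append(sid)
                labels[sid] = SampleLabel(breed=breed, region="synthetic")
                rows.append(lineage_seqs[li][used[li]])
                used[li] += 1
                lineage_of_sample[sid] = lineage
                breed_of_sample[sid] = breed

    founder_d = [
        int((founders[i] != founders[j]).sum())
        for i in range(cfg.n_lineages)
        for j in range(i + 1, cfg.n_lineages)
    ]
    min_fd = min(founder_d) if founder_d else 0
    lineage_counts = {
        lineages[li]: int(n_per_lineage[li]) for li in range(cfg.n_lineages)
    }
    truth = TruthRecord(
        lineage_of_sample,
        breed_of_sample,
        lineage_counts,
        per_breed_counts,
        {lineages[i]: founders[i].tobytes().decode() for i in range(cfg.n_lineages)},
        min_fd,
        overlap_warning=(cfg.n_lineages > 1 and min_fd <= within_max),
        seed=cfg.seed,
    )
    return Alignment(ids, np.vstack(rows), labels), truth


def generate_reference_fixture(
    L: int = 612, n_lineages: int = 5, seed: int = 2021
) -> tuple[Alignment, dict[str, str]]:
    """Labelled reference haplotypes (A..E), pairwise >= 15 mutations apart."""
    rng = np.random.default_rng(seed)
    root = _random_seq(L, rng)
    founders = _make_founders(root, n_lineages, 16, rng)
    letters = [LINEAGE_LETTERS[i] for i in range(n_lineages)]
    ids = [f"ref_{c}" for c in letters]
    labels = {
        sid: SampleLabel(breed=c, region="reference") for sid, c in zip(ids, letters)
    }
    aln = Alignment(ids, np.vstack(founders), labels)
    return aln, dict(zip(ids, letters))


def write_fixture(
    cfg: GeneratorConfig, outdir: str | Path, prefix: str = "synthetic"
) -> dict[str, Path]:
    """Write FASTA + metadata TSV + truth JSON for a generated dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, truth = generate_breeds(cfg)
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "metadata": outdir / f"{prefix}.meta.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    aln.to_fasta(paths["fasta"])
    aln.write_metadata(paths["metadata"])
    truth.to_json(paths["truth"])
    return paths
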
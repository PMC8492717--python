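"""Metric multidimensional scaling of pairwise Phi_ST matrices.

Default is classical (Torgerson) scaling: double-centre the squared
distance matrix and eigendecompose; an iterative SMACOF mode (seeded)
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mitopop.popgen import FstMatrix


class MdsError(ValueError):
    pass


@dataclass
class MdsResult:
    populations: list[str]
    coordinates: np.ndarray  # (n_pops, dims), column means zero
    eigenvalues: np.ndarray
    stress: float

    def to_tsv(self, path: str | Path) -> None:
        dims = self.coordinates.shape[1]
        with open(path, "w") as fh:
            fh.write("population\t" + "\t".join(f"dim{i+1}" for i in range(dims)) + "\n")
            for name, row in zip(self.populations, self.coordinates):
                fh.write(name + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")

    def plot(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        xy = self.coordinates
        ax.scatter(xy[:, 0], xy[:, 1])
        for name, (x, y) in zip(self.populations, xy[:, :2]):
            ax.annotate(name, (x, y), fontsize=8)
        ax.set_xlabel("dimension 1")
        ax.set_ylabel("dimension 2")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def _stress(d_in: np.ndarray, coords: np.ndarray) -> float:
    d_emb = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    )
    denom = (d_in**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_in - d_emb) ** 2).sum() / denom))


def mds_from_fst(
    f: FstMatrix | np.ndarray,
    dims: int = 2,
    mode: str = "classical",
    seed: int | None = None,
    populations: list[str] | None = None,
) -> MdsResult:
    """Embed a symmetric distance matrix (negatives clamped to 0)."""
    if isinstance(f, FstMatrix):
        d = np.asarray(f.values, dtype=float)
        populations = list(f.populations)
    else:
        d = np.asarray(f, dtype=float)
        if populations is None:
            populations = [f"pop{i}" for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise MdsError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise MdsError("distance matrix must be symmetric")
    n = d.shape[0]
    dims = min(dims, max(n - 1, 1))
    d = np.clip(d, 0.0, None)
    np.fill_diagonal(d, 0.0)

    if np.allclose(d, 0.0):
        return MdsResult(populations, np.zeros((n, dims)), np.zeros(n), 0.0)

    if mode == "classical":
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        evals, evecs = np.linalg.eigh(b)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        pos = np.clip(evals[:dims], 0.0, None)
        coords = evecs[:, :dims] * np.sqrt(pos)
    elif mode == "smacof":
        import warnings as _warnings

        from sklearn.manifold import MDS

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            model = MDS(
                n_components=dims,
                dissimilarity="precomputed",
                metric=True,
                n_init=4,
                normalized_stress=False,
                random_state=seed,
            )
            coords = model.fit_transform(d)
        evals = np.full(n, np.nan)
    else:
        raise MdsError(f"unknown MDS mode {mode!r}")

    coords = coords - coords.mean(axis=0, keepdims=True)
    if mode == "classical":
        return MdsResult(populations, coords, evals, _stress(d, coords))
    return MdsResult(populations, coords, evals, _stress(d, coords))
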
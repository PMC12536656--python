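"""PMC-surface matrices and concavity diagnostics.

The first nine variable scores are arranged row-major into a 3×3 grid
(X1 X2 X3 / X4 X5 X6 / X7 X8 X9) and drawn as a surface; X10, constant at 1
across the corpus, is excluded to keep the matrix square.  Low cells appear
as depressions ("concavity") and mark weak rubric dimensions.  Concavity is
quantified here as the per-cell shortfall 1 − score and its total — a
package convention, since the underlying model describes concavity only
qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .pmc_scoring import PMCResult, round_half_up

#: Row-major placement of the nine plotted variables.
SURFACE_VARIABLES = ("X1", "X2", "X3", "X4", "X5", "X6", "X7", "X8", "X9")


@dataclass(frozen=True)
class SurfaceMatrix:
    """3×3 grid of variable scores, row-major X1..X9."""

    cells: tuple[tuple[float, float, float], ...]
    label: str = "policy"

    def __post_init__(self):
        arr = np.asarray(self.cells, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError(f"surface must be 3x3, got {arr.shape}")
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("surface cells must lie in [0, 1]")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.cells, dtype=float)

    @property
    def cell_sum(self) -> float:
        return float(self.array.sum())


@dataclass(frozen=True)
class ConcavityReport:
    """Per-cell shortfall 1 − score and its total over the grid."""

    per_cell_depression: tuple[tuple[float, float, float], ...]
    total_depression: float


def build_surface(scores: Mapping[str, float], label: str = "policy") -> SurfaceMatrix:
    """Arrange X1..X9 scores row-major into a surface matrix (X10 excluded)."""
    missing = [v for v in SURFACE_VARIABLES if v not in scores]
    if missing:
        raise KeyError(f"missing variables for surface: {missing}")
    vals = [scores[v] for v in SURFACE_VARIABLES]
    cells = tuple(tuple(vals[r * 3 + c] for c in range(3)) for r in range(3))
    return SurfaceMatrix(cells=cells, label=label)


def mean_surface(
    results: Sequence[PMCResult], label: str = "group mean"
) -> SurfaceMatrix:
    """Cellwise arithmetic mean surface over a set of policies, 3 decimals."""
    if not results:
        raise ValueError("cannot average an empty result set")
    stack = np.stack([build_surface(r.variable_scores).array for r in results])
    mean = stack.mean(axis=0)
    cells = tuple(
        tuple(round_half_up(float(x)) for x in row) for row in mean
    )
    return SurfaceMatrix(cells=cells, label=label)


def concavity(surface: SurfaceMatrix) -> ConcavityReport:
    """Depression 1 − score per cell; total over the nine cells."""
    dep = 1.0 - surface.array
    return ConcavityReport(
        per_cell_depression=tuple(tuple(float(x) for x in row) for row in dep),
        total_depression=float(dep.sum()),
    )


def render_surface(surface: SurfaceMatrix, path: str | Path) -> Path:
    """Draw the 3×3 lattice as a 3-D surface chart (PNG or SVG by suffix).

    No interpolation: the nine cells are plotted as-is on a 3×3 grid with z
    fixed to [0, 1].  Output is deterministic for identical input.
    """
    path = Path(path)
    x, y = np.meshgrid(np.arange(1, 4), np.arange(1, 4))
    z = surface.array
    with plt.rc_context({"svg.hashsalt": "pmcpolicy"}):
        fig = plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(111, projection="3d")
        ax.plot_surface(x, y, z, cmap="viridis", vmin=0.0, vmax=1.0, edgecolor="k", linewidth=0.4)
        ax.set_zlim(0.0, 1.0)
        ax.set_xticks([1, 2, 3])
        ax.set_yticks([1, 2, 3])
        ax.set_xlabel("column")
        ax.set_ylabel("row")
        ax.set_zlabel("score")
        ax.set_title(surface.label)
        fig.savefig(path, metadata=_deterministic_metadata(path.suffix))
        plt.close(fig)
    return path


def _deterministic_metadata(suffix: str) -> dict | None:
    # strip timestamps so identical inputs give byte-identical files
    if suffix.lower() == ".svg":
        return {"Date": None}
    if suffix.lower() == ".png":
        return {"Software": "pmcpolicy"}
    return None


def surface_table(surface: SurfaceMatrix) -> "np.ndarray":
    return surface.array


def save_surface(surface: SurfaceMatrix, path: str | Path) -> None:
    np.savetxt(path, surface.array, delimiter=",", fmt="%.3f")
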
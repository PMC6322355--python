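"""Three-target affinity landscapes.

Plots one target's mean docking score (z) over the plane spanned by two
other targets' scores (x, y). Compounds with good predicted affinity for
all three targets fall in the low-score "valley" of the surface — the
visual complement of the multitarget indices. Gridding is piecewise-linear
interpolation on a Delaunay triangulation of the compound scatter; cells
outside the convex hull are masked, never extrapolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .errors import GeometryError
from .multitarget_index import AggregatedScores

__all__ = ["ContourGrid", "build_contour_grid", "export_grid", "plot_contour"]


@dataclass
class ContourGrid:
    """A rectilinear grid of interpolated scores over a compound scatter."""

    x_axis: np.ndarray
    y_axis: np.ndarray
    z: np.ndarray          # shape (len(y_axis), len(x_axis)); NaN where masked
    mask: np.ndarray       # True = outside the convex hull of the scatter
    points: np.ndarray     # (n, 3) scatter the grid was built from
    compounds: tuple[str, ...]
    targets: tuple[str, str, str]
    resolution: int
    _interpolator: LinearNDInterpolator = field(repr=False, default=None)

    def interpolate(self, x: float, y: float) -> float:
        """Evaluate the underlying interpolant at an arbitrary point."""
        return float(self._interpolator(x, y))

    def minimum_cell(self) -> tuple[float, float, float]:
        """(x, y, z) of the unmasked grid cell with the lowest z."""
        masked = np.where(self.mask, np.inf, self.z)
        iy, ix = np.unravel_index(np.argmin(masked), masked.shape)
        return float(self.x_axis[ix]), float(self.y_axis[iy]), float(self.z[iy, ix])


def build_contour_grid(
    agg: AggregatedScores,
    x_target: str,
    y_target: str,
    z_target: str,
    resolution: int = 50,
) -> ContourGrid:
    """Grid ``z_target``'s scores over the (``x_target``, ``y_target``) plane.

    Uses every compound with a mean score for all three targets; needs at
    least three non-collinear such compounds to triangulate.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    compounds, xs, ys, zs = [], [], [], []
    for compound in agg.compounds:
        triple = [agg.get(compound, t) for t in (x_target, y_target, z_target)]
        if all(v is not None for v in triple):
            compounds.append(compound)
            xs.append(triple[0])
            ys.append(triple[1])
            zs.append(triple[2])
    points = np.column_stack([xs, ys, zs]) if compounds else np.empty((0, 3))
    if len(compounds) < 3:
        raise GeometryError(
            f"need >=3 compounds with scores for all of {x_target}, {y_target}, "
            f"{z_target}; found {len(compounds)}"
        )
    try:
        interp = LinearNDInterpolator(points[:, :2], points[:, 2])
    except QhullError as exc:
        raise GeometryError(f"degenerate (collinear) scatter: {exc}") from None
    x_axis = np.linspace(points[:, 0].min(), points[:, 0].max(), resolution)
    y_axis = np.linspace(points[:, 1].min(), points[:, 1].max(), resolution)
    grid_x, grid_y = np.meshgrid(x_axis, y_axis)
    z = interp(grid_x, grid_y)
    mask = np.isnan(z)
    if mask.all():
        raise GeometryError("degenerate (collinear) scatter: empty triangulation")
    return ContourGrid(
        x_axis=x_axis,
        y_axis=y_axis,
        z=z,
        mask=mask,
        points=points,
        compounds=tuple(compounds),
        targets=(x_target, y_target, z_target),
        resolution=resolution,
        _interpolator=interp,
    )


def export_grid(grid: ContourGrid, out_dir: str | Path, stem: str = "contour") -> None:
    """Write the z matrix as CSV plus a JSON sidecar with axes and targets."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / f"{stem}_z.csv", grid.z, delimiter=",")
    sidecar = {
        "targets": {"x": grid.targets[0], "y": grid.targets[1], "z": grid.targets[2]},
        "resolution": grid.resolution,
        "x_axis": grid.x_axis.tolist(),
        "y_axis": grid.y_axis.tolist(),
        "compounds": list(grid.compounds),
    }
    with (out_dir / f"{stem}_axes.json").open("w", encoding="utf-8") as handle:
        json.dump(sidecar, handle, indent=2)
        handle.write("\n")


def plot_contour(grid: ContourGrid, path: str | Path, invert_axes: bool = True) -> None:
    """Render a filled contour; optionally put better (more negative) scores
    bottom-left, the orientation usual for affinity landscapes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    contour = ax.contourf(grid.x_axis, grid.y_axis, grid.z, levels=12, cmap="RdYlBu")
    ax.plot(grid.points[:, 0], grid.points[:, 1], "ko", markersize=3)
    if invert_axes:
        ax.invert_xaxis()
        ax.invert_yaxis()
    ax.set_xlabel(f"{grid.targets[0]} mean docking score")
    ax.set_ylabel(f"{grid.targets[1]} mean docking score")
    fig.colorbar(contour, ax=ax, label=f"{grid.targets[2]} mean docking score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
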
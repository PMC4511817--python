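"""Linear rugosity: elevation profiles along transects and their path/chord ratio.

The rugosity index of a transect is the along-surface path distance divided
by the straight-line (chord) distance between its endpoints; a flat surface
scores exactly 1.  Profiles are sampled on straight transect lines with
bilinear interpolation of cell-centre elevations — unlike cell-to-cell
path-distance walks on the raster graph this has no diagonal-step inflation
and is exact on planar surfaces.

The plot-level index is averaged over a transect plan; the default plan uses
six transects — two along the long axis (at 1/3 and 2/3 of the width), two
along the short axis (at 1/3 and 2/3 of the length) and the two diagonals —
covering horizontal, vertical and diagonal directions across the plot.
Transect endpoints are expressed in fractional coordinates of the cell-centre
extent, so every station lies within the interpolable lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grid_io import ElevationGrid

__all__ = [
    "ProfileTrace",
    "RugosityResult",
    "DEFAULT_TRANSECT_PLAN",
    "extract_profile",
    "rugosity_index",
    "mean_rugosity",
]

#: ((fx0, fy0), (fx1, fy1)) pairs in fractional coordinates of the cell-centre
#: extent: fx along x (west->east), fy along y (north->south).
DEFAULT_TRANSECT_PLAN: tuple[tuple[tuple[float, float], tuple[float, float]], ...] = (
    ((0.0, 1 / 3), (1.0, 1 / 3)),
    ((0.0, 2 / 3), (1.0, 2 / 3)),
    ((1 / 3, 0.0), (1 / 3, 1.0)),
    ((2 / 3, 0.0), (2 / 3, 1.0)),
    ((0.0, 0.0), (1.0, 1.0)),
    ((0.0, 1.0), (1.0, 0.0)),
)


@dataclass
class ProfileTrace:
    """Sampled elevation profile along one straight transect."""

    chainage: np.ndarray  # m along the transect, strictly increasing from 0
    elevation: np.ndarray  # m, up-positive
    start: tuple[float, float]
    end: tuple[float, float]

    def __post_init__(self) -> None:
        self.chainage = np.asarray(self.chainage, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.chainage.size < 2:
            raise ValueError("profile needs at least 2 stations")
        if not (np.diff(self.chainage) > 0).all() or self.chainage[0] != 0:
            raise ValueError("chainage must strictly increase from 0")

    @property
    def stations(self) -> np.ndarray:
        return np.column_stack([self.chainage, self.elevation])


@dataclass
class RugosityResult:
    """Per-transect rugosity indices with plot-level mean and standard error."""

    per_transect: list[tuple[tuple[float, float], tuple[float, float], float]]
    mean_rugosity: float
    se_rugosity: float
    failed: list[tuple[tuple[float, float], tuple[float, float], str]] = field(
        default_factory=list
    )


def _interpolator(grid: ElevationGrid) -> RegularGridInterpolator:
    z = grid.masked_values()
    return RegularGridInterpolator(
        (np.arange(grid.n_rows), np.arange(grid.n_cols)),
        z,
        method="linear",
        bounds_error=False,
        fill_value=None,  # linear extrapolation in the half-cell rim
    )


def extract_profile(
    grid: ElevationGrid,
    start: tuple[float, float],
    end: tuple[float, float],
    step: float | None = None,
) -> ProfileTrace:
    """Sample an elevation profile along the straight line start -> end.

    Stations are evenly spaced with spacing <= ``step`` (default: one cell
    size) and include both endpoints.  Elevations come from bilinear
    interpolation of cell-centre values; a transect touching nodata fails
    with the first offending chainage.
    """
    if step is None:
        step = grid.cell_size
    if not (step > 0):
        raise ValueError(f"step must be > 0, got {step}")
    x0, ymin, x1, ymax = grid.extent
    for name, (px, py) in (("start", start), ("end", end)):
        if not (x0 <= px <= x1 and ymin <= py <= ymax):
            raise ValueError(
                f"{name} point {(px, py)} outside the grid extent "
                f"({x0}, {ymin}, {x1}, {ymax})"
            )
    length = float(np.hypot(end[0] - start[0], end[1] - start[1]))
    if length == 0:
        raise ValueError("start and end coincide")
    n_seg = max(1, int(np.ceil(length / step - 1e-12)))
    chainage = np.linspace(0.0, length, n_seg + 1)
    t = chainage / length
    xs = start[0] + t * (end[0] - start[0])
    ys = start[1] + t * (end[1] - start[1])
    # continuous (row, col) coordinates of the cell-centre lattice
    cols = (xs - grid.origin[0]) / grid.cell_size - 0.5
    rows = (grid.origin[1] - ys) / grid.cell_size - 0.5
    elev = _interpolator(grid)(np.column_stack([rows, cols]))
    if np.isnan(elev).any():
        bad = chainage[np.isnan(elev)][0]
        raise ValueError(f"transect crosses nodata; first bad chainage {bad:.6g} m")
    return ProfileTrace(chainage=chainage, elevation=elev, start=tuple(start), end=tuple(end))


def rugosity_index(trace: ProfileTrace) -> float:
    """Path length / chord length of a profile; >= 1, == 1 only when level."""
    dc = np.diff(trace.chainage)
    dz = np.diff(trace.elevation)
    path = float(np.hypot(dc, dz).sum())
    return path / float(trace.chainage[-1])


def _plan_to_coords(
    grid: ElevationGrid, plan
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    cs = grid.cell_size
    x0, ymin, x1, ymax = grid.extent
    cx0, cx1 = x0 + cs / 2, x1 - cs / 2
    cy0, cy1 = ymax - cs / 2, ymin + cs / 2  # fy runs north -> south
    out = []
    for (fx0, fy0), (fx1, fy1) in plan:
        p = (cx0 + fx0 * (cx1 - cx0), cy0 + fy0 * (cy1 - cy0))
        q = (cx0 + fx1 * (cx1 - cx0), cy0 + fy1 * (cy1 - cy0))
        out.append((p, q))
    return out


def mean_rugosity(
    grid: ElevationGrid,
    plan=DEFAULT_TRANSECT_PLAN,
    step: float | None = None,
) -> RugosityResult:
    """Average rugosity over a transect plan (default: the six-transect plan).

    Transects that fail (nodata crossing) are flagged and excluded; fewer
    than two usable transects is an error.  SE is the sample standard
    deviation of the per-transect indices over sqrt(n).
    """
    coords = _plan_to_coords(grid, plan)
    if len(coords) < 2:
        raise ValueError("transect plan must contain at least 2 transects")
    per: list[tuple[tuple[float, float], tuple[float, float], float]] = []
    failed: list[tuple[tuple[float, float], tuple[float, float], str]] = []
    for p, q in coords:
        try:
            trace = extract_profile(grid, p, q, step=step)
            per.append((p, q, rugosity_index(trace)))
        except ValueError as exc:
            failed.append((p, q, str(exc)))
    if len(per) < 2:
        raise ValueError(
            f"only {len(per)} usable transects (need >= 2); failures: "
            + "; ".join(msg for _, _, msg in failed)
        )
    vals = np.array([r for _, _, r in per])
    se = float(vals.std(ddof=1) / np.sqrt(vals.size))
    return RugosityResult(
        per_transect=per,
        mean_rugosity=float(vals.mean()),
        se_rugosity=se,
        failed=failed,
    )
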
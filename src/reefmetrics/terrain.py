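"""Per-cell slope and curvature from a DEM via 3x3 window operators.

Slope uses the average-maximum technique: weighted third-order finite
differences over the 3x3 neighbourhood (Horn's method).  With the nine
elevations numbered row-wise top-to-bottom,

    Z1 Z2 Z3
    Z4 Z5 Z6        (Z5 = centre, L = cell size)
    Z7 Z8 Z9

    dz/dx = [(Z3 + 2 Z6 + Z9) - (Z1 + 2 Z4 + Z7)] / (8 L)
    dz/dy = [(Z1 + 2 Z2 + Z3) - (Z7 + 2 Z8 + Z9)] / (8 L)
    tan(theta) = sqrt((dz/dx)^2 + (dz/dy)^2)

Percent slope is ``100 * tan(theta)`` (so 100 % = 45 degrees); degree output
is ``atan`` of the same quantity.  Both are exact for planar surfaces.

Curvature fits the Zevenbergen-Thorne partial quartic through the nine cells:

    D = [(Z4 + Z6)/2 - Z5] / L^2       E = [(Z2 + Z8)/2 - Z5] / L^2
    F = (-Z1 + Z3 + Z7 - Z9) / (4 L^2)
    G = (-Z4 + Z6) / (2 L)             H = (Z2 - Z8) / (2 L)

and reports, in hundredths of the z-unit (the conventional GIS scaling):

    combined = -2 (D + E) * 100                     (convex > 0)
    profile  = +2 (D G^2 + E H^2 + F G H) / (G^2 + H^2) * 100   (convex < 0)
    planform = -2 (D H^2 + E G^2 - F G H) / (G^2 + H^2) * 100

Profile curvature follows the surface in the direction of maximum slope,
planform perpendicular to it; on level cells (G = H = 0) the direction is
undefined and both are reported as 0.  An optional ``z_unit_scale`` rescales
all three outputs to a different reference z-unit (e.g. a 0.5 cm-cell survey
rescaled to the 1 m z-unit used by terrestrial studies).

One-cell borders and cells with any masked neighbour are masked — derivative
values are never fabricated by padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_io import ElevationGrid, MetricRaster

__all__ = [
    "QuadCoefficients",
    "fit_quadratic_window",
    "slope_raster",
    "curvature_raster",
]

_CONVENTION_SLOPE = "tan(theta) of steepest descent; Horn 8-point weighted difference"
_CONVENTION_CURV = (
    "Zevenbergen-Thorne 3x3 fit, x100 of z-unit; combined convex-positive, "
    "profile convex-negative, planform convex-negative"
)


@dataclass(frozen=True)
class QuadCoefficients:
    """Second- and first-order coefficients of the local 3x3 surface fit.

    D, E, F are in 1/m (second order); G, H are dimensionless gradients.
    """

    D: float
    E: float
    F: float
    G: float
    H: float
    window_center: tuple[int, int]


def _windows(z: np.ndarray) -> tuple[np.ndarray, ...]:
    """The nine shifted views Z1..Z9 for every interior cell."""
    return (
        z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:],
        z[1:-1, :-2], z[1:-1, 1:-1], z[1:-1, 2:],
        z[2:, :-2], z[2:, 1:-1], z[2:, 2:],
    )


def _require_3x3(grid: ElevationGrid) -> None:
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise ValueError(
            f"grid smaller than 3x3 ({grid.n_rows}x{grid.n_cols}): "
            "window derivatives need at least one interior cell"
        )


def fit_quadratic_window(grid: ElevationGrid, row: int, col: int) -> QuadCoefficients:
    """Fit the local partial-quartic surface at one interior cell.

    Raises ``ValueError`` on border cells or if any of the nine cells in the
    window is masked ("incomplete window").
    """
    _require_3x3(grid)
    if not (1 <= row < grid.n_rows - 1 and 1 <= col < grid.n_cols - 1):
        raise ValueError(f"({row}, {col}) is not an interior cell")
    win_mask = grid.nodata_mask[row - 1 : row + 2, col - 1 : col + 2]
    if win_mask.any():
        raise ValueError(f"incomplete window at ({row}, {col}): masked neighbour present")
    w = grid.values[row - 1 : row + 2, col - 1 : col + 2]
    z1, z2, z3, z4, z5, z6, z7, z8, z9 = w.ravel()
    L = grid.cell_size
    return QuadCoefficients(
        D=((z4 + z6) / 2 - z5) / L**2,
        E=((z2 + z8) / 2 - z5) / L**2,
        F=(-z1 + z3 + z7 - z9) / (4 * L**2),
        G=(-z4 + z6) / (2 * L),
        H=(z2 - z8) / (2 * L),
        window_center=(row, col),
    )


def _interior_valid(grid: ElevationGrid) -> np.ndarray:
    """Validity of each interior cell: all nine window cells unmasked."""
    ok = ~grid.nodata_mask
    v = np.ones((grid.n_rows - 2, grid.n_cols - 2), dtype=bool)
    for w in _windows(ok):
        v &= w
    return v


def slope_raster(grid: ElevationGrid, units: str = "percent") -> MetricRaster:
    """Maximum rate of elevational change per cell, as percent or degrees.

    ``units="percent"`` gives rise/run (tan theta) x 100; ``units="degrees"``
    gives the slope angle.  Border cells and cells next to nodata are masked.
    """
    if units not in ("percent", "degrees"):
        raise ValueError(f"units must be 'percent' or 'degrees', got {units!r}")
    _require_3x3(grid)
    z = grid.masked_values()
    z1, z2, z3, z4, _z5, z6, z7, z8, z9 = _windows(z)
    L = grid.cell_size
    with np.errstate(invalid="ignore"):
        dzdx = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8 * L)
        dzdy = ((z1 + 2 * z2 + z3) - (z7 + 2 * z8 + z9)) / (8 * L)
        tan_theta = np.hypot(dzdx, dzdy)
    interior = 100.0 * tan_theta if units == "percent" else np.degrees(np.arctan(tan_theta))
    interior[~_interior_valid(grid)] = np.nan

    out = np.full(grid.shape, np.nan)
    out[1:-1, 1:-1] = interior
    return MetricRaster(
        values=out,
        metric_name="percent_slope" if units == "percent" else "slope_degrees",
        units="percent" if units == "percent" else "degrees",
        convention=_CONVENTION_SLOPE,
        cell_size=grid.cell_size,
        origin=grid.origin,
    )


def curvature_raster(
    grid: ElevationGrid, z_unit_scale: float = 1.0
) -> tuple[MetricRaster, MetricRaster, MetricRaster]:
    """Combined, profile and planform curvature rasters.

    ``z_unit_scale`` multiplies all three outputs to express them at a chosen
    reference z-unit (default 1: values stay in hundredths of the grid's own
    z-unit).  Returns ``(combined, profile, planform)``.
    """
    if not (z_unit_scale > 0):
        raise ValueError(f"z_unit_scale must be > 0, got {z_unit_scale}")
    _require_3x3(grid)
    z = grid.masked_values()
    z1, z2, z3, z4, z5, z6, z7, z8, z9 = _windows(z)
    L = grid.cell_size
    with np.errstate(invalid="ignore", divide="ignore"):
        D = ((z4 + z6) / 2 - z5) / L**2
        E = ((z2 + z8) / 2 - z5) / L**2
        F = (-z1 + z3 + z7 - z9) / (4 * L**2)
        G = (-z4 + z6) / (2 * L)
        H = (z2 - z8) / (2 * L)

        combined = -2 * (D + E) * 100.0
        denom = G**2 + H**2
        safe = np.where(denom > 0, denom, 1.0)
        # level cells (G = H = 0): slope direction undefined, report 0
        profile = np.where(denom > 0, 2 * (D * G**2 + E * H**2 + F * G * H) / safe, 0.0) * 100.0
        planform = np.where(denom > 0, -2 * (D * H**2 + E * G**2 - F * G * H) / safe, 0.0) * 100.0

    valid = _interior_valid(grid)
    rasters = []
    for name, arr in (
        ("curvature_combined", combined),
        ("curvature_profile", profile),
        ("curvature_planform", planform),
    ):
        interior = arr * z_unit_scale
        interior[~valid] = np.nan
        out = np.full(grid.shape, np.nan)
        out[1:-1, 1:-1] = interior
        rasters.append(
            MetricRaster(
                values=out,
                metric_name=name,
                units=f"1/100 z-unit x {z_unit_scale:g}",
                convention=_CONVENTION_CURV,
                cell_size=grid.cell_size,
                origin=grid.origin,
            )
        )
    return tuple(rasters)  # type: ignore[return-value]
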
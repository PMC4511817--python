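"""Synthetic reef scenes with analytically known structural metrics.

Two families of scenes:

* :func:`make_analytic_surface` — single closed-form surfaces (flat, tilted
  plane, paraboloid dome/bowl, hemisphere, sine field, triangle wave) whose
  slope, curvature, surface complexity and rugosity are known exactly, used
  as oracles for every pipeline stage.

* :func:`make_colony_field` — a survey-plot emulation: a 25 x 6 m reef plot
  at sub-centimetre cell size with non-overlapping colonies of four
  morphotypes placed on a gently undulating rock/sand matrix:

  - ``mounding``   spherical caps         (closed-form complexity 2Rh/a^2)
  - ``encrusting`` low cosine-squared bumps (complexity by quadrature)
  - ``plating``    raised discs with steep conical rims (closed form)
  - ``branching``  high-frequency rectified sine patches (no closed form)

  The matrix undulation is smoothly suppressed to zero under and around each
  colony footprint so the closed forms stay exact.  Being a 2.5D surface the
  generator cannot express true overhangs; plating rims are steep (not
  reentrant) stand-ins for plate margins.

All randomness flows from one ``numpy`` Generator seeded by ``seed``:
identical (seed, parameters) reproduce a scene bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import quad
from shapely.geometry import MultiPolygon, Point, Polygon, box

from .grid_io import AnnotationFeature, AnnotationSet, ElevationGrid
from .stats import GroupedSample

__all__ = [
    "SyntheticScene",
    "SYNTHETIC_TAXONOMY",
    "DEFAULT_MORPHOTYPES",
    "make_analytic_surface",
    "make_colony_field",
    "make_grouped_metrics",
    "cap_complexity",
    "disc_complexity",
    "bump_complexity",
]

SYNTHETIC_TAXONOMY: dict[str, bool] = {
    "mounding": True,
    "encrusting": True,
    "plating": True,
    "branching": True,
    "rock/rubble": False,
    "sand": False,
}

#: Morphotype shape parameters: radii in metres, other lengths as ratios of
#: the footprint radius.  Radii give >= 20 cells per radius at the default
#: 0.5 cm cell so drape recovery of the closed forms is resolution-adequate.
DEFAULT_MORPHOTYPES: dict[str, dict] = {
    "mounding": {"radius": (0.15, 0.30), "height_ratio": 0.6},
    "encrusting": {"radius": (0.15, 0.30), "height_ratio": 0.15},
    "plating": {"radius": (0.15, 0.30), "height_ratio": 0.5, "rim_ratio": 0.1},
    "branching": {"radius": (0.12, 0.25), "height": 0.06, "wavelength": 0.08},
}

DEFAULT_COUNTS: dict[str, int] = {"mounding": 6, "encrusting": 6, "plating": 4, "branching": 4}


@dataclass
class SyntheticScene:
    """DEM + annotations + per-feature analytic truth for a generated scene."""

    grid: ElevationGrid
    annotations: AnnotationSet
    truth: pd.DataFrame  # feature_id, class_label, analytic metric columns (NaN = no closed form)
    seed: int | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def cap_complexity(a: float, h: float) -> float:
    """Surface complexity of a spherical cap: lateral area 2*pi*R*h over the
    footprint pi*a^2, with sphere radius R = (a^2 + h^2) / (2h)."""
    R = (a**2 + h**2) / (2 * h)
    return 2 * R * h / a**2


def disc_complexity(a: float, h: float, w: float) -> float:
    """Surface complexity of a flat-topped disc with a conical rim.

    Top radius a - w at height h; the rim is a cone frustum from (a, 0) to
    (a - w, h) with slant sqrt(w^2 + h^2)."""
    top = np.pi * (a - w) ** 2
    rim = np.pi * (a + (a - w)) * np.hypot(w, h)
    return float((top + rim) / (np.pi * a**2))


def bump_complexity(a: float, h: float) -> float:
    """Surface complexity of z = h cos^2(pi r / 2a), r <= a, by quadrature."""

    def integrand(r: float) -> float:
        dz = -h * np.sin(np.pi * r / a) * np.pi / (2 * a)
        return 2 * np.pi * r * np.sqrt(1 + dz**2)

    area, _err = quad(integrand, 0, a, limit=200)
    return float(area / (np.pi * a**2))


def _sine_arc_ratio(amplitude: float, wavelength: float, length: float) -> float:
    """Arc length / chord for z = A sin(2 pi x / L) over [0, length]."""
    k = 2 * np.pi / wavelength

    def integrand(x: float) -> float:
        return np.sqrt(1 + (amplitude * k * np.cos(k * x)) ** 2)

    arc, _err = quad(integrand, 0, length, limit=500)
    return float(arc / length)


# ---------------------------------------------------------------------------
# analytic single-surface scenes
# ---------------------------------------------------------------------------

def _grid_coords(extent: tuple[float, float], cell_size: float):
    lx, ly = extent
    nc = int(round(lx / cell_size))
    nr = int(round(ly / cell_size))
    if nr < 3 or nc < 3:
        raise ValueError(f"extent {extent} at cell {cell_size} gives {nr}x{nc} < 3x3 cells")
    xs = (np.arange(nc) + 0.5) * cell_size
    ys = ly - (np.arange(nr) + 0.5) * cell_size
    return nr, nc, xs, ys


def make_analytic_surface(
    kind: str,
    extent: tuple[float, float] = (2.0, 2.0),
    cell_size: float = 0.01,
    **params,
) -> SyntheticScene:
    """Generate a DEM sampling a named closed-form surface, with truth.

    Kinds and their parameters (lengths in metres):

    - ``flat``: ``value`` (default 0)
    - ``plane``: gradients ``gx``, ``gy``
    - ``dome`` / ``bowl``: paraboloid ``z = -/+ a r^2`` about the plot
      centre, coefficient ``a`` (1/m)
    - ``hemisphere``: ``radius``; z = sqrt(R^2 - r^2) inside the footprint,
      0 outside; the annotation polygon is the footprint circle
    - ``sine_field``: ``amplitude``, ``wavelength``, ridges perpendicular to x
    - ``triangle_wave``: ``slope`` (|dz/dx|, default 1) and integer
      ``period_cells`` (even, default 8); breakpoints fall exactly on cell
      centres so profile sampling along x sees every segment at full slope

    The annotation polygon is the plot inset by one cell (full resolution of
    the interior drape), except for ``hemisphere``.  ``truth`` columns are
    NaN where no closed form applies.
    """
    lx, ly = extent
    nr, nc, xs, ys = _grid_coords(extent, cell_size)
    xx, yy = np.meshgrid(xs, ys)
    origin = (0.0, ly)

    truth: dict[str, float] = {
        "surface_complexity": np.nan,
        "mean_percent_slope": np.nan,
        "mean_curv_combined": np.nan,
        "rugosity_long_axis": np.nan,
    }
    polygon = box(cell_size, cell_size, lx - cell_size, ly - cell_size)

    if kind == "flat":
        z = np.full((nr, nc), float(params.get("value", 0.0)))
        truth.update(
            surface_complexity=1.0,
            mean_percent_slope=0.0,
            mean_curv_combined=0.0,
            rugosity_long_axis=1.0,
        )
    elif kind == "plane":
        gx = float(params.get("gx", 0.0))
        gy = float(params.get("gy", 0.0))
        z = gx * xx + gy * yy
        truth.update(
            surface_complexity=float(np.sqrt(1 + gx**2 + gy**2)),
            mean_percent_slope=100.0 * float(np.hypot(gx, gy)),
            mean_curv_combined=0.0,
        )
    elif kind in ("dome", "bowl"):
        a = float(params["a"])
        sign = -1.0 if kind == "dome" else 1.0
        r2 = (xx - lx / 2) ** 2 + (yy - ly / 2) ** 2
        z = sign * a * r2
        # combined curvature -2(D + E) x 100 with D = E = sign * a
        truth.update(mean_curv_combined=-sign * 400.0 * a)
    elif kind == "hemisphere":
        radius = float(params["radius"])
        cx, cy = lx / 2, ly / 2
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        z = np.sqrt(np.maximum(radius**2 - r2, 0.0))
        polygon = Point(cx, cy).buffer(radius, quad_segs=256)
        truth.update(surface_complexity=2.0)  # 2 pi R^2 / pi R^2
    elif kind == "sine_field":
        amplitude = float(params["amplitude"])
        wavelength = float(params["wavelength"])
        z = amplitude * np.sin(2 * np.pi * xx / wavelength)
        ratio = _sine_arc_ratio(amplitude, wavelength, lx - 2 * cell_size)
        truth.update(rugosity_long_axis=ratio, surface_complexity=ratio)
    elif kind == "triangle_wave":
        slope = float(params.get("slope", 1.0))
        period = int(params.get("period_cells", 8))
        if period < 2 or period % 2:
            raise ValueError("period_cells must be an even integer >= 2")
        u = np.arange(nc) % period
        col_z = slope * cell_size * (period / 2 - np.abs(u - period / 2))
        z = np.broadcast_to(col_z, (nr, nc)).copy()
        truth.update(rugosity_long_axis=float(np.sqrt(1 + slope**2)))
    else:
        raise ValueError(f"unknown surface kind {kind!r}")

    if not np.isfinite(z).all():
        raise ValueError(f"surface parameters produce non-finite elevations ({kind})")

    grid = ElevationGrid(values=z, cell_size=cell_size, origin=origin)
    annotations = AnnotationSet(
        features=[
            AnnotationFeature(
                feature_id="surface", class_label="rock/rubble", polygon=polygon, biotic=False
            )
        ],
        taxonomy=SYNTHETIC_TAXONOMY,
        plot_extent=(0.0, 0.0, lx, ly),
    )
    truth_df = pd.DataFrame(
        [{"feature_id": "surface", "class_label": "rock/rubble", **truth}]
    )
    return SyntheticScene(
        grid=grid,
        annotations=annotations,
        truth=truth_df,
        params={"kind": kind, "extent": extent, "cell_size": cell_size, **params},
    )


# ---------------------------------------------------------------------------
# colony-field scenes
# ---------------------------------------------------------------------------

def _colony_height(cls: str, p: dict, a: float) -> float:
    if cls == "branching":
        return float(p["height"])
    return float(p["height_ratio"]) * a


def _colony_profile(cls: str, p: dict, a: float, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Elevation the colony adds, on a window of offsets from its centre."""
    dx, dy = np.broadcast_arrays(dx, dy)
    r = np.hypot(dx, dy)
    inside = r < a
    z = np.zeros_like(r)
    if cls == "mounding":
        h = _colony_height(cls, p, a)
        R = (a**2 + h**2) / (2 * h)
        z[inside] = np.sqrt(np.maximum(R**2 - r[inside] ** 2, 0.0)) - (R - h)
    elif cls == "encrusting":
        h = _colony_height(cls, p, a)
        z[inside] = h * np.cos(np.pi * r[inside] / (2 * a)) ** 2
    elif cls == "plating":
        h = _colony_height(cls, p, a)
        w = float(p["rim_ratio"]) * a
        ri = r[inside]
        z[inside] = np.where(ri <= a - w, h, h * (a - ri) / w)
    elif cls == "branching":
        h = float(p["height"])
        k = 2 * np.pi / float(p["wavelength"])
        z[inside] = h * np.abs(np.sin(k * dx[inside]) * np.sin(k * dy[inside]))
    else:
        raise ValueError(f"unknown morphotype {cls!r}")
    return z


def _colony_truth(cls: str, p: dict, a: float) -> float:
    if cls == "mounding":
        return cap_complexity(a, _colony_height(cls, p, a))
    if cls == "plating":
        return disc_complexity(a, _colony_height(cls, p, a), float(p["rim_ratio"]) * a)
    if cls == "encrusting":
        return bump_complexity(a, _colony_height(cls, p, a))
    return np.nan  # branching: no closed form


def make_colony_field(
    counts: Mapping[str, int] | None = None,
    morphotypes: Mapping[str, dict] | None = None,
    extent: tuple[float, float] = (25.0, 6.0),
    cell_size: float = 0.005,
    seed: int = 0,
    matrix_amplitude: float = 0.04,
    matrix_wavelength: float = 2.0,
    gap: float = 0.05,
    ramp: float = 0.10,
    max_attempts_per_colony: int = 500,
) -> SyntheticScene:
    """Place non-overlapping colonies of each morphotype on an undulating matrix.

    The matrix is ``A/2 (sin 2 pi x / L + sin 2 pi y / L)`` and is ramped to
    exactly zero within ``gap`` of every colony footprint (cosine ramp of
    width ``ramp``), so each colony sits on a locally flat base and its
    closed-form complexity holds exactly.  Colony centres are drawn by
    rejection sampling; failure to place the requested count within
    ``max_attempts_per_colony`` tries per colony is an error reporting the
    achieved count.  The matrix itself is annotated as two half-plot
    features, rock/rubble (west) and sand (east), minus the colony
    footprints.
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    morphotypes = dict(DEFAULT_MORPHOTYPES if morphotypes is None else morphotypes)
    lx, ly = extent
    nr, nc, xs, ys = _grid_coords(extent, cell_size)
    rng = np.random.default_rng(seed)

    # draw radii and place centres (rejection sampling, order fixed by class name)
    placed: list[tuple[str, float, float, float]] = []  # (class, cx, cy, a)
    for cls in sorted(counts):
        if counts[cls] < 0:
            raise ValueError(f"negative count for {cls!r}")
        p = morphotypes[cls]
        for _ in range(counts[cls]):
            lo, hi = p["radius"]
            a = float(rng.uniform(lo, hi))
            margin = a + gap + ramp + cell_size
            for _attempt in range(max_attempts_per_colony):
                cx = float(rng.uniform(margin, lx - margin))
                cy = float(rng.uniform(margin, ly - margin))
                if all(
                    np.hypot(cx - ox, cy - oy) > a + oa + gap for _, ox, oy, oa in placed
                ):
                    placed.append((cls, cx, cy, a))
                    break
            else:
                raise ValueError(
                    f"could not place colony {len(placed) + 1} (class {cls!r}) without "
                    f"overlap in {max_attempts_per_colony} attempts; placed {len(placed)}"
                )

    # matrix surface
    xx = xs[None, :]
    yy = ys[:, None]
    z = (matrix_amplitude / 2) * (
        np.sin(2 * np.pi * xx / matrix_wavelength) + np.sin(2 * np.pi * yy / matrix_wavelength)
    )
    z = np.broadcast_to(z, (nr, nc)).copy() if z.shape != (nr, nc) else z

    def window(cx: float, cy: float, radius: float):
        c0 = max(0, int((cx - radius) / cell_size) - 1)
        c1 = min(nc, int((cx + radius) / cell_size) + 2)
        r0 = max(0, int((ly - (cy + radius)) / cell_size) - 1)
        r1 = min(nr, int((ly - (cy - radius)) / cell_size) + 2)
        return (slice(r0, r1), slice(c0, c1))

    # suppress the matrix under and around each colony (cosine ramp -> exactly 0)
    for cls, cx, cy, a in placed:
        win = window(cx, cy, a + gap + ramp + 2 * cell_size)
        dx = xs[win[1]][None, :] - cx
        dy = ys[win[0]][:, None] - cy
        d = np.hypot(dx, dy)
        t = np.clip((d - (a + gap)) / ramp, 0.0, 1.0)
        z[win] *= 0.5 - 0.5 * np.cos(np.pi * t)

    # add colony shapes on the (now flat) base
    for cls, cx, cy, a in placed:
        win = window(cx, cy, a + cell_size)
        dx = xs[win[1]][None, :] - cx
        dy = ys[win[0]][:, None] - cy
        z[win] += _colony_profile(cls, morphotypes[cls], a, dx, dy)

    grid = ElevationGrid(values=z, cell_size=cell_size, origin=(0.0, ly))

    # annotations: one circle per colony, matrix halves minus colony footprints
    features: list[AnnotationFeature] = []
    truth_rows = []
    circles = []
    for i, (cls, cx, cy, a) in enumerate(placed):
        fid = f"{cls}_{i}"
        circle = Point(cx, cy).buffer(a, quad_segs=64)
        circles.append(circle)
        features.append(
            AnnotationFeature(feature_id=fid, class_label=cls, polygon=circle, biotic=True)
        )
        truth_rows.append(
            {
                "feature_id": fid,
                "class_label": cls,
                "center_x": cx,
                "center_y": cy,
                "radius": a,
                "surface_complexity": _colony_truth(cls, morphotypes[cls], a),
            }
        )

    halves = {
        "rock/rubble": box(0.0, 0.0, lx / 2, ly),
        "sand": box(lx / 2, 0.0, lx, ly),
    }
    for label, half in halves.items():
        remainder = half
        for c in circles:
            remainder = remainder.difference(c)
        parts = (
            list(remainder.geoms) if isinstance(remainder, MultiPolygon) else [remainder]
        )
        for j, part in enumerate(parts):
            if part.is_empty or not isinstance(part, Polygon):
                continue
            fid = f"matrix_{label.replace('/', '_')}_{j}"
            features.append(
                AnnotationFeature(feature_id=fid, class_label=label, polygon=part, biotic=False)
            )
            truth_rows.append(
                {
                    "feature_id": fid,
                    "class_label": label,
                    "center_x": np.nan,
                    "center_y": np.nan,
                    "radius": np.nan,
                    "surface_complexity": np.nan,
                }
            )

    annotations = AnnotationSet(
        features=features, taxonomy=SYNTHETIC_TAXONOMY, plot_extent=(0.0, 0.0, lx, ly)
    )
    return SyntheticScene(
        grid=grid,
        annotations=annotations,
        truth=pd.DataFrame(truth_rows),
        seed=seed,
        params={
            "counts": counts,
            "extent": extent,
            "cell_size": cell_size,
            "matrix_amplitude": matrix_amplitude,
            "matrix_wavelength": matrix_wavelength,
            "gap": gap,
            "ramp": ramp,
        },
    )


def make_grouped_metrics(
    effects: Mapping[str, tuple[float, float]],
    n_per_class: int,
    seed: int = 0,
    distribution: str = "normal",
) -> GroupedSample:
    """Draw per-class metric samples for ANOVA/Tukey/MANOVA power and
    type-I-error studies.

    ``effects`` maps class label to (mean, sd); ``distribution`` is
    ``"normal"`` or ``"lognormal"`` (parameters then apply on the log scale).
    """
    if n_per_class < 2:
        raise ValueError("need n >= 2 per class")
    rng = np.random.default_rng(seed)
    data = {}
    for label in sorted(effects):
        mean, sd = effects[label]
        if not (sd > 0):
            raise ValueError(f"class {label!r}: sd must be > 0, got {sd}")
        draw = rng.normal(mean, sd, size=n_per_class)
        data[label] = np.exp(draw) if distribution == "lognormal" else draw
    if distribution not in ("normal", "lognormal"):
        raise ValueError(f"unknown distribution {distribution!r}")
    return GroupedSample(data=data)
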
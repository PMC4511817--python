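"""Raster, vector and table I/O plus the coordinate conventions shared by all stages.

Conventions fixed here and relied on everywhere else:

* Coordinates are **local planar metres** (the survey lays out a tape-and-depth
  local frame, not a projected CRS).  A CRS tag present in an input file is
  noted in the log and otherwise ignored.
* Elevation is **up-positive**.  Depth-gauge rasters (depth increasing
  downwards) are converted on load with ``depth_mode=True``, which negates the
  band.
* Raster registration is **cell-centre**: cell ``(row, col)`` has its centre at
  ``(origin_x + (col + 0.5) * cell_size, origin_y - (row + 0.5) * cell_size)``
  where ``origin`` is the outer corner of the top-left cell.  Row 0 is the
  northern (largest ``y``) edge.
* Cells are square; a GeoTIFF with unequal pixel scales is rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape

logger = logging.getLogger(__name__)

# GeoTIFF tag codes (kept explicit because the writer/reader below speak raw TIFF)
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0

#: Benthic classes of the French Frigate Shoals survey plot: six scleractinian
#: coral species (biotic) over a rock/rubble and sand matrix (abiotic).
FFS_TAXONOMY: dict[str, bool] = {
    "A. cytherea": True,
    "M. capitata": True,
    "M. patula": True,
    "P. compressa": True,
    "P. lobata": True,
    "P. meandrina": True,
    "rock/rubble": False,
    "sand": False,
}


class GridIOError(ValueError):
    """Raised for malformed raster/vector inputs."""


@dataclass
class ElevationGrid:
    """A single-band DEM on a square-celled planar grid.

    Parameters
    ----------
    values : (nrows, ncols) float array
        Elevation in metres, up-positive.  Masked cells may hold any value
        (they are set to NaN on load).
    cell_size : float
        Edge length of a (square) cell in metres.
    origin : (float, float)
        ``(x, y)`` of the outer corner of the top-left cell.
    nodata_mask : bool array or None
        True where elevation is missing.  ``None`` means fully valid.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise GridIOError(f"elevation grid must be 2-D, got {self.values.ndim}-D")
        if not (self.cell_size > 0):
            raise GridIOError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise GridIOError("nodata_mask shape does not match values")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if not np.isfinite(self.values[~self.nodata_mask]).all():
            raise GridIOError("non-masked elevations must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Outer bounding box ``(xmin, ymin, xmax, ymax)`` in metres."""
        ox, oy = self.origin
        return (ox, oy - self.n_rows * self.cell_size, ox + self.n_cols * self.cell_size, oy)

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Cell-centre y coordinates, descending (row 0 first)."""
        return self.origin[1] - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def masked_values(self) -> np.ndarray:
        """Elevations with masked cells as NaN (copy)."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out


@dataclass
class MetricRaster:
    """A per-cell derived metric aligned cell-for-cell with a source DEM."""

    values: np.ndarray
    metric_name: str
    units: str
    convention: str
    cell_size: float
    origin: tuple[float, float]
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool) | ~np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out


@dataclass
class AnnotationFeature:
    """One digitised benthic feature: a labelled polygon in local planar metres."""

    feature_id: str
    class_label: str
    polygon: Polygon
    biotic: bool

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            raise GridIOError(f"feature {self.feature_id!r}: geometry must be a Polygon")
        if not self.polygon.is_valid:
            raise GridIOError(
                f"feature {self.feature_id!r}: invalid polygon (self-intersecting ring?)"
            )
        if self.polygon.area == 0:
            raise GridIOError(f"feature {self.feature_id!r}: polygon has zero area")


@dataclass
class AnnotationSet:
    """The digitised catalogue of every benthic feature in a survey plot."""

    features: list[AnnotationFeature]
    taxonomy: Mapping[str, bool]
    plot_extent: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GridIOError(f"duplicate feature_ids: {dupes}")
        ext = box(*self.plot_extent)
        for f in self.features:
            if f.class_label not in self.taxonomy:
                raise GridIOError(
                    f"feature {f.feature_id!r}: label {f.class_label!r} not in taxonomy "
                    f"{sorted(self.taxonomy)}"
                )
            if not f.polygon.intersects(ext):
                raise GridIOError(
                    f"feature {f.feature_id!r} does not intersect the plot extent"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def plot_area(self) -> float:
        x0, y0, x1, y1 = self.plot_extent
        return (x1 - x0) * (y1 - y0)


# ---------------------------------------------------------------------------
# GeoTIFF
# ---------------------------------------------------------------------------

def _read_geo_tags(page) -> tuple[tuple[float, float], tuple[float, float]]:
    """Return ((sx, sy), origin) from a GeoTIFF page; reject rotated transforms."""
    tags = page.tags
    if _TAG_MODEL_TRANSFORMATION in tags:
        m = np.asarray(tags[_TAG_MODEL_TRANSFORMATION].value, dtype=float).reshape(4, 4)
        if m[0, 1] != 0 or m[1, 0] != 0:
            raise GridIOError(
                "rotated affine transform is not supported "
                f"(off-diagonal terms {m[0, 1]}, {m[1, 0]})"
            )
        return (abs(m[0, 0]), abs(m[1, 1])), (m[0, 3], m[1, 3])
    sx = sy = 1.0
    ox = oy = 0.0
    if _TAG_MODEL_PIXEL_SCALE in tags:
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        sx, sy = float(scale[0]), float(scale[1])
    if _TAG_MODEL_TIEPOINT in tags:
        tp = tags[_TAG_MODEL_TIEPOINT].value
        i, j, _k, x, y, _z = (float(v) for v in tp[:6])
        ox = x - i * sx
        oy = y + j * sy
    return (sx, sy), (ox, oy)


def load_dem(path: str | Path, depth_mode: bool = False) -> ElevationGrid:
    """Load a single-band GeoTIFF DEM.

    Parameters
    ----------
    path : path to a single-band float GeoTIFF with square, unrotated cells.
    depth_mode : bool
        If True, band values are depths (positive downwards) and are negated
        so the returned grid is up-positive elevation.

    Raises
    ------
    GridIOError
        For multi-band files, non-square cells or rotated transforms.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise GridIOError(f"{path.name}: expected a single band, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise GridIOError(
                f"{path.name}: expected a single band, found {page.samplesperpixel} samples/pixel"
            )
        (sx, sy), origin = _read_geo_tags(page)
        if not np.isclose(sx, sy, rtol=1e-9, atol=0.0):
            raise GridIOError(
                f"{path.name}: cells must be square; pixel scale is {sx} x {sy}"
            )
        if _TAG_GEO_KEY_DIRECTORY in page.tags:
            logger.info(
                "%s: CRS geo-keys present; interpreted as local planar metres and ignored",
                path.name,
            )
        values = page.asarray().astype(np.float64)
        nodata = None
        if _TAG_GDAL_NODATA in page.tags:
            try:
                nodata = float(page.tags[_TAG_GDAL_NODATA].value)
            except (TypeError, ValueError):
                nodata = None
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == nodata
    if depth_mode:
        values = -values
    values[mask] = np.nan
    return ElevationGrid(values=values, cell_size=sx, origin=origin, nodata_mask=mask)


def write_dem(
    grid: ElevationGrid | MetricRaster,
    path: str | Path,
    nodata: float = DEFAULT_NODATA,
) -> None:
    """Write an elevation grid or metric raster as a single-band float64 GeoTIFF.

    Masked cells are written as ``nodata`` and the GDAL nodata tag is set, so a
    round trip through :func:`load_dem` restores values and mask exactly.
    """
    path = Path(path)
    out = grid.values.astype(np.float64).copy()
    out[grid.nodata_mask] = nodata
    cs = grid.cell_size
    ox, oy = grid.origin
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(nodata)),
    ]
    description = ""
    if isinstance(grid, MetricRaster):
        description = json.dumps(
            {"metric_name": grid.metric_name, "units": grid.units, "convention": grid.convention}
        )
    tifffile.imwrite(path, out, extratags=extratags, description=description)


# ---------------------------------------------------------------------------
# GeoJSON annotations
# ---------------------------------------------------------------------------

def load_annotations(
    path: str | Path,
    taxonomy: Mapping[str, bool],
    plot_extent: tuple[float, float, float, float] | None = None,
) -> AnnotationSet:
    """Load a GeoJSON FeatureCollection of labelled benthic polygons.

    Each feature must carry a ``"class"`` property naming its benthic class;
    the class must be a member of ``taxonomy`` (label -> biotic flag).
    MultiPolygons are split into one feature per part (ids suffixed ``_pN``).
    ``plot_extent`` defaults to the collection's ``"plot_extent"`` top-level
    property, or to the bounding box of all geometries.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GridIOError(f"{path.name}: expected a GeoJSON FeatureCollection")
    if "crs" in doc:
        logger.info("%s: CRS member present; coordinates treated as local planar metres", path.name)

    features: list[AnnotationFeature] = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        label = props.get("class", props.get("class_label"))
        if label is None:
            raise GridIOError(f"{path.name}: feature {i} has no 'class' property")
        if label not in taxonomy:
            raise GridIOError(
                f"{path.name}: unknown class label {label!r}; taxonomy is {sorted(taxonomy)}"
            )
        fid = str(props.get("id", feat.get("id", f"f{i}")))
        geom = shape(feat["geometry"])
        if isinstance(geom, Polygon):
            parts = [(fid, geom)]
        elif isinstance(geom, MultiPolygon):
            parts = [(f"{fid}_p{k}", g) for k, g in enumerate(geom.geoms)]
        else:
            raise GridIOError(
                f"{path.name}: feature {fid!r} has geometry type {geom.geom_type}; "
                "only Polygon/MultiPolygon are supported"
            )
        for pid, poly in parts:
            features.append(
                AnnotationFeature(
                    feature_id=pid,
                    class_label=label,
                    polygon=poly,
                    biotic=bool(taxonomy[label]),
                )
            )

    if plot_extent is None:
        if "plot_extent" in doc:
            plot_extent = tuple(float(v) for v in doc["plot_extent"])  # type: ignore[assignment]
        elif features:
            xs0, ys0, xs1, ys1 = zip(*(f.polygon.bounds for f in features))
            plot_extent = (min(xs0), min(ys0), max(xs1), max(ys1))
        else:
            raise GridIOError(f"{path.name}: empty collection and no plot_extent given")
    return AnnotationSet(features=features, taxonomy=dict(taxonomy), plot_extent=plot_extent)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as a GeoJSON FeatureCollection (round-trippable)."""
    doc = {
        "type": "FeatureCollection",
        "plot_extent": list(annotations.plot_extent),
        "features": [
            {
                "type": "Feature",
                "id": f.feature_id,
                "properties": {"id": f.feature_id, "class": f.class_label},
                "geometry": mapping(f.polygon),
            }
            for f in annotations.features
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Feature-metric tables
# ---------------------------------------------------------------------------

#: Fixed column order of the per-feature CSV.
FEATURE_TABLE_COLUMNS: tuple[str, ...] = (
    "feature_id",
    "class_label",
    "area_2d_m2",
    "area_3d_m2",
    "surface_complexity",
    "mean_percent_slope",
    "se_percent_slope",
    "mean_curv_combined",
    "se_curv_combined",
    "mean_curv_profile",
    "se_curv_profile",
    "mean_curv_planform",
    "se_curv_planform",
    "n_cells",
    "area_2d_vector_m2",
    "flags",
)


def write_feature_table(table, path: str | Path) -> None:
    """Write a per-feature metrics table as CSV with the fixed column order.

    ``table`` may be a :class:`~reefmetrics.zonal.FeatureMetricsTable` or a
    DataFrame with (a subset of) :data:`FEATURE_TABLE_COLUMNS`.  Missing
    metrics (e.g. no valid cells) are written as empty fields, never "0".
    """
    df = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    if len(df.columns) == 0:
        df = pd.DataFrame(columns=list(FEATURE_TABLE_COLUMNS))
    cols = [c for c in FEATURE_TABLE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in FEATURE_TABLE_COLUMNS]
    df = df.reindex(columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a per-feature metrics CSV written by :func:`write_feature_table`."""
    return pd.read_csv(path)
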
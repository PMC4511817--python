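"""Zonal statistics: per-feature and per-class summaries of the metric rasters.

The annotation catalogue is rasterised to a label grid (cell-centre
membership, same tie rule as the surface module), per-cell metrics are
aggregated to per-feature mean +/- SE, and class-level summaries with percent
cover reproduce the structure of a community table:

* surface complexity and slope are summarised **over features** (each colony
  is one replicate);
* curvature class statistics **pool cells** within the class, reconstructed
  exactly from the per-feature moments (within + between decomposition);
* percent cover uses exact vector polygon areas, clipped to the plot extent.

SE is always the sample standard deviation (n-1 denominator) over sqrt(n),
and is missing — not zero — when n < 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .grid_io import AnnotationSet, ElevationGrid, MetricRaster
from .surface import cells_in_polygon, surface_complexity_table
from .terrain import curvature_raster, slope_raster

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMetricsTable",
    "rasterize_partition",
    "feature_summary",
    "percent_cover",
    "community_summary",
    "compute_feature_metrics",
]

BACKGROUND = -1

#: Community-summary column order (mirrors the survey's published table).
COMMUNITY_COLUMNS = (
    "class_label",
    "mean_surface_complexity",
    "se_surface_complexity",
    "percent_cover",
    "mean_percent_slope",
    "se_percent_slope",
    "mean_curv_combined",
    "se_curv_combined",
    "mean_curv_profile",
    "se_curv_profile",
    "mean_curv_planform",
    "se_curv_planform",
    "n_features",
)


@dataclass
class FeatureMetricsTable:
    """Per-feature record of areas, complexity and terrain-metric summaries.

    Wraps a DataFrame with one row per feature (see
    :data:`reefmetrics.grid_io.FEATURE_TABLE_COLUMNS`).
    """

    df: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.df

    def __len__(self) -> int:
        return len(self.df)


def rasterize_partition(grid: ElevationGrid, annotations: AnnotationSet) -> np.ndarray:
    """Per-cell feature index (row order in ``annotations``), -1 = background.

    Features must be pairwise non-overlapping after the cell-centre tie rule;
    a cell claimed twice raises an error naming both features and the cell.
    """
    labels = np.full(grid.shape, BACKGROUND, dtype=np.int32)
    for idx, feat in enumerate(annotations):
        sel = cells_in_polygon(grid, feat.polygon)
        clash = sel & (labels != BACKGROUND)
        if clash.any():
            r, c = np.argwhere(clash)[0]
            other = annotations.features[labels[r, c]].feature_id
            raise ValueError(
                f"overlapping features: {feat.feature_id!r} and {other!r} "
                f"both claim cell ({r}, {c})"
            )
        labels[sel] = idx
    return labels


def feature_summary(
    labels: np.ndarray, metric: MetricRaster, annotations: AnnotationSet
) -> pd.DataFrame:
    """Per-feature mean and SE of a metric raster over the labelled cells.

    Masked metric cells are excluded from n.  Features with no valid cell get
    NaN mean/SE and a flag; n = 1 gives a mean but no SE.
    """
    if labels.shape != metric.shape:
        raise ValueError("label grid and metric raster shapes differ")
    vals = metric.masked_values()
    records = []
    for idx, feat in enumerate(annotations):
        cells = vals[labels == idx]
        cells = cells[np.isfinite(cells)]
        n = cells.size
        rec = {"feature_id": feat.feature_id, "n": n, "mean": np.nan, "se": np.nan, "flags": ""}
        if n == 0:
            rec["flags"] = "no_valid_cells"
        else:
            rec["mean"] = float(cells.mean())
            if n >= 2:
                rec["se"] = float(cells.std(ddof=1) / np.sqrt(n))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def percent_cover(annotations: AnnotationSet) -> pd.Series:
    """Percent of plot planimetric area covered by each class (vector areas).

    Every taxonomy class appears (0 for classes with no features).  Polygon
    parts outside the plot extent are clipped out with a logged warning.
    """
    ext = box(*annotations.plot_extent)
    plot_area = annotations.plot_area
    cover = {label: 0.0 for label in annotations.taxonomy}
    clipped = 0.0
    for feat in annotations:
        poly = feat.polygon
        if not poly.within(ext):
            kept = poly.intersection(ext)
            clipped += poly.area - kept.area
            poly = kept
        cover[feat.class_label] += poly.area
    if clipped > 0:
        logger.warning("clipped %.6g m^2 of annotation area outside the plot extent", clipped)
    return pd.Series({k: 100.0 * v / plot_area for k, v in cover.items()}, name="percent_cover")


def _over_features(group: pd.DataFrame, col: str) -> tuple[float, float]:
    vals = group[col].dropna().to_numpy()
    if vals.size == 0:
        return np.nan, np.nan
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else np.nan
    return mean, se


def _pooled_cells(
    group: pd.DataFrame, mean_col: str, se_col: str, n_col: str = "n_cells"
) -> tuple[float, float]:
    """Class mean/SE over pooled cells, from per-feature (mean, se, n) moments.

    Exact: pooled SS = sum[(n_i - 1) sd_i^2 + n_i (m_i - M)^2].
    """
    g = group[[mean_col, se_col, n_col]].rename(columns={n_col: "n_cells"})
    g = g[(g["n_cells"] > 0) & g[mean_col].notna()]
    if len(g) == 0:
        return np.nan, np.nan
    n = g["n_cells"].to_numpy(dtype=float)
    m = g[mean_col].to_numpy(dtype=float)
    sd = g[se_col].to_numpy(dtype=float) * np.sqrt(n)  # se = sd/sqrt(n)
    sd = np.where(np.isfinite(sd), sd, 0.0)  # n = 1 features: no within-feature SS
    N = n.sum()
    grand = float((n * m).sum() / N)
    if N < 2:
        return grand, np.nan
    ss = float(((n - 1) * sd**2).sum() + (n * (m - grand) ** 2).sum())
    pooled_sd = np.sqrt(ss / (N - 1))
    return grand, float(pooled_sd / np.sqrt(N))


def community_summary(table: FeatureMetricsTable, covers: pd.Series) -> pd.DataFrame:
    """Class-level structural-metric summary with percent cover attached.

    Surface complexity and slope: mean +/- SE over features.  Curvature:
    mean +/- SE over cells pooled within the class.  Every class present in
    ``covers`` (the taxonomy) appears, even with zero features.
    """
    df = table.to_frame()
    records = []
    for label in covers.index:
        group = df[df["class_label"] == label]
        rec = {"class_label": label, "n_features": len(group), "percent_cover": covers[label]}
        for col, out in (
            ("surface_complexity", "surface_complexity"),
            ("mean_percent_slope", "percent_slope"),
        ):
            if col in df.columns:
                mean, se = _over_features(group, col)
            else:
                mean, se = np.nan, np.nan
            rec[f"mean_{out}"] = mean
            rec[f"se_{out}"] = se
        for kind in ("combined", "profile", "planform"):
            mcol, scol = f"mean_curv_{kind}", f"se_curv_{kind}"
            ncol = f"n_curv_{kind}" if f"n_curv_{kind}" in df.columns else "n_cells"
            if mcol in df.columns and len(group):
                mean, se = _pooled_cells(group, mcol, scol, n_col=ncol)
            else:
                mean, se = np.nan, np.nan
            rec[f"mean_curv_{kind}"] = mean
            rec[f"se_curv_{kind}"] = se
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    return out.reindex(columns=[c for c in COMMUNITY_COLUMNS if c in out.columns])


def compute_feature_metrics(
    grid: ElevationGrid,
    annotations: AnnotationSet,
    z_unit_scale: float = 1.0,
    slope_units: str = "percent",
) -> FeatureMetricsTable:
    """Run the full per-feature pipeline: drape areas + zonal terrain metrics.

    Convenience wrapper chaining surface complexity, slope and curvature
    rasters, rasterised partition and per-feature summaries into one table.
    """
    table = surface_complexity_table(grid, annotations)
    labels = rasterize_partition(grid, annotations)
    slope = slope_raster(grid, units=slope_units)
    combined, profile, planform = curvature_raster(grid, z_unit_scale=z_unit_scale)

    slope_cols = feature_summary(labels, slope, annotations)
    table["mean_percent_slope"] = slope_cols["mean"].to_numpy()
    table["se_percent_slope"] = slope_cols["se"].to_numpy()
    for name, raster in (
        ("combined", combined),
        ("profile", profile),
        ("planform", planform),
    ):
        cols = feature_summary(labels, raster, annotations)
        table[f"mean_curv_{name}"] = cols["mean"].to_numpy()
        table[f"se_curv_{name}"] = cols["se"].to_numpy()
        table[f"n_curv_{name}"] = cols["n"].to_numpy()
    return FeatureMetricsTable(df=table)
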
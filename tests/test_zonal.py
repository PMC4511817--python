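"""Rasterised partition, per-feature/per-class aggregation and percent cover."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from reefmetrics import (
    community_summary,
    feature_summary,
    percent_cover,
    rasterize_partition,
)
from reefmetrics.grid_io import ElevationGrid, MetricRaster
from reefmetrics.zonal import BACKGROUND, FeatureMetricsTable

from conftest import make_annotations, make_feature


def metric_from(values, cell_size=0.1):
    return MetricRaster(
        values=np.asarray(values, dtype=float), metric_name="test", units="",
        convention="", cell_size=cell_size, origin=(0.0, values.shape[0] * cell_size),
    )


class TestRasterizePartition:
    def test_single_covering_polygon_labels_every_cell(self, flat_grid):
        anns = make_annotations([make_feature(box(-1, -1, 3, 3))])
        labels = rasterize_partition(flat_grid, anns)
        assert (labels == 0).all()

    def test_abutting_rectangles_partition_without_overlap(self, flat_grid):
        # shared edge at x = 1.0 lies on a cell boundary: no centre is claimed twice
        anns = make_annotations(
            [make_feature(box(-1, -1, 1.0, 3), "west"), make_feature(box(1.0, -1, 3, 3), "east")]
        )
        labels = rasterize_partition(flat_grid, anns)
        assert (labels != BACKGROUND).all()
        assert (labels[:, :10] == 0).all() and (labels[:, 10:] == 1).all()

    def test_overlap_error_names_both_features_and_cell(self, flat_grid):
        anns = make_annotations(
            [make_feature(box(0, 0, 1.5, 2), "a"), make_feature(box(0.5, 0, 2, 2), "b")]
        )
        with pytest.raises(ValueError, match="'b' and 'a'"):
            rasterize_partition(flat_grid, anns)

    def test_sub_cell_polygon_labels_nothing(self, flat_grid):
        anns = make_annotations([make_feature(box(0.101, 0.101, 0.14, 0.14), "tiny")])
        labels = rasterize_partition(flat_grid, anns)
        assert (labels == BACKGROUND).all()


class TestFeatureSummary:
    def test_constant_feature_mean_and_zero_se(self, flat_grid):
        anns = make_annotations([make_feature(box(0, 0, 2, 2), "a")])
        labels = rasterize_partition(flat_grid, anns)
        metric = metric_from(np.full(flat_grid.shape, 7.0))
        out = feature_summary(labels, metric, anns)
        assert out.loc[0, "mean"] == 7.0
        assert out.loc[0, "se"] == 0.0

    def test_hand_computed_se(self):
        grid = ElevationGrid(np.zeros((1, 3)), cell_size=1.0, origin=(0, 1))
        anns = make_annotations([make_feature(box(0, 0, 3, 1), "a")], plot_extent=(0, 0, 3, 1))
        labels = rasterize_partition(grid, anns)
        metric = metric_from(np.array([[1.0, 2.0, 3.0]]), cell_size=1.0)
        out = feature_summary(labels, metric, anns)
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "se"] == pytest.approx(1.0 / np.sqrt(3))  # sd({1,2,3}) = 1

    def test_order_invariance(self, flat_grid):
        rng = np.random.default_rng(5)
        metric = metric_from(rng.normal(size=flat_grid.shape))
        f1 = make_feature(box(0.1, 0.1, 0.9, 0.9), "a")
        f2 = make_feature(box(1.1, 1.1, 1.9, 1.9), "b")
        out_ab = feature_summary(
            rasterize_partition(flat_grid, make_annotations([f1, f2])), metric,
            make_annotations([f1, f2]),
        ).set_index("feature_id")
        out_ba = feature_summary(
            rasterize_partition(flat_grid, make_annotations([f2, f1])), metric,
            make_annotations([f2, f1]),
        ).set_index("feature_id")
        for fid in ("a", "b"):
            assert out_ab.loc[fid, "mean"] == out_ba.loc[fid, "mean"]

    def test_no_valid_cells_flagged_with_nan_not_zero(self, flat_grid):
        anns = make_annotations([make_feature(box(0.101, 0.101, 0.14, 0.14), "tiny")])
        labels = rasterize_partition(flat_grid, anns)
        out = feature_summary(labels, metric_from(np.zeros(flat_grid.shape)), anns)
        assert out.loc[0, "flags"] == "no_valid_cells"
        assert np.isnan(out.loc[0, "mean"])


class TestPercentCover:
    def test_full_plot_polygon_is_100(self):
        anns = make_annotations([make_feature(box(0, 0, 2, 2), "a", label="sand")])
        covers = percent_cover(anns)
        assert covers["sand"] == pytest.approx(100.0)

    def test_two_half_plots_50_50_and_zero_classes_present(self):
        anns = make_annotations(
            [make_feature(box(0, 0, 1, 2), "a", label="sand"),
             make_feature(box(1, 0, 2, 2), "b", label="rock/rubble")]
        )
        covers = percent_cover(anns)
        assert covers["sand"] == pytest.approx(50.0)
        assert covers["rock/rubble"] == pytest.approx(50.0)
        assert covers["plating"] == 0.0  # taxonomy class with no features
        assert covers.sum() == pytest.approx(100.0, abs=0.1)

    def test_overhanging_feature_clipped(self, caplog):
        anns = make_annotations([make_feature(box(1, 0, 3, 2), "a", label="sand")])
        with caplog.at_level("WARNING"):
            covers = percent_cover(anns)
        assert covers["sand"] == pytest.approx(50.0)
        assert any("clipped" in r.message for r in caplog.records)

    def test_rasterized_area_converges_to_vector_cover(self):
        # a disc rasterised at two resolutions: cell-count area approaches the
        # vector area as the cell size shrinks
        disc = Point(1.03, 0.96).buffer(0.57, quad_segs=128)
        anns = make_annotations([make_feature(disc, "d", label="sand")])
        errors = []
        for cs in (0.1, 0.025):
            n = int(round(2.0 / cs))
            grid = ElevationGrid(np.zeros((n, n)), cell_size=cs, origin=(0, 2))
            labels = rasterize_partition(grid, anns)
            raster_area = (labels == 0).sum() * cs**2
            errors.append(abs(raster_area - disc.area))
        assert errors[1] < errors[0]


class TestCommunitySummary:
    def _table(self, rows):
        return FeatureMetricsTable(df=pd.DataFrame(rows))

    def test_feature_replicate_mean_and_se(self):
        table = self._table(
            [{"feature_id": "a", "class_label": "sand", "surface_complexity": 1.0, "n_cells": 4},
             {"feature_id": "b", "class_label": "sand", "surface_complexity": 3.0, "n_cells": 4}]
        )
        covers = pd.Series({"sand": 100.0})
        out = community_summary(table, covers).set_index("class_label")
        assert out.loc["sand", "mean_surface_complexity"] == pytest.approx(2.0)
        assert out.loc["sand", "se_surface_complexity"] == pytest.approx(1.0)  # sd sqrt(2)/sqrt(2)

    def test_single_feature_class_has_no_se(self):
        table = self._table(
            [{"feature_id": "a", "class_label": "sand", "surface_complexity": 1.5, "n_cells": 4}]
        )
        out = community_summary(table, pd.Series({"sand": 100.0})).set_index("class_label")
        assert np.isnan(out.loc["sand", "se_surface_complexity"])

    def test_zero_feature_class_still_listed(self):
        table = self._table(
            [{"feature_id": "a", "class_label": "sand", "surface_complexity": 1.5, "n_cells": 4}]
        )
        out = community_summary(
            table, pd.Series({"sand": 60.0, "rock/rubble": 40.0})
        ).set_index("class_label")
        assert out.loc["rock/rubble", "n_features"] == 0
        assert out.loc["rock/rubble", "percent_cover"] == pytest.approx(40.0)

    def test_pooled_curvature_equals_direct_cell_pooling(self):
        rng = np.random.default_rng(9)
        cells_a, cells_b = rng.normal(size=40), rng.normal(loc=0.5, size=25)
        def moments(c):
            return {
                "mean_curv_combined": c.mean(),
                "se_curv_combined": c.std(ddof=1) / np.sqrt(c.size),
                "n_cells": c.size,
            }
        table = self._table(
            [{"feature_id": "a", "class_label": "sand", **moments(cells_a)},
             {"feature_id": "b", "class_label": "sand", **moments(cells_b)}]
        )
        out = community_summary(table, pd.Series({"sand": 100.0})).set_index("class_label")
        pooled = np.concatenate([cells_a, cells_b])
        assert out.loc["sand", "mean_curv_combined"] == pytest.approx(pooled.mean(), rel=1e-12)
        assert out.loc["sand", "se_curv_combined"] == pytest.approx(
            pooled.std(ddof=1) / np.sqrt(pooled.size), rel=1e-12
        )
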
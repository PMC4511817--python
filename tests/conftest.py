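import numpy as np
import pytest
from hypothesis import settings

from reefmetrics import AnnotationFeature, AnnotationSet, ElevationGrid
from reefmetrics.synthetic_reef import SYNTHETIC_TAXONOMY

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def grid_from_function(fn, extent=(2.0, 2.0), cell_size=0.1):
    """DEM sampling z = fn(x, y) at cell centres, origin (0, Ly)."""
    lx, ly = extent
    nc, nr = int(round(lx / cell_size)), int(round(ly / cell_size))
    xs = (np.arange(nc) + 0.5) * cell_size
    ys = ly - (np.arange(nr) + 0.5) * cell_size
    xx, yy = np.meshgrid(xs, ys)
    return ElevationGrid(values=fn(xx, yy), cell_size=cell_size, origin=(0.0, ly))


@pytest.fixture
def flat_grid():
    return grid_from_function(lambda x, y: np.zeros_like(x))


@pytest.fixture
def ramp_grid():
    """Plane z = x (45 degrees along x)."""
    return grid_from_function(lambda x, y: x)


def make_feature(polygon, feature_id="f0", label="rock/rubble"):
    return AnnotationFeature(
        feature_id=feature_id, class_label=label, polygon=polygon, biotic=False
    )


def make_annotations(features, plot_extent=(0.0, 0.0, 2.0, 2.0)):
    return AnnotationSet(
        features=features, taxonomy=SYNTHETIC_TAXONOMY, plot_extent=plot_extent
    )
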
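"""Published class-level structural metrics for the French Frigate Shoals plot.

The surveyed reef plot (FFS site 33, Northwestern Hawaiian Islands) has a
published community table of per-class surface complexity, percent cover,
percent slope and curvature means (+/- SE) over 2,290 digitised colonies and
the two abiotic substrate classes.  The raw DEM behind those numbers is not
redistributable, so this module ships the class-level table itself as
reference input for cover-arithmetic and cross-study comparison.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = [
    "published_community_table",
    "PLATING_BRANCHING_CLASSES",
    "MOUNDING_ENCRUSTING_CLASSES",
    "ABIOTIC_CLASSES",
]

#: Plating / branching morphology corals (the structurally complex group).
PLATING_BRANCHING_CLASSES = ("A. cytherea", "P. compressa", "P. meandrina")
#: Mounding / encrusting morphology corals.
MOUNDING_ENCRUSTING_CLASSES = ("M. capitata", "M. patula", "P. lobata")
#: Abiotic substrate classes.
ABIOTIC_CLASSES = ("rock/rubble", "sand")


def published_community_table() -> pd.DataFrame:
    """The published per-class community metrics table, indexed by class."""
    path = files("reefmetrics.data") / "ffs_community_metrics.csv"
    with path.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    return df.set_index("class_label")
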
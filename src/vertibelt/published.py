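"""Published Mount Taishan reference tables.

The Mount Taishan study that this pipeline generalises printed its fitted
cloud-model characteristics per terrain analysis unit and its belt
delineation, but its DEM and forest-inventory rasters are not publicly
available.  The printed tables are therefore re-entered here as inputs: they
drive the worked examples of the between-type expectation-difference
("invasion") analysis and serve as a realistic configuration template.

All elevations in metres; ``n`` columns are sample-point counts.
"""

from __future__ import annotations

import pandas as pd

from .forest_typing import CONIFER, DECIDUOUS, MIXED

_UNIT_ROWS = [
    # elev_class, forest_type, aspect_class, Ex_m, En_m, He_m, n
    ("<550", DECIDUOUS, "sunny", 407.51, 67.92, 17.56, 137),
    ("<550", DECIDUOUS, "shady", 438.58, 53.15, 8.19, 64),
    ("<550", CONIFER, "sunny", 378.51, 79.12, 24.22, 227),
    ("<550", CONIFER, "shady", 404.91, 64.89, 16.46, 190),
    ("<550", MIXED, "sunny", 370.57, 83.01, 26.26, 87),
    ("<550", MIXED, "shady", 399.43, 70.13, 10.46, 62),
    ("550-900", DECIDUOUS, "sunny", 700.89, 110.01, 34.51, 339),
    ("550-900", DECIDUOUS, "shady", 700.58, 108.92, 34.73, 231),
    ("550-900", CONIFER, "sunny", 695.54, 124.66, 48.07, 270),
    ("550-900", CONIFER, "shady", 706.86, 116.89, 40.92, 440),
    ("550-900", MIXED, "sunny", 701.82, 122.30, 46.43, 116),
    ("550-900", MIXED, "shady", 686.65, 109.73, 33.66, 115),
    ("900-1100", DECIDUOUS, "sunny", 963.56, 46.08, 12.13, 51),
    ("900-1100", DECIDUOUS, "shady", 965.84, 57.76, 17.90, 31),
    ("900-1100", CONIFER, "sunny", 987.51, 60.86, 21.50, 106),
    ("900-1100", CONIFER, "shady", 983.87, 57.78, 19.57, 131),
    ("900-1100", MIXED, "sunny", 992.33, 56.72, 19.61, 28),
    ("900-1100", MIXED, "shady", 988.66, 57.10, 20.46, 29),
    ("1100-1350", CONIFER, "sunny", 1182.76, 57.93, 18.60, 57),
    ("1100-1350", CONIFER, "shady", 1188.50, 59.57, 21.50, 54),
    ("1100-1350", MIXED, "sunny", 1213.16, 64.36, 21.73, 9),
    ("1100-1350", MIXED, "shady", 1218.48, 61.54, 17.06, 12),
    (">1350", CONIFER, "sunny", 1377.64, 64.09, 26.90, 11),
    (">1350", CONIFER, "shady", 1382.60, 59.60, 21.02, 17),
    (">1350", MIXED, "sunny", 1373.57, 48.58, 16.77, 8),
    (">1350", MIXED, "shady", 1389.07, 56.38, 16.27, 11),
]

_ZONE_ROWS = [
    # forest_type, zone, threshold_pct, range_low_m, range_high_m, n
    (DECIDUOUS, "upper", 26.32, 900.0, None, 74),
    (DECIDUOUS, "core", 26.32, 550.0, 900.0, 568),
    (DECIDUOUS, "lower", 26.32, None, 550.0, 198),
    (CONIFER, "upper", 54.64, 1350.0, None, 28),
    (CONIFER, "core", 54.64, 900.0, 1350.0, 334),
    (CONIFER, "lower", 54.64, None, 900.0, 1120),
    (MIXED, "core", 30.0, 1300.0, 1500.0, 23),
    (MIXED, "lower", 30.0, None, 1300.0, 436),
]


def taishan_unit_cloud_table() -> pd.DataFrame:
    """Cloud-model characteristics per (elevation class x type x aspect) unit."""
    return pd.DataFrame(
        _UNIT_ROWS,
        columns=["elev_class", "forest_type", "aspect_class", "Ex_m", "En_m", "He_m", "n"],
    )


def taishan_zone_table() -> pd.DataFrame:
    """Belt internal structure: zones, thresholds, ranges and point counts."""
    return pd.DataFrame(
        _ZONE_ROWS,
        columns=["forest_type", "zone", "threshold_pct", "range_low_m", "range_high_m", "n"],
    )
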
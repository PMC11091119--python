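"""Elevation-bin proportion profiles and the mean-threshold zone delineation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import raster_from_rows, standmap_from_types
from vertibelt.errors import ValidationError
from vertibelt.forest_typing import CONIFER, DECIDUOUS, MIXED
from vertibelt.zonation import (
    ElevationBinning,
    bin_proportions,
    delineate_zones,
    main_range,
    threshold,
)


def profile_from_pcts(pcts, forest_type=DECIDUOUS, origin=500.0, width=50.0):
    """Single-type long-format profile from a list of per-bin percentages."""
    rows = []
    for i, p in enumerate(pcts):
        for t in (DECIDUOUS, CONIFER, MIXED):
            rows.append(
                {
                    "bin_low_m": origin + i * width,
                    "bin_high_m": origin + (i + 1) * width,
                    "forest_type": t,
                    "area_pct": p if t == forest_type else 0.0,
                }
            )
    return pd.DataFrame(rows)


def test_bin_proportions_direct_count():
    dem = raster_from_rows([[510.0, 560.0, 560.0, 610.0]])
    stands = standmap_from_types([[CONIFER, CONIFER, DECIDUOUS, MIXED]])
    prof = bin_proportions(stands, dem, ElevationBinning(500.0, 50.0, 3))
    get = lambda low, t: prof[
        (prof["bin_low_m"] == low) & (prof["forest_type"] == t)
    ]["area_pct"].iloc[0]
    assert get(500.0, CONIFER) == 100.0
    assert get(550.0, CONIFER) == 50.0
    assert get(550.0, DECIDUOUS) == 50.0
    assert get(600.0, MIXED) == 100.0


def test_bin_proportions_nonforest_and_duplication_invariance():
    dem = raster_from_rows([[510.0, 560.0]])
    stands = standmap_from_types([["nonforest", "nonforest"]])
    prof = bin_proportions(stands, dem)
    assert (prof["area_pct"] == 0.0).all()

    dem1 = raster_from_rows([[510.0, 560.0, 560.0, 610.0]])
    types1 = [[CONIFER, CONIFER, DECIDUOUS, MIXED]]
    dem2 = raster_from_rows([[510.0, 560.0, 560.0, 610.0]] * 2)
    prof1 = bin_proportions(standmap_from_types(types1), dem1, ElevationBinning(500, 50, 3))
    prof2 = bin_proportions(standmap_from_types(types1 * 2), dem2, ElevationBinning(500, 50, 3))
    assert np.allclose(prof1["area_pct"], prof2["area_pct"])


def test_binning_covers_range_and_is_half_open():
    b = ElevationBinning.for_range(512.0, 700.0, 50.0)
    assert b.origin == 500.0
    assert b.edges[-1] >= 700.0
    assert b.index(550.0) == 1
    assert b.index(549.999) == 0


def test_main_range_scan_and_tie_breaks():
    prof = profile_from_pcts([2, 15, 30, 28, 3])
    assert main_range(prof, DECIDUOUS, floor_pct=10.0) == (550.0, 700.0)

    # uniform above floor -> whole profile
    prof2 = profile_from_pcts([20, 20, 20])
    assert main_range(prof2, DECIDUOUS, floor_pct=10.0) == (500.0, 650.0)

    # two equal-length runs: take the one with the higher maximum
    prof3 = profile_from_pcts([15, 18, 2, 30, 16, 2])
    assert main_range(prof3, DECIDUOUS, floor_pct=10.0) == (650.0, 750.0)
    # still tied -> lower elevation run
    prof4 = profile_from_pcts([15, 30, 2, 30, 15, 2])
    assert main_range(prof4, DECIDUOUS, floor_pct=10.0) == (500.0, 600.0)

    with pytest.raises(ValidationError):
        main_range(profile_from_pcts([1, 2, 3]), DECIDUOUS, floor_pct=50.0)


def test_threshold_is_unweighted_bin_mean():
    prof = profile_from_pcts([10, 30, 40, 20])
    assert threshold(prof, DECIDUOUS, (500.0, 700.0)) == pytest.approx(25.0)
    assert threshold(prof, DECIDUOUS, (500.0, 600.0)) == pytest.approx(20.0)

    rng = np.random.default_rng(9)
    pcts = rng.uniform(0, 100, size=16)
    prof16 = profile_from_pcts(list(pcts))
    assert threshold(prof16, DECIDUOUS, (500.0, 500.0 + 16 * 50)) == pytest.approx(
        sum(pcts) / 16
    )
    with pytest.raises(ValidationError):
        threshold(prof, DECIDUOUS, (100.0, 120.0))


def test_delineate_zones_scan_example():
    prof = profile_from_pcts([10, 30, 40, 20])
    entry = delineate_zones(prof, DECIDUOUS, (500.0, 700.0), 25.0)
    assert entry.core == (550.0, 650.0)
    assert entry.lower == (-math.inf, 550.0)
    assert entry.upper == (650.0, math.inf)
    # every elevation belongs to exactly one zone
    for z in (400.0, 550.0, 600.0, 650.0, 1000.0):
        zones = [entry.zone_of(z)]
        assert len(zones) == 1 and zones[0] in {"core", "upper", "lower"}


def test_delineate_zones_all_above_threshold():
    prof = profile_from_pcts([30, 40, 35])
    entry = delineate_zones(prof, DECIDUOUS, (500.0, 650.0), 25.0)
    assert entry.core == (500.0, 650.0)


def test_delineate_zones_outliers_and_errors():
    prof = profile_from_pcts([30, 10, 40, 35, 10])
    entry = delineate_zones(prof, DECIDUOUS, (500.0, 750.0), 25.0)
    assert entry.core == (600.0, 700.0)
    assert entry.outlier_bins == [500.0]
    with pytest.raises(ValidationError):
        delineate_zones(prof, DECIDUOUS, (500.0, 750.0), 90.0)


def test_delineate_zones_upper_support_flag():
    prof = profile_from_pcts([10, 30, 40, 20])
    entry = delineate_zones(prof, DECIDUOUS, (500.0, 700.0), 25.0, upper_support=2)
    assert entry.upper_empty
    entry2 = delineate_zones(prof, DECIDUOUS, (500.0, 700.0), 25.0, upper_support=5)
    assert not entry2.upper_empty


def test_taishan_shaped_deciduous_profile_recovers_core():
    """A unimodal profile super-threshold between 550 and 900 m yields the
    published core interval [550, 900)."""
    # bins 250..1050 (16 bins); percentages rise above 26.32 only in 550-900
    pcts = [13, 15, 18, 20, 22, 22, 30, 35, 39, 37, 32, 28, 26, 15, 13, 12]
    prof = profile_from_pcts(pcts, origin=250.0)
    thr = threshold(prof, DECIDUOUS, (250.0, 1050.0))
    entry = delineate_zones(prof, DECIDUOUS, (250.0, 1050.0), thr)
    assert entry.core == (550.0, 900.0)


def test_monotone_threshold_never_widens_core():
    pcts = [5, 20, 45, 60, 40, 15, 5]
    prof = profile_from_pcts(pcts)
    widths = []
    for thr in (10, 25, 35, 50):
        e = delineate_zones(prof, DECIDUOUS, (500.0, 850.0), thr)
        widths.append(e.core[1] - e.core[0])
    assert widths == sorted(widths, reverse=True)


def test_delineation_idempotent_on_core_restriction():
    pcts = [10, 30, 40, 20]
    prof = profile_from_pcts(pcts)
    e1 = delineate_zones(prof, DECIDUOUS, (500.0, 700.0), 25.0)
    e2 = delineate_zones(prof, DECIDUOUS, e1.core, 25.0)
    assert e2.core == e1.core
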
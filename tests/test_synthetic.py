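"""Synthetic mountain generator: determinism, bounds, ground-truth
consistency, and agreement between drawn stand maps and the truth curves."""

import numpy as np
import pytest

from vertibelt.errors import ConfigurationError, InputError
from vertibelt.forest_typing import (
    CONIFER,
    DECIDUOUS,
    FOREST_TYPES,
    MIXED,
    classify_stand,
    classify_stands,
    parse_composition,
)
from vertibelt.synthetic import (
    BeltParams,
    SyntheticConfig,
    generate_dem,
    generate_stand_map,
    generate_truth,
    occupancy_probabilities,
)
from vertibelt.zonation import ElevationBinning, bin_proportions


def test_noise_free_dem_is_a_cone_with_peak_at_center():
    cfg = SyntheticConfig(
        n_rows=101, n_cols=101, cell_size=25.0, base_elev=0.0, peak_elev=1500.0,
        roughness=0.0, seed=1,
    )
    dem = generate_dem(cfg)
    assert dem.values.max() == pytest.approx(1500.0)
    assert dem.values[50, 50] == pytest.approx(1500.0)
    # radially non-increasing along the central row
    row = dem.values[50, 50:]
    assert (np.diff(row) <= 1e-9).all()
    assert np.isfinite(dem.values).all()


def test_dem_determinism_and_three_sigma_bound():
    cfg = SyntheticConfig(n_rows=100, n_cols=100, cell_size=25.0, roughness=20.0, seed=7)
    a = generate_dem(cfg)
    b = generate_dem(cfg)
    assert np.array_equal(a.values, b.values)
    # independent scan against the 3-sigma bound
    assert a.values.min() >= cfg.base_elev - 3 * cfg.roughness
    assert a.values.max() <= cfg.peak_elev + 3 * cfg.roughness


@pytest.mark.parametrize(
    "field, value",
    [
        ("n_rows", 0),
        ("cell_size", -1.0),
        ("roughness", -5.0),
        ("nonforest_frac", 1.5),
        ("patch_scale", 0),
    ],
)
def test_invalid_config_names_offending_field(field, value):
    cfg = SyntheticConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=field):
        cfg.validate()


def test_invalid_belt_ordering_rejected():
    belts = {
        DECIDUOUS: BeltParams(1100.0, 150.0, 60.0, 40.0),
        CONIFER: BeltParams(700.0, 150.0, 60.0, 40.0),
        MIXED: BeltParams(1375.0, 75.0, 60.0, 40.0),
    }
    with pytest.raises(ConfigurationError, match="increase"):
        SyntheticConfig(belts=belts).validate()
    with pytest.raises(ConfigurationError, match="base_elev"):
        SyntheticConfig(base_elev=2000.0).validate()


def test_truth_probabilities_normalise_and_core_symmetry():
    cfg = SyntheticConfig()
    truth = generate_truth(cfg)
    z = np.linspace(0.0, 2000.0, 256)
    probs = truth.occupancy(z)
    total = sum(probs.values())
    assert np.allclose(total, 1.0, atol=1e-12)
    for t, belt in cfg.belts.items():
        lo, hi = truth.core_intervals[t]
        assert (lo + hi) / 2 == pytest.approx(belt.center_elev)
        assert hi - lo == pytest.approx(2 * belt.core_halfwidth)
        # truth interval matches the maximiser of the closed-form curve
        peak_z = z[np.argmax(probs[t])]
        assert lo - 60 <= peak_z <= hi + 60


def test_top_belt_occupancy_monotone_through_transition():
    cfg = SyntheticConfig().noise_free()
    top = cfg.belts[MIXED]
    z = np.linspace(
        top.center_elev - top.core_halfwidth - 300, top.center_elev, 200
    )
    p = occupancy_probabilities(cfg, z)[MIXED]
    assert (np.diff(p) >= -1e-12).all()


def test_stand_map_compositions_match_labels():
    cfg = SyntheticConfig(n_rows=80, n_cols=80, seed=3)
    dem = generate_dem(cfg)
    stands = generate_stand_map(cfg, dem)
    table = stands.attributes
    for comp_text in table["composition"]:
        comp = parse_composition(comp_text)
        if comp:
            assert sum(t for _, t in comp) == 10
    classified = classify_stands(stands)
    # the label implied by the composition is the label that was drawn:
    # dominant species consistent with the composition's top entry
    for _, row in classified.attributes.iterrows():
        comp = parse_composition(row["composition"])
        if comp:
            assert row["dominant_species"] == comp[0][0]


def test_stand_map_determinism_and_dimension_check():
    cfg = SyntheticConfig(n_rows=60, n_cols=60, seed=5)
    dem = generate_dem(cfg)
    a = generate_stand_map(cfg, dem)
    b = generate_stand_map(cfg, dem)
    assert np.array_equal(a.stand_id, b.stand_id)
    assert a.attributes.equals(b.attributes)
    other = generate_dem(SyntheticConfig(n_rows=50, n_cols=50, seed=5))
    with pytest.raises(InputError):
        generate_stand_map(cfg, other)


def test_all_nonforest_when_fraction_is_one():
    cfg = SyntheticConfig(n_rows=30, n_cols=30, nonforest_frac=1.0, seed=2)
    dem = generate_dem(cfg)
    stands = classify_stands(generate_stand_map(cfg, dem))
    assert (stands.attributes["forest_type"] == "nonforest").all()


def test_cell_at_conifer_center_is_conifer_without_patch_noise():
    """With aspect shifts off and per-cell patches, a stand drawn at the
    conifer belt centre has conifer tenths >= 7 whenever the conifer label
    was drawn; and the conifer label is the modal draw there."""
    cfg = SyntheticConfig().noise_free()
    center = cfg.belts[CONIFER].center_elev
    probs = occupancy_probabilities(cfg, np.array([center]))
    assert probs[CONIFER][0] == max(p[0] for p in probs.values())


def test_empirical_bin_proportions_match_truth_curves(small_synthetic):
    """Monte-Carlo agreement: drawn per-bin type shares sit within 5
    percentage points of the closed-form occupancy curves in well-populated
    bins."""
    cfg, dem, stands, truth = small_synthetic
    binning = ElevationBinning.for_range(*dem.finite_range())
    prof = bin_proportions(stands, dem, binning)
    centers = (prof["bin_low_m"] + prof["bin_high_m"]) / 2
    # restrict to bins with at least 400 cells
    big = prof["bin_area_m2"] >= 400 * cfg.cell_size**2
    # aspect shift mixes sunny/shady curves; bound using the shadier curve +- shift band
    for t in FOREST_TYPES:
        sel = (prof["forest_type"] == t) & big
        z = centers[sel].to_numpy()
        emp = prof.loc[sel, "area_pct"].to_numpy() / 100.0
        lo = np.minimum(
            truth.occupancy(z, sunny=False)[t], truth.occupancy(z, sunny=True)[t]
        )
        hi = np.maximum(
            truth.occupancy(z, sunny=False)[t], truth.occupancy(z, sunny=True)[t]
        )
        assert (emp >= lo - 0.05).all() and (emp <= hi + 0.05).all()
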
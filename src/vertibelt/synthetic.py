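"""Synthetic mountain landscapes with known vegetation ground truth.

Real DEMs and forest-inventory stand maps of the kind this package analyses
are rarely shareable, so the generator here builds a stand-in with an analytic
ground truth: a single-peak cone DEM with optional smoothed terrain noise, and
a stand map whose forest-type occupancy probabilities follow plateau-and-decay
"belt" curves of elevation, stacked bottom-to-top, shifted upward on sunny
slopes, and drawn patchwise to mimic stand polygons.

The occupancy model: each forest type t has weight

    w_t(z) = 1                                inside [center - hw, center + hw]
           = exp(-(edge distance)/decay)      outside (separate lower/upper decay)

plus a constant background weight w0 = f/(1-f) for non-forest cover fraction f.
Cell probabilities are the normalised weights, so they sum to one over
{3 types + nonforest}.  The truth core interval of type t is
[center - hw, center + hw] (for the unshifted, shady aspect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError
from .forest_typing import CONIFER, DECIDUOUS, FOREST_TYPES, MIXED, format_composition
from .grid import ElevationGrid, Raster, StandMap

BROADLEAF_CODES = ("QUE", "ROB")
CONIFER_CODES = ("PIN", "PLA", "LAR")


@dataclass(frozen=True)
class BeltParams:
    """One forest belt: plateau core plus exponential extension tails."""

    center_elev: float  # m, belt core centre (shady aspect)
    core_halfwidth: float  # m, half-width of the occupancy plateau
    lower_decay: float  # m, e-folding scale below the core
    upper_decay: float  # m, e-folding scale above the core
    aspect_shift: float = 0.0  # m, added to the centre on sunny cells


#: Default belt stack: three belts with bin-aligned cores separated by
#: ~100 m transition gaps, lower tails wider than upper tails.
DEFAULT_BELTS: dict[str, BeltParams] = {
    DECIDUOUS: BeltParams(700.0, 150.0, 60.0, 40.0, 30.0),
    CONIFER: BeltParams(1100.0, 150.0, 60.0, 40.0, 30.0),
    MIXED: BeltParams(1375.0, 75.0, 60.0, 40.0, 30.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic mountain and its vegetation belts."""

    n_rows: int = 500
    n_cols: int = 500
    cell_size: float = 25.0  # m
    base_elev: float = 150.0  # m, plain surrounding the mountain
    peak_elev: float = 1530.0  # m, summit
    roughness: float = 15.0  # m, std of smoothed terrain noise
    belts: dict[str, BeltParams] = field(default_factory=lambda: dict(DEFAULT_BELTS))
    patch_scale: int = 4  # cells, side of one stand patch
    nonforest_frac: float = 0.30  # background non-forest share
    seed: int = 20240513

    def validate(self) -> None:
        if self.n_rows <= 0:
            raise ConfigurationError("n_rows must be positive")
        if self.n_cols <= 0:
            raise ConfigurationError("n_cols must be positive")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if not self.base_elev < self.peak_elev:
            raise ConfigurationError("base_elev must be below peak_elev")
        if self.roughness < 0:
            raise ConfigurationError("roughness must be non-negative")
        if self.patch_scale < 1:
            raise ConfigurationError("patch_scale must be >= 1")
        if not 0.0 <= self.nonforest_frac <= 1.0:
            raise ConfigurationError("nonforest_frac must be in [0, 1]")
        if set(self.belts) != set(FOREST_TYPES):
            raise ConfigurationError(
                f"belts must define exactly the types {FOREST_TYPES}"
            )
        centers = [self.belts[t].center_elev for t in FOREST_TYPES]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ConfigurationError(
                "belts centers must strictly increase bottom-to-top"
            )
        for t, b in self.belts.items():
            for name in ("core_halfwidth", "lower_decay", "upper_decay"):
                if getattr(b, name) <= 0:
                    raise ConfigurationError(f"belts[{t}].{name} must be positive")

    def noise_free(self) -> "SyntheticConfig":
        """The deterministic-terrain variant used for ground-truth recovery:
        no terrain noise, per-cell patches, no aspect shift."""
        belts = {t: replace(b, aspect_shift=0.0) for t, b in self.belts.items()}
        return replace(self, roughness=0.0, patch_scale=1, belts=belts)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one synthetic landscape."""

    config: SyntheticConfig
    core_intervals: dict[str, tuple[float, float]]
    occupancy: Callable  # occupancy(z, sunny=False) -> dict label -> prob array
    seed: int

    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "seed": self.seed,
            "nonforest_frac": cfg.nonforest_frac,
            "core_intervals": {t: list(v) for t, v in self.core_intervals.items()},
            "belts": {
                t: {
                    "center_elev": b.center_elev,
                    "core_halfwidth": b.core_halfwidth,
                    "lower_decay": b.lower_decay,
                    "upper_decay": b.upper_decay,
                    "aspect_shift": b.aspect_shift,
                }
                for t, b in cfg.belts.items()
            },
        }


def _belt_weight(z: np.ndarray, belt: BeltParams, sunny) -> np.ndarray:
    center = belt.center_elev + np.where(sunny, belt.aspect_shift, 0.0)
    lo = center - belt.core_halfwidth
    hi = center + belt.core_halfwidth
    below = np.clip(lo - z, 0.0, None)
    above = np.clip(z - hi, 0.0, None)
    return np.exp(-below / belt.lower_decay - above / belt.upper_decay)


def occupancy_probabilities(
    config: SyntheticConfig, z, sunny=False
) -> dict[str, np.ndarray]:
    """Per-label occupancy probabilities at elevation(s) *z*.

    Normalised belt weights with a constant non-forest background; the
    returned probabilities sum to 1 over {forest types} + {'nonforest'}.
    """
    z = np.asarray(z, dtype=float)
    sunny = np.broadcast_to(np.asarray(sunny, dtype=bool), z.shape)
    if config.nonforest_frac >= 1.0:
        zero = np.zeros_like(z)
        return {**{t: zero.copy() for t in FOREST_TYPES}, "nonforest": zero + 1.0}
    w0 = config.nonforest_frac / (1.0 - config.nonforest_frac)
    weights = {t: _belt_weight(z, config.belts[t], sunny) for t in FOREST_TYPES}
    total = w0 + sum(weights.values())
    probs = {t: w / total for t, w in weights.items()}
    probs["nonforest"] = w0 / total
    return probs


def generate_dem(config: SyntheticConfig) -> ElevationGrid:
    """Cone mountain plus Gaussian-smoothed, 3-sigma-clipped terrain noise.

    Deterministic for a fixed seed; every elevation lies in
    [base_elev - 3*roughness, peak_elev + 3*roughness]; the global maximum sits
    at the grid centre; no nodata cells.
    """
    config.validate()
    n, m = config.n_rows, config.n_cols
    rows, cols = np.mgrid[0:n, 0:m]
    cy, cx = (n - 1) / 2.0, (m - 1) / 2.0
    r = np.hypot((cols - cx) * config.cell_size, (rows - cy) * config.cell_size)
    r_max = min(n, m) * config.cell_size / 2.0
    relief = config.peak_elev - config.base_elev
    dem = np.clip(config.peak_elev - relief * r / r_max, config.base_elev, None)

    if config.roughness > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        noise = rng.standard_normal((n, m))
        smooth = ndimage.gaussian_filter(noise, sigma=3.0, mode="reflect")
        std = smooth.std()
        if std > 0:
            smooth *= config.roughness / std
        dem = dem + np.clip(smooth, -3 * config.roughness, 3 * config.roughness)
    return Raster(dem.astype(float), config.cell_size)


def generate_truth(config: SyntheticConfig) -> TruthRecord:
    """The exact occupancy curves and core intervals behind the generator."""
    config.validate()
    cores = {
        t: (
            b.center_elev - b.core_halfwidth,
            b.center_elev + b.core_halfwidth,
        )
        for t, b in config.belts.items()
    }

    def occ(z, sunny=False):
        return occupancy_probabilities(config, z, sunny)

    return TruthRecord(config=config, core_intervals=cores, occupancy=occ, seed=config.seed)


def _draw_composition(label: str, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Composition tenths consistent with the drawn forest-type label."""
    if label == "nonforest":
        return []
    if label == DECIDUOUS:
        major = BROADLEAF_CODES[rng.integers(len(BROADLEAF_CODES))]
        minor = CONIFER_CODES[rng.integers(len(CONIFER_CODES))]
        tenths = int(rng.integers(7, 11))
    elif label == CONIFER:
        major = CONIFER_CODES[rng.integers(len(CONIFER_CODES))]
        minor = BROADLEAF_CODES[rng.integers(len(BROADLEAF_CODES))]
        tenths = int(rng.integers(7, 11))
    elif label == MIXED:
        # neither group reaches 7: broadleaf share in {4,5,6}
        b_tenths = int(rng.integers(4, 7))
        b_code = BROADLEAF_CODES[rng.integers(len(BROADLEAF_CODES))]
        c_code = CONIFER_CODES[rng.integers(len(CONIFER_CODES))]
        if b_tenths >= 5:
            return [(b_code, b_tenths), (c_code, 10 - b_tenths)]
        return [(c_code, 10 - b_tenths), (b_code, b_tenths)]
    else:  # pragma: no cover - labels are internal
        raise ValueError(f"unknown label {label!r}")
    if tenths == 10:
        return [(major, 10)]
    return [(major, tenths), (minor, 10 - tenths)]


def generate_stand_map(config: SyntheticConfig, dem: ElevationGrid) -> StandMap:
    """Draw a patchwise stand map over *dem* from the belt occupancy curves.

    Stand patches are ``patch_scale`` x ``patch_scale`` blocks of cells; each
    patch draws one forest-type label from the occupancy probabilities at its
    mean elevation and majority aspect class, then a species composition
    consistent with that label.  Deterministic for a fixed config seed.
    """
    import pandas as pd

    from .sampling import classify_aspect, compute_aspect

    config.validate()
    if dem.values.shape != (config.n_rows, config.n_cols):
        raise InputError(
            f"DEM shape {dem.values.shape} does not match config "
            f"({config.n_rows}, {config.n_cols})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    sunny = classify_aspect(compute_aspect(dem)) == "sunny"

    ps = config.patch_scale
    n, m = config.n_rows, config.n_cols
    nb_r = -(-n // ps)
    nb_c = -(-m // ps)

    # per-patch mean elevation and majority aspect
    patch_elev = np.zeros((nb_r, nb_c))
    patch_sunny = np.zeros((nb_r, nb_c), dtype=bool)
    for i in range(nb_r):
        for j in range(nb_c):
            block = np.s_[i * ps : min((i + 1) * ps, n), j * ps : min((j + 1) * ps, m)]
            patch_elev[i, j] = np.nanmean(dem.values[block])
            patch_sunny[i, j] = sunny[block].mean() >= 0.5

    probs = occupancy_probabilities(config, patch_elev.ravel(), patch_sunny.ravel())
    labels = list(FOREST_TYPES) + ["nonforest"]
    pmat = np.column_stack([probs[lab].ravel() for lab in labels])
    cum = np.cumsum(pmat, axis=1)
    u = rng.random(cum.shape[0])
    label_idx = (u[:, None] >= cum).sum(axis=1)

    records = []
    for sid, li in enumerate(label_idx):
        comp = _draw_composition(labels[li], rng)
        records.append(
            {
                "dominant_species": comp[0][0] if comp else "",
                "composition": format_composition(comp),
            }
        )
    attributes = pd.DataFrame(records)
    attributes.index.name = "stand_id"

    patch_ids = np.arange(nb_r * nb_c).reshape(nb_r, nb_c)
    stand_id = np.repeat(np.repeat(patch_ids, ps, axis=0), ps, axis=1)[:n, :m]
    return StandMap(stand_id, attributes, config.cell_size, dem.xll, dem.yll)
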
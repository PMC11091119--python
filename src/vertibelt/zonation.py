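"""Vertical-belt delineation from elevation-bin area proportions.

For each forest type the per-bin area percentage is profiled over fixed-width
elevation bins (default 50 m, left-closed right-open, edges at multiples of
the width).  The belt's *main range* is the longest contiguous run of bins at
or above a floor percentage; the *threshold* is the unweighted mean of the
per-bin percentages across that range; the *core zone* is the contiguous
super-threshold run containing the peak bin, and everything below/above the
core is the lower/upper extension zone (open-ended; clipped to the DEM range
only when reported).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ValidationError
from .forest_typing import FOREST_TYPES
from .grid import ElevationGrid, StandMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElevationBinning:
    """Left-closed right-open elevation bins [origin + i*width, ...)."""

    origin: float
    width: float = 50.0
    n_bins: int = 1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("bin width must be positive")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")

    @classmethod
    def for_range(
        cls, zmin: float, zmax: float, width: float = 50.0, origin: float | None = None
    ) -> "ElevationBinning":
        """Bins tiling [zmin, zmax]; origin defaults to floor(zmin/width)*width."""
        if origin is None:
            origin = math.floor(zmin / width) * width
        n_bins = max(1, math.floor((zmax - origin) / width) + 1)
        return cls(origin=origin, width=width, n_bins=n_bins)

    @property
    def edges(self) -> np.ndarray:
        return self.origin + self.width * np.arange(self.n_bins + 1)

    def index(self, z) -> np.ndarray:
        """Bin index of elevation(s); -1 outside the tiling."""
        idx = np.floor((np.asarray(z, dtype=float) - self.origin) / self.width)
        idx = idx.astype(int)
        return np.where((idx < 0) | (idx >= self.n_bins), -1, idx)


@dataclass
class ZoneEntry:
    """Core / upper / lower delineation for one forest type (metres)."""

    forest_type: str
    threshold_pct: float
    main_range: tuple[float, float]
    core: tuple[float, float]
    lower: tuple[float, float]  # (-inf, core_low)
    upper: tuple[float, float]  # (core_high, inf)
    upper_empty: bool = False
    outlier_bins: list[float] = field(default_factory=list)

    def zone_of(self, elevation: float) -> str:
        if self.core[0] <= elevation < self.core[1]:
            return "core"
        return "lower" if elevation < self.core[0] else "upper"


class ZoneScheme(dict):
    """Mapping forest_type -> ZoneEntry with YAML round-tripping."""

    def zone_of(self, forest_type: str, elevation: float) -> str:
        return self[forest_type].zone_of(elevation)

    def to_yaml(self, path) -> None:
        payload = {
            t: {
                "threshold_pct": round(float(e.threshold_pct), 4),
                "main_range": list(e.main_range),
                "core": list(e.core),
                "lower": ["-inf", e.lower[1]],
                "upper": [e.upper[0], "inf"],
                "upper_empty": bool(e.upper_empty),
                "outlier_bins": [float(b) for b in e.outlier_bins],
            }
            for t, e in self.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ZoneScheme":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        scheme = cls()
        for t, d in payload.items():
            core = tuple(float(v) for v in d["core"])
            scheme[t] = ZoneEntry(
                forest_type=t,
                threshold_pct=float(d["threshold_pct"]),
                main_range=tuple(float(v) for v in d["main_range"]),
                core=core,
                lower=(-math.inf, core[0]),
                upper=(core[1], math.inf),
                upper_empty=bool(d.get("upper_empty", False)),
                outlier_bins=[float(b) for b in d.get("outlier_bins", [])],
            )
        return scheme


def bin_proportions(
    stands: StandMap,
    dem: ElevationGrid,
    binning: ElevationBinning | None = None,
    type_column: str = "forest_type",
) -> pd.DataFrame:
    """Per-bin area percentage of each forest type.

    Returns a long-format frame (bin_low_m, bin_high_m, forest_type, area_pct,
    area_m2, bin_area_m2).  Percentages are relative to the total bin area, so
    the three forest types sum to <= 100 (remainder is non-forest).
    """
    if type_column not in stands.attributes.columns:
        raise InputError("stand map has no forest_type column; classify first")
    if stands.shape != dem.values.shape:
        raise InputError(
            f"stand map shape {stands.shape} does not match DEM {dem.values.shape}"
        )
    elev = dem.values.ravel()
    types = stands.cell_column(type_column, fill="nonforest").ravel()
    ok = np.isfinite(elev)
    elev, types = elev[ok], types[ok]
    if binning is None:
        binning = ElevationBinning.for_range(elev.min(), elev.max())

    idx = binning.index(elev)
    inside = idx >= 0
    idx, types = idx[inside], types[inside]
    totals = np.bincount(idx, minlength=binning.n_bins)

    edges = binning.edges
    cell_area = stands.cell_size**2
    rows = []
    for t in FOREST_TYPES:
        counts = np.bincount(idx[types == t], minlength=binning.n_bins)
        for b in range(binning.n_bins):
            pct = 100.0 * counts[b] / totals[b] if totals[b] else 0.0
            rows.append(
                {
                    "bin_low_m": edges[b],
                    "bin_high_m": edges[b + 1],
                    "forest_type": t,
                    "area_pct": pct,
                    "area_m2": counts[b] * cell_area,
                    "bin_area_m2": totals[b] * cell_area,
                }
            )
    empty = totals == 0
    if empty.any():
        log.info("bin_proportions: %d empty elevation bins", int(empty.sum()))
    return pd.DataFrame(rows)


def _type_profile(profile: pd.DataFrame, forest_type: str) -> pd.DataFrame:
    sub = profile[profile["forest_type"] == forest_type].sort_values("bin_low_m")
    if sub.empty:
        raise ValidationError(f"profile has no rows for type {forest_type!r}")
    return sub.reset_index(drop=True)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        if not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def main_range(
    profile: pd.DataFrame, forest_type: str, floor_pct: float = 10.0
) -> tuple[float, float]:
    """Longest contiguous run of bins with area_pct >= floor_pct.

    Ties go to the run containing the higher maximum percentage, then to the
    lower-elevation run.
    """
    sub = _type_profile(profile, forest_type)
    pct = sub["area_pct"].to_numpy()
    runs = _runs(pct >= floor_pct)
    if not runs:
        raise ValidationError(
            f"no elevation bin reaches floor {floor_pct}% for {forest_type!r}"
        )
    # longest run; tie-break on max pct; final tie-break: lowest elevation
    best = max(
        runs, key=lambda r: (r[1] - r[0], pct[r[0] : r[1] + 1].max(), -r[0])
    )
    return (
        float(sub["bin_low_m"].iloc[best[0]]),
        float(sub["bin_high_m"].iloc[best[1]]),
    )


def threshold(
    profile: pd.DataFrame, forest_type: str, elev_range: tuple[float, float]
) -> float:
    """Unweighted mean of the per-bin percentages across *elev_range*."""
    sub = _type_profile(profile, forest_type)
    sel = (sub["bin_low_m"] >= elev_range[0]) & (sub["bin_high_m"] <= elev_range[1])
    if not sel.any():
        raise ValidationError(f"range {elev_range} covers no bins")
    return float(sub.loc[sel, "area_pct"].mean())


def delineate_zones(
    profile: pd.DataFrame,
    forest_type: str,
    elev_range: tuple[float, float],
    threshold_pct: float,
    upper_support: int | None = None,
    min_points: int = 3,
) -> ZoneEntry:
    """Split elevations into core / upper / lower zones for one type.

    The core is the contiguous run of bins strictly above *threshold_pct*
    (within *elev_range*) that contains the maximum-percentage bin; all lower
    elevations form the lower extension, all higher the upper extension.
    Isolated super-threshold bins outside the core run are reported in
    ``outlier_bins`` with a logged warning.  If *upper_support* (a sample
    count above the core) is given and falls below *min_points*, the upper
    extension is flagged empty.
    """
    sub = _type_profile(profile, forest_type)
    sel = (sub["bin_low_m"] >= elev_range[0]) & (sub["bin_high_m"] <= elev_range[1])
    sub = sub[sel].reset_index(drop=True)
    if sub.empty:
        raise ValidationError(f"range {elev_range} covers no bins")
    pct = sub["area_pct"].to_numpy()
    above = pct > threshold_pct
    if not above.any():
        raise ValidationError(
            f"no bin exceeds threshold {threshold_pct}% for {forest_type!r}"
        )
    peak = int(np.argmax(pct))
    core_run = next(r for r in _runs(above) if r[0] <= peak <= r[1])
    outliers = [
        float(sub["bin_low_m"].iloc[i])
        for r in _runs(above)
        if r != core_run
        for i in range(r[0], r[1] + 1)
    ]
    if outliers:
        log.warning(
            "delineate_zones(%s): isolated super-threshold bins at %s m",
            forest_type,
            outliers,
        )
    core = (
        float(sub["bin_low_m"].iloc[core_run[0]]),
        float(sub["bin_high_m"].iloc[core_run[1]]),
    )
    upper_empty = upper_support is not None and upper_support < min_points
    return ZoneEntry(
        forest_type=forest_type,
        threshold_pct=float(threshold_pct),
        main_range=(float(elev_range[0]), float(elev_range[1])),
        core=core,
        lower=(-math.inf, core[0]),
        upper=(core[1], math.inf),
        upper_empty=upper_empty,
        outlier_bins=outliers,
    )


def build_zone_scheme(
    profile: pd.DataFrame,
    floor_pct: float = 10.0,
    overrides: dict | None = None,
) -> ZoneScheme:
    """Delineate all three forest types from one proportion profile.

    *overrides* may supply, per type, an explicit ``main_range`` and/or a fixed
    ``threshold_pct`` (the faithful mode for reproducing hand-chosen ranges).
    """
    overrides = overrides or {}
    scheme = ZoneScheme()
    for t in FOREST_TYPES:
        ov = overrides.get(t, {})
        rng = tuple(ov["main_range"]) if "main_range" in ov else main_range(
            profile, t, floor_pct
        )
        thr = ov.get("threshold_pct")
        if thr is None:
            thr = threshold(profile, t, rng)
        scheme[t] = delineate_zones(profile, t, rng, thr)
    return scheme
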
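"""Forest-type classification from species-composition tenths.

A stand's composition is recorded in the forestry convention of *tenths*: each
species' share of the stand, as an integer 0-10, with shares summing to exactly
10 (e.g. ``7QUE3PIN`` = seven tenths oak, three tenths pine).  A stand whose
broadleaf (resp. conifer) tenths reach the purity threshold (default 7) is a
deciduous broad-leaved (resp. temperate coniferous) stand; anything else is a
mixed coniferous-broadleaved stand.  Stands with an empty composition are
non-forest.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import ElevationGrid, StandMap

# Forest-type labels, ordered bottom belt -> top belt.
DECIDUOUS = "deciduous_broadleaf"
CONIFER = "temperate_conifer"
MIXED = "mixed"
NONFOREST = "nonforest"
FOREST_TYPES = (DECIDUOUS, CONIFER, MIXED)

#: Synthetic species vocabulary: 2 broadleaf + 3 conifer codes.
SPECIES_GROUPS: dict[str, str] = {
    "QUE": "broadleaf",  # oaks
    "ROB": "broadleaf",  # black locust
    "PIN": "conifer",  # pines
    "PLA": "conifer",  # arborvitae
    "LAR": "conifer",  # larches
}

#: Tenths at or above which one group makes the stand "pure".
PURE_THRESHOLD_TENTHS = 7

_TOKEN = re.compile(r"(10|[0-9])([A-Z]{3})")

Composition = Sequence[tuple[str, int]]


def parse_composition(text: str) -> list[tuple[str, int]]:
    """Parse a tenths-code composition string like ``"7QUE3PIN"``.

    Returns a list of ``(species_code, tenths)``.  The empty string denotes a
    non-forest stand and parses to an empty list.  Raises
    :class:`ValidationError` (with the failing position) on malformed input or
    when the tenths do not sum to 10.
    """
    if text == "":
        return []
    items: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None:
            raise ValidationError(
                f"malformed composition {text!r} at position {pos}"
            )
        items.append((match.group(2), int(match.group(1))))
        pos = match.end()
    total = sum(t for _, t in items)
    if total != 10:
        raise ValidationError(
            f"composition {text!r} tenths sum to {total}, expected 10"
        )
    return items


def format_composition(items: Composition) -> str:
    """Inverse of :func:`parse_composition`."""
    return "".join(f"{tenths}{code}" for code, tenths in items)


def classify_stand(
    composition: Composition,
    groups: Mapping[str, str] = SPECIES_GROUPS,
    pure_threshold: int = PURE_THRESHOLD_TENTHS,
) -> str:
    """Forest type of one stand from its composition tenths.

    Broadleaf tenths >= *pure_threshold* -> deciduous broad-leaved; conifer
    tenths >= *pure_threshold* -> temperate coniferous; otherwise mixed.  An
    empty composition is non-forest.
    """
    if len(composition) == 0:
        return NONFOREST
    total = 0
    tally = {"broadleaf": 0, "conifer": 0}
    for code, tenths in composition:
        group = groups.get(code)
        if group is None:
            raise ValidationError(f"unknown species code {code!r}")
        tally[group] += tenths
        total += tenths
    if total != 10:
        raise ValidationError(f"composition tenths sum to {total}, expected 10")
    if tally["broadleaf"] >= pure_threshold:
        return DECIDUOUS
    if tally["conifer"] >= pure_threshold:
        return CONIFER
    return MIXED


def classify_stands(
    stands: StandMap,
    groups: Mapping[str, str] = SPECIES_GROUPS,
    pure_threshold: int = PURE_THRESHOLD_TENTHS,
) -> StandMap:
    """Return a StandMap whose attribute table gains a ``forest_type`` column."""
    table = stands.attributes.copy()
    table["forest_type"] = [
        classify_stand(parse_composition(text), groups, pure_threshold)
        for text in table["composition"].astype(str).str.strip()
    ]
    return StandMap(stands.stand_id, table, stands.cell_size, stands.xll, stands.yll)


def dominant_species_profile(
    stands: StandMap,
    dem: ElevationGrid,
    bin_width: float = 50.0,
) -> pd.DataFrame:
    """Area percentage of each dominant species per elevation bin.

    Percentages are relative to the *total* bin area (forest plus non-forest),
    so the per-bin sum over species is at most 100.  Returns a long-format
    table (bin_low_m, bin_high_m, species, area_pct).
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if stands.shape != dem.values.shape:
        raise ValidationError(
            f"stand map shape {stands.shape} does not match DEM {dem.values.shape}"
        )
    elev = dem.values.ravel()
    dominant = stands.cell_column("dominant_species").ravel()
    ok = np.isfinite(elev)
    if not ok.any():
        import warnings

        warnings.warn("no finite elevations overlap the stand map")
        return pd.DataFrame(columns=["bin_low_m", "bin_high_m", "species", "area_pct"])
    elev, dominant = elev[ok], dominant[ok]

    lo = np.floor(elev.min() / bin_width) * bin_width
    idx = np.floor((elev - lo) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    totals = np.bincount(idx, minlength=n_bins)

    rows = []
    species = sorted({d for d in dominant if d})
    for sp in species:
        counts = np.bincount(idx[dominant == sp], minlength=n_bins)
        for b in range(n_bins):
            if totals[b] == 0:
                continue
            rows.append(
                {
                    "bin_low_m": lo + b * bin_width,
                    "bin_high_m": lo + (b + 1) * bin_width,
                    "species": sp,
                    "area_pct": 100.0 * counts[b] / totals[b],
                }
            )
    return pd.DataFrame(rows)
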
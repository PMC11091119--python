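"""Regular point-grid sampling and terrain stratification.

A regular grid of sample points (default spacing 200 m, half-spacing inset
from the lower-left extent corner) is dropped over the study area; each point
takes the elevation and forest type of its containing cell, an aspect class
(sunny = aspect in [112.5, 292.5) degrees clockwise from north; shady =
everything else, including flat cells), an elevation class (default edges
550 / 900 / 1100 / 1350 m, left-closed right-open), a terrain unit
(elevation class x aspect class), and the belt zone of its forest type.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError
from .grid import ElevationGrid, StandMap
from .zonation import ZoneScheme

log = logging.getLogger(__name__)

SUNNY_RANGE = (112.5, 292.5)  # degrees, left-closed right-open
DEFAULT_ELEV_CLASS_EDGES = (550.0, 900.0, 1100.0, 1350.0)
DEFAULT_FLAT_TOL = 1e-8  # elevation-units per metre


def make_grid(
    extent: tuple[float, float, float, float], spacing: float
) -> np.ndarray:
    """Regular point grid inside *extent* = (xmin, ymin, xmax, ymax).

    Points sit at (xmin + spacing/2 + i*spacing, ymin + spacing/2 + j*spacing)
    and all lie strictly inside the extent.
    """
    if spacing <= 0:
        raise InputError("spacing must be positive")
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise InputError("extent is degenerate")
    xs = np.arange(xmin + spacing / 2.0, xmax, spacing)
    ys = np.arange(ymin + spacing / 2.0, ymax, spacing)
    if xs.size == 0 or ys.size == 0:
        log.warning("spacing %.1f exceeds the extent; returning a single point", spacing)
        xs = np.array([(xmin + xmax) / 2.0])
        ys = np.array([(ymin + ymax) / 2.0])
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def extract_elevation(points: np.ndarray, dem: ElevationGrid) -> np.ndarray:
    """Containing-cell elevation for each (x, y) point.

    Points outside the footprint or on nodata cells get NaN; the count is
    logged so callers can drop them.
    """
    points = np.asarray(points, dtype=float)
    vals = dem.value_at(points[:, 0], points[:, 1])
    vals = np.asarray(vals, dtype=float)
    n_bad = int(np.sum(~np.isfinite(vals)))
    if n_bad:
        log.info("extract_elevation: dropped %d points (outside footprint or nodata)", n_bad)
    return vals


def compute_aspect(dem: ElevationGrid, flat_tol: float = DEFAULT_FLAT_TOL) -> np.ndarray:
    """Aspect grid in degrees clockwise from north; NaN marks flat cells.

    Horn's 8-neighbour finite differences on the 3x3 window; border cells use
    edge-replicated (one-sided) differences.  A cell is flat when its gradient
    magnitude is below *flat_tol*.
    """
    z = np.asarray(dem.values, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise InputError("DEM must be at least 3x3 to compute aspect")
    if not np.isfinite(z).any():
        raise InputError("DEM is entirely nodata")
    zp = np.pad(z, 1, mode="edge")
    c = dem.cell_size
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * c)  # toward east
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * c)  # toward north
    grad = np.hypot(dzdx, dzdy)
    # downslope azimuth, clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[grad < flat_tol] = np.nan
    aspect[~np.isfinite(z)] = np.nan
    return aspect


def classify_aspect(aspect_deg) -> np.ndarray:
    """'sunny' for aspect in [112.5, 292.5) degrees; 'shady' otherwise (incl. flat)."""
    a = np.asarray(aspect_deg, dtype=float)
    sunny = (a >= SUNNY_RANGE[0]) & (a < SUNNY_RANGE[1])
    return np.where(np.isfinite(a) & sunny, "sunny", "shady")


def elev_class_labels(edges=DEFAULT_ELEV_CLASS_EDGES) -> list[str]:
    edges = [f"{e:g}" for e in edges]
    labels = [f"<{edges[0]}"]
    labels += [f"{a}-{b}" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]}")
    return labels


def classify_elevation(elevation, edges=DEFAULT_ELEV_CLASS_EDGES) -> np.ndarray:
    """Elevation class per point, left-closed right-open at each edge."""
    labels = np.array(elev_class_labels(edges), dtype=object)
    idx = np.searchsorted(np.asarray(edges, dtype=float), np.asarray(elevation, dtype=float), side="right")
    return labels[idx]


def assign_units(
    points: pd.DataFrame,
    zone_scheme: ZoneScheme,
    elev_class_edges=DEFAULT_ELEV_CLASS_EDGES,
) -> pd.DataFrame:
    """Attach elev_class, unit_id and belt zone to an attributed point table.

    *points* must carry ``elevation_m``, ``aspect_class`` and ``forest_type``.
    The zone is looked up per point from its type's ZoneEntry; by the zone
    partition every elevation belongs to exactly one of core/upper/lower.
    """
    out = points.copy()
    out["elev_class"] = classify_elevation(out["elevation_m"].to_numpy(), elev_class_edges)
    out["unit_id"] = out["elev_class"].astype(str) + "|" + out["aspect_class"].astype(str)
    zones = []
    for t, z in zip(out["forest_type"], out["elevation_m"]):
        zones.append(zone_scheme.zone_of(t, z) if t in zone_scheme else "")
    out["zone"] = zones
    return out


def build_sample_table(
    dem: ElevationGrid,
    stands: StandMap,
    zone_scheme: ZoneScheme,
    spacing: float = 200.0,
    elev_class_edges=DEFAULT_ELEV_CLASS_EDGES,
    flat_tol: float = DEFAULT_FLAT_TOL,
) -> pd.DataFrame:
    """Full sample-point table: grid, extract, classify, stratify.

    Non-forest points and points without valid elevation are dropped (their
    counts are logged).  Columns: point_id, x, y, elevation_m, aspect_deg,
    aspect_class, forest_type, zone, elev_class, unit_id.
    """
    if "forest_type" not in stands.attributes.columns:
        raise InputError("stand map has no forest_type column; classify first")
    pts = make_grid(dem.extent, spacing)
    elev = extract_elevation(pts, dem)

    aspect_grid = compute_aspect(dem, flat_tol)
    aspect_raster = ElevationGrid(aspect_grid, dem.cell_size, dem.xll, dem.yll)
    # containing-cell lookups for aspect and stand id
    row, col = dem.cell_index(pts[:, 0], pts[:, 1])
    inside = (row >= 0) & (col >= 0)
    aspect = np.full(len(pts), np.nan)
    aspect[inside] = aspect_grid[row[inside], col[inside]]
    type_grid = stands.cell_column("forest_type", fill="nonforest")
    ftype = np.full(len(pts), "nonforest", dtype=object)
    ftype[inside] = type_grid[row[inside], col[inside]]

    table = pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "elevation_m": elev,
            "aspect_deg": aspect,
            "aspect_class": classify_aspect(aspect),
            "forest_type": ftype,
        }
    )
    n0 = len(table)
    table = table[np.isfinite(table["elevation_m"])]
    table = table[table["forest_type"].isin(zone_scheme.keys())]
    n_dropped = n0 - len(table)
    if n_dropped:
        log.info("build_sample_table: dropped %d non-forest/invalid points", n_dropped)
    table = table.reset_index(drop=True)
    table.insert(0, "point_id", np.arange(len(table)))
    return assign_units(table, zone_scheme, elev_class_edges)


def points_to_geojson(points: pd.DataFrame, path) -> None:
    """Write the sample-point table as a GeoJSON FeatureCollection."""
    import json

    feats = []
    for _, r in points.iterrows():
        props = {
            k: (None if (isinstance(v, float) and not np.isfinite(v)) else v)
            for k, v in r.items()
            if k not in ("x", "y")
        }
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r["x"], r["y"]]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, default=str)
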
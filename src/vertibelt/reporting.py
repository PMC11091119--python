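"""Report assembly: cloud-parameter tables, expectation differences, cloud
maps, and the config-driven end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cloud import MIN_POINTS, CloudParameters, fit_strata, forward_cloud
from .errors import InputError, ValidationError
from .forest_typing import FOREST_TYPES, classify_stands
from .grid import ElevationGrid, StandMap
from .sampling import build_sample_table, points_to_geojson
from .synthetic import (
    BeltParams,
    SyntheticConfig,
    generate_dem,
    generate_stand_map,
    generate_truth,
)
from .zonation import ElevationBinning, ZoneScheme, bin_proportions, build_zone_scheme

log = logging.getLogger(__name__)


def zone_cloud_table(
    points: pd.DataFrame, min_points: int = MIN_POINTS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cloud parameters per (forest type x belt zone) stratum + skip report."""
    return fit_strata(points, ["forest_type", "zone"], min_points=min_points)


def unit_cloud_table(
    points: pd.DataFrame, min_points: int = MIN_POINTS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cloud parameters per (elevation class x forest type x aspect) unit."""
    return fit_strata(
        points, ["elev_class", "forest_type", "aspect_class"], min_points=min_points
    )


def ex_differences(
    unit_table: pd.DataFrame, pair: tuple[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute Ex difference between two forest types per terrain unit.

    *unit_table* needs columns elev_class, forest_type, aspect_class, Ex_m.
    Returns ``(per_unit, summary)``: per-unit |Ex_a - Ex_b| rounded to 0.01 m
    (units missing either type are skipped), and a per-elevation-class min-max
    summary across aspect classes.  Symmetric in the pair.
    """
    type_a, type_b = pair
    if type_a == type_b:
        raise ValidationError("ex_differences requires two distinct forest types")
    rows = []
    for (elev_class, aspect_class), sub in unit_table.groupby(
        ["elev_class", "aspect_class"], sort=False
    ):
        ex = sub.set_index("forest_type")["Ex_m"]
        if type_a not in ex.index or type_b not in ex.index:
            continue
        rows.append(
            {
                "elev_class": elev_class,
                "aspect_class": aspect_class,
                "type_a": type_a,
                "type_b": type_b,
                "abs_Ex_diff_m": round(abs(float(ex[type_a]) - float(ex[type_b])), 2),
            }
        )
    per_unit = pd.DataFrame(
        rows, columns=["elev_class", "aspect_class", "type_a", "type_b", "abs_Ex_diff_m"]
    )
    if per_unit.empty:
        return per_unit, pd.DataFrame(
            columns=["elev_class", "min_abs_Ex_diff_m", "max_abs_Ex_diff_m"]
        )
    summary = (
        per_unit.groupby("elev_class", sort=False)["abs_Ex_diff_m"]
        .agg(min_abs_Ex_diff_m="min", max_abs_Ex_diff_m="max")
        .reset_index()
    )
    return per_unit, summary


def plot_cloud(
    droplets: pd.DataFrame,
    out_path: str | Path,
    title: str | None = None,
    ax=None,
) -> Path | None:
    """Scatter the cloud droplets (x in metres vs membership in [0, 1])."""
    if len(droplets) == 0:
        raise ValidationError("cannot plot an empty droplet set")
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.scatter(droplets["x_m"], droplets["membership"], s=3, alpha=0.4, lw=0)
    ax.set_ylim(0.0, 1.0)
    ax.set_xlabel("elevation (m)")
    ax.set_ylabel("membership")
    if title:
        ax.set_title(title, fontsize=9)
    if own_fig:
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return Path(out_path)
    return None


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------


def diff_frames_empty() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["elev_class", "aspect_class", "type_a", "type_b", "abs_Ex_diff_m"]
    )


def summary_frames_empty() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["elev_class", "min_abs_Ex_diff_m", "max_abs_Ex_diff_m", "type_a", "type_b"]
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def synthetic_config_from_dict(cfg: dict) -> SyntheticConfig:
    cfg = dict(cfg)
    belts = cfg.pop("belts", None)
    base = SyntheticConfig(**cfg) if belts is None else SyntheticConfig(
        belts={t: BeltParams(**b) for t, b in belts.items()}, **cfg
    )
    base.validate()
    return base


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> Path:
    """Execute simulate/load -> classify -> zonate -> sample -> cloud -> report.

    *seed* overrides the simulate and cloud seeds, for reproducible reruns.
    Writes all tables, the zone scheme, figures, and a run manifest into
    *outdir*; returns the output directory.  Any stage failure raises with the
    stage name in the message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        # --- inputs -------------------------------------------------------
        stage = "simulate/load"
        truth = None
        if "simulate" in config:
            sim_cfg = dict(config["simulate"])
            if seed is not None:
                sim_cfg["seed"] = seed
            synth = synthetic_config_from_dict(sim_cfg)
            dem = generate_dem(synth)
            stands = generate_stand_map(synth, dem)
            truth = generate_truth(synth)
            dem.write_ascii(outdir / "dem.asc")
            with open(outdir / "truth.yaml", "w") as fh:
                yaml.safe_dump(truth.to_dict(), fh, sort_keys=False)
        elif "inputs" in config:
            paths = config["inputs"]
            for key in ("dem", "stand_raster", "stand_attributes"):
                if key not in paths or not Path(paths[key]).exists():
                    raise InputError(f"missing input file for {key!r}: {paths.get(key)}")
            dem = ElevationGrid.read_ascii(paths["dem"])
            stands = StandMap.read(paths["stand_raster"], paths["stand_attributes"])
        else:
            raise InputError("config needs a 'simulate' or 'inputs' section")

        # --- classify -----------------------------------------------------
        stage = "classify"
        stands = classify_stands(stands)
        stands.write(outdir / "stand_id.asc", outdir / "stand_attributes.csv")

        # --- zonate -------------------------------------------------------
        stage = "zonate"
        bin_cfg = config.get("binning", {})
        zmin, zmax = dem.finite_range()
        binning = ElevationBinning.for_range(
            zmin, zmax, width=bin_cfg.get("width", 50.0), origin=bin_cfg.get("origin")
        )
        profile = bin_proportions(stands, dem, binning)
        profile.to_csv(outdir / "proportion_profile.csv", index=False)
        zone_cfg = config.get("zones", {})
        scheme = build_zone_scheme(
            profile,
            floor_pct=zone_cfg.get("floor_pct", 10.0),
            overrides=zone_cfg.get("overrides"),
        )
        scheme.to_yaml(outdir / "zones.yaml")

        # --- sample -------------------------------------------------------
        stage = "sample"
        sam_cfg = config.get("sampling", {})
        points = build_sample_table(
            dem,
            stands,
            scheme,
            spacing=sam_cfg.get("spacing", 200.0),
            elev_class_edges=tuple(
                sam_cfg.get("elev_class_edges", (550.0, 900.0, 1100.0, 1350.0))
            ),
        )
        points.to_csv(outdir / "sample_points.csv", index=False)
        points_to_geojson(points, outdir / "sample_points.geojson")

        # --- cloud --------------------------------------------------------
        stage = "cloud"
        cloud_cfg = config.get("cloud", {})
        min_points = cloud_cfg.get("min_points", MIN_POINTS)
        zone_params, zone_skips = zone_cloud_table(points, min_points)
        unit_params, unit_skips = unit_cloud_table(points, min_points)
        zone_params.to_csv(outdir / "zone_cloud_parameters.csv", index=False)
        unit_params.to_csv(outdir / "unit_cloud_parameters.csv", index=False)
        pd.concat([zone_skips, unit_skips]).to_csv(
            outdir / "skipped_strata.csv", index=False
        )

        # --- report -------------------------------------------------------
        stage = "report"
        rep_cfg = config.get("report", {})
        pairs = rep_cfg.get(
            "pairs",
            [[FOREST_TYPES[0], FOREST_TYPES[2]], [FOREST_TYPES[1], FOREST_TYPES[2]]],
        )
        diff_frames, summary_frames = [], []
        for pair in pairs:
            per_unit, summary = ex_differences(unit_params, tuple(pair))
            if len(per_unit):
                diff_frames.append(per_unit)
            if len(summary):
                summary_frames.append(summary.assign(type_a=pair[0], type_b=pair[1]))
        diffs = pd.concat(diff_frames) if diff_frames else diff_frames_empty()
        diffs.to_csv(outdir / "ex_differences.csv", index=False)
        summaries = (
            pd.concat(summary_frames) if summary_frames else summary_frames_empty()
        )
        summaries.to_csv(outdir / "ex_differences_summary.csv", index=False)

        if rep_cfg.get("figures", True) and len(zone_params):
            m = cloud_cfg.get("droplets", 2000)
            droplet_seed = cloud_cfg.get("seed", seed or 0)
            fig, axes = plt.subplots(
                len(zone_params), 1, figsize=(6, 2.4 * len(zone_params)), squeeze=False
            )
            for i, (_, row) in enumerate(zone_params.iterrows()):
                params = CloudParameters(
                    ex=row["Ex_m"], en=row["En_m"], he=row["He_m"], n=int(row["n"])
                )
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(droplet_seed) % 2**31, i])
                )
                drops = forward_cloud(params, m, rng)
                plot_cloud(
                    drops,
                    out_path=None,
                    title=f"{row['forest_type']} / {row['zone']}"
                    f"  (Ex={row['Ex_m']:.1f} m, En={row['En_m']:.1f} m, He={row['He_m']:.1f} m)",
                    ax=axes[i, 0],
                )
            fig.tight_layout()
            fig.savefig(outdir / "cloud_models.png", dpi=120)
            plt.close(fig)

        stage = "manifest"
        manifest = {
            "config_hash": _config_hash(config),
            "seed": seed if seed is not None else config.get("simulate", {}).get("seed"),
            "versions": {
                "vertibelt": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:  # annotate which stage failed, then re-raise
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    return outdir
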
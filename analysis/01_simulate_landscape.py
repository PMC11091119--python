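"""Generate the study landscape: a 500x500-cell synthetic mountain (25 m
cells, 150-1530 m relief) with three stacked forest belts, and persist the
DEM, stand map and generator ground truth under results/landscape/."""

from pathlib import Path

import yaml

from vertibelt.synthetic import SyntheticConfig, generate_dem, generate_stand_map, generate_truth

SEED = 20240513
OUT = Path(__file__).resolve().parent.parent / "results" / "landscape"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    dem = generate_dem(cfg)
    stands = generate_stand_map(cfg, dem)
    truth = generate_truth(cfg)

    dem.write_ascii(OUT / "dem.asc")
    stands.write(OUT / "stand_id.asc", OUT / "stand_attributes.csv")
    with open(OUT / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=False)

    zmin, zmax = dem.finite_range()
    print(f"DEM: {cfg.n_rows}x{cfg.n_cols} cells at {cfg.cell_size} m, "
          f"elevations {zmin:.0f}-{zmax:.0f} m")
    print(f"stands: {len(stands.attributes)} patches "
          f"({cfg.patch_scale}x{cfg.patch_scale} cells each)")
    for t, (lo, hi) in truth.core_intervals.items():
        print(f"  truth core {t}: [{lo:.0f}, {hi:.0f}] m")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
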
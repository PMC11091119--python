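"""Fit the backward cloud generator per (forest type x zone) stratum and per
terrain analysis unit, draw forward-generator cloud maps for the zone
strata, and write the parameter tables under results/."""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from vertibelt.cloud import CloudParameters, forward_cloud
from vertibelt.reporting import plot_cloud, unit_cloud_table, zone_cloud_table

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20240513


def main() -> None:
    points = pd.read_csv(BASE / "sample_points.csv")

    zone_params, zone_skips = zone_cloud_table(points)
    unit_params, unit_skips = unit_cloud_table(points)
    zone_params.to_csv(BASE / "zone_cloud_parameters.csv", index=False)
    unit_params.to_csv(BASE / "unit_cloud_parameters.csv", index=False)
    pd.concat([zone_skips, unit_skips]).to_csv(BASE / "skipped_strata.csv", index=False)

    print("cloud parameters per belt zone (m):")
    print(
        zone_params.assign(
            Ex_m=zone_params["Ex_m"].round(2),
            En_m=zone_params["En_m"].round(2),
            He_m=zone_params["He_m"].round(2),
        ).to_string(index=False)
    )
    if len(zone_skips) + len(unit_skips):
        print(f"{len(zone_skips) + len(unit_skips)} strata skipped (n < 3)")

    fig, axes = plt.subplots(
        len(zone_params), 1, figsize=(6, 2.2 * len(zone_params)), squeeze=False
    )
    for i, (_, row) in enumerate(zone_params.iterrows()):
        p = CloudParameters(ex=row["Ex_m"], en=row["En_m"], he=row["He_m"], n=int(row["n"]))
        rng = np.random.default_rng(np.random.SeedSequence([SEED, i]))
        plot_cloud(
            forward_cloud(p, 2000, rng),
            out_path=None,
            title=f"{row['forest_type']} / {row['zone']}",
            ax=axes[i, 0],
        )
    fig.tight_layout()
    fig.savefig(BASE / "cloud_models.png", dpi=120)
    print(f"wrote parameter tables and {BASE/'cloud_models.png'}")


if __name__ == "__main__":
    main()
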
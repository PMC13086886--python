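"""Current impact status of existing MCAs: zonal CI statistics, Jenks
low/medium/high impact classes, ANOVA against the regional mean, and the
kernel-density overlap between the MCA network's CI distribution and the
full region's.

Reads results/seascape/ and results/ci/; writes results/mca_status/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cimnet import (
    CIRaster,
    assign_class,
    compare_mca_to_region,
    distribution_overlap,
    extract_cells,
    filter_mcas,
    jenks_breaks,
    merge_zones,
    rasterize_footprint,
    summarize_mca,
)
from cimnet import io as cio
from cimnet.synthetic import RegionGrid, _coast_distance

SEASCAPE = Path("results/seascape")
CI_DIR = Path("results/ci")
OUT = Path("results/mca_status")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sea = cio.read_raster(SEASCAPE / "sea_mask.asc")[0].astype(bool)
    region = RegionGrid(*sea.shape, sea_mask=sea, coast_distance=_coast_distance(sea))
    ci = CIRaster(cio.read_raster(CI_DIR / "ci.asc")[0])
    records = cio.read_mcas(SEASCAPE / "mcas.geojson")

    merged = merge_zones(records)
    kept = filter_mcas(merged, governance_allow={"federal", "joint"}, min_area=1.0)
    print(f"MCA records: {len(records)} zones -> {len(merged)} merged MCAs -> "
          f"{len(kept)} kept (federal/joint governance, area >= 1 km^2)")

    region_values = ci.ci[sea]
    breaks = jenks_breaks(region_values, 3)
    print("Jenks class bounds (right-closed): "
          f"Low <= {breaks.boundaries[0]:.2f} < Medium <= {breaks.boundaries[1]:.2f} "
          f"< High <= {breaks.data_max:.2f}")

    rows = []
    masks = {}
    for rec in kept:
        vals = extract_cells(ci, rec, region)
        masks[rec.mca_id] = rasterize_footprint(region, rec.footprint)
        s = summarize_mca(rec.mca_id, vals, rec.footprint.area)
        cmp_res = compare_mca_to_region(s.cell_values, region_values)
        rows.append(
            {
                "mca_id": s.mca_id,
                "status": rec.status,
                "n_cells": s.n_cells,
                "area_km2": round(s.area, 2),
                "mean_ci": s.mean_ci,
                "ci95": s.ci95_halfwidth,
                "impact_class": assign_class(s.mean_ci, breaks),
                "F": cmp_res.F,
                "p": cmp_res.p,
                "direction": cmp_res.direction,
            }
        )
    table = pd.DataFrame(rows).sort_values("mean_ci", ascending=False)
    table.to_csv(OUT / "mca_status.csv", index=False)

    existing = table[table["status"] == "existing"]
    net_cells = np.concatenate(
        [ci.ci[masks[m]] for m in existing["mca_id"]]
    )
    ov = distribution_overlap(net_cells, region_values)
    with open(OUT / "overlap.json", "w") as fh:
        json.dump({"total_overlap_pct": ov.overlap_pct, "method": ov.method}, fh, indent=2)

    print(f"existing MCAs: {len(existing)}; "
          f"{(existing['direction'] == 'above').sum()} significantly above the "
          f"regional mean, {(existing['direction'] == 'below').sum()} below")
    print(f"impact classes among existing MCAs: "
          f"{existing['impact_class'].value_counts().to_dict()}")
    print(f"CI distribution overlap, existing-MCA network vs region: "
          f"{ov.overlap_pct:.1f}%")
    print(table.head(8).to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
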
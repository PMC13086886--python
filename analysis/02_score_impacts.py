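"""Score cumulative impacts: per-activity impact scores, the additive CI
raster, and the per-sector decomposition.

Reads the seascape written by 01_simulate_seascape.py and writes the CI
raster, per-sector rasters and a per-sector share table to results/ci/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cimnet import cumulative_impact, impact_scores, sector_decompose
from cimnet import io as cio

IN = Path("results/seascape")
OUT = Path("results/ci")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stressors, _ = cio.read_raster_stack(IN / "stressors.csv", kind="stressor")
    habitats, _ = cio.read_raster_stack(IN / "habitats.csv", kind="habitat")
    vuln = cio.read_vulnerability(IN / "vulnerability.csv")
    sea = cio.read_raster(IN / "sea_mask.asc")[0].astype(bool)

    cube = impact_scores(stressors, habitats, vuln)
    ci = cumulative_impact(cube)
    cio.write_raster(OUT / "ci.asc", ci.ci)

    rasters, _ = sector_decompose(cube)
    rows = []
    total = ci.ci[sea].sum()
    for sector, ras in rasters.items():
        cio.write_raster(OUT / f"ci_{sector.lower()}.asc", ras.ci)
        rows.append(
            {"sector": sector, "share_of_regional_ci": ras.ci[sea].sum() / total}
        )
    shares = pd.DataFrame(rows).sort_values("share_of_regional_ci", ascending=False)
    shares.to_csv(OUT / "sector_shares.csv", index=False)

    print(f"regional mean CI over {sea.sum()} sea cells: {ci.ci[sea].mean():.2f} "
          f"(max {ci.ci[sea].max():.2f})")
    print("sector shares of regional CI:")
    print(shares.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
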
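"""Generate the synthetic study seascape and write every input layer.

A 64x64 (1 km^2 cells) region with ~25% land, 45 stressor layers across
the five sectors (Climate, Fishing, Marine, Coastal, Land), 24 binary
habitat layers whose union covers the sea, a sparse habitat x stressor
vulnerability matrix, and 20 MCAs (mixed governance, one multi-zone, one
sub-km^2). Outputs land in results/seascape/.
"""

from pathlib import Path

from cimnet import io as cio
from cimnet.synthetic import (
    default_sector_configs,
    make_region,
    simulate_habitats,
    simulate_mcas,
    simulate_stressors,
    simulate_vulnerability,
)

SEED = 42
OUT = Path("results/seascape")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    region = make_region(64, 64, 0.25, SEED)
    stressors = simulate_stressors(region, default_sector_configs(), SEED + 1)
    habitats = simulate_habitats(region, 24, 0.25, SEED + 2)
    vuln = simulate_vulnerability(24, len(stressors), 0.3, SEED + 3)
    vuln = vuln.__class__(
        vuln.weights.set_axis([s.activity_id for s in stressors], axis=1)
        .set_axis([h.habitat_id for h in habitats], axis=0)
    )
    mcas = simulate_mcas(region, 20, SEED + 4)

    srows, hrows = [], []
    for s in stressors:
        path = f"stressor_{s.activity_id}.asc"
        cio.write_raster(OUT / path, s.intensity)
        srows.append({"id": s.activity_id, "sector": s.sector, "path": path})
    for h in habitats:
        path = f"habitat_{h.habitat_id}.asc"
        cio.write_raster(OUT / path, h.presence)
        hrows.append({"id": h.habitat_id, "path": path})
    cio.write_layer_manifest(OUT / "stressors.csv", srows)
    cio.write_layer_manifest(OUT / "habitats.csv", hrows)
    cio.write_vulnerability(OUT / "vulnerability.csv", vuln)
    cio.write_mcas(OUT / "mcas.geojson", mcas)
    cio.write_raster(OUT / "sea_mask.asc", region.sea_mask.astype(float))

    n_sea = region.n_sea
    print(f"region: 64x64, {n_sea} sea cells ({n_sea / 4096:.0%} of grid)")
    print(f"stressors: {len(stressors)} layers; habitats: {len(habitats)}")
    print(f"MCA zones: {len(mcas)} ({len({m.mca_id for m in mcas})} distinct MCAs)")
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
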
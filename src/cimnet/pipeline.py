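"""End-to-end workflow: seascape -> CI scoring -> MCA overlay ->
classification/representativeness -> protection-standard scenario.

Configuration is a plain mapping (YAML on disk). Inputs either come from
the synthetic generator (``simulate`` section) or from files (``inputs``
section with layer manifests, vulnerability CSV and MCA GeoJSON). Every
stage's products are written under ``out_dir`` together with a
provenance JSON carrying the config hash and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .classify import (
    assign_class,
    compare_mca_to_region,
    distribution_overlap,
    jenks_breaks,
)
from .engine import CIRaster, cumulative_impact, impact_scores, sector_decompose
from .overlay import (
    extract_cells,
    filter_mcas,
    merge_zones,
    rasterize_footprint,
    summarize_mca,
)
from .scenario import (
    ScenarioSpec,
    apply_scenario,
    mca_decline,
    network_summary,
    percent_decline_cell,
    protection_potential,
)
from .synthetic import (
    RegionGrid,
    _coast_distance,
    default_sector_configs,
    make_region,
    simulate_habitats,
    simulate_mcas,
    simulate_stressors,
    simulate_vulnerability,
)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def demo_config(seed: int = 42, out_dir: str = "results/demo") -> dict:
    """The shipped 64x64 synthetic demo configuration.

    45 stressor layers across five sectors, 24 habitats, 20 MCAs; the
    scenario removes four fishing activities plus one marine activity
    (the synthetic analogue of bottom-contact gear plus disposal at sea)
    from inside all existing and proposed MCA footprints.
    """
    return {
        "simulate": {
            "rows": 64,
            "cols": 64,
            "land_fraction": 0.25,
            "n_habitats": 24,
            "mean_coverage": 0.25,
            "vulnerability_sparsity": 0.3,
            "n_mcas": 20,
        },
        "k_classes": 3,
        "alpha": 0.05,
        "min_area_km2": 1.0,
        "governance_allow": ["federal", "joint"],
        "scenario": {
            "name": "protection_standard",
            "prohibited_activities": [
                "fishing_00",
                "fishing_01",
                "fishing_02",
                "fishing_03",
                "marine_00",
            ],
        },
        "seed": seed,
        "out_dir": out_dir,
    }


def validate_config(config: dict) -> None:
    if config.get("k_classes", 3) < 2:
        raise ValueError("k_classes must be >= 2")
    alpha = config.get("alpha", 0.05)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if "simulate" not in config and "inputs" not in config:
        raise ValueError("config needs a 'simulate' or 'inputs' section")
    if "inputs" in config:
        for key, path in config["inputs"].items():
            if not Path(path).exists():
                raise FileNotFoundError(f"inputs.{key}: {path} does not exist")


def _load_inputs(config: dict):
    if "simulate" in config:
        sim = config["simulate"]
        seed = int(config.get("seed", 0))
        region = make_region(sim["rows"], sim["cols"], sim["land_fraction"], seed)
        stressors = simulate_stressors(region, default_sector_configs(), seed + 1)
        habitats = simulate_habitats(
            region, sim["n_habitats"], sim["mean_coverage"], seed + 2
        )
        vuln = simulate_vulnerability(
            sim["n_habitats"],
            len(stressors),
            sim.get("vulnerability_sparsity", 0.3),
            seed + 3,
        )
        # the generic generator ids are positional; align them to the layers
        vuln = vuln.__class__(
            vuln.weights.set_axis([s.activity_id for s in stressors], axis=1).set_axis(
                [h.habitat_id for h in habitats], axis=0
            )
        )
        mcas = simulate_mcas(region, sim["n_mcas"], seed + 4)
        return region, stressors, habitats, vuln, mcas
    inputs = config["inputs"]
    stressors, _ = cio.read_raster_stack(inputs["stressor_manifest"], kind="stressor")
    habitats, _ = cio.read_raster_stack(inputs["habitat_manifest"], kind="habitat")
    vuln = cio.read_vulnerability(inputs["vulnerability"])
    mcas = cio.read_mcas(inputs["mcas"])
    # region grid recovered from the loaded layers: sea = habitat union
    presence = np.zeros(habitats[0].presence.shape, dtype=bool)
    for h in habitats:
        presence |= h.presence.astype(bool)
    region = RegionGrid(
        n_rows=presence.shape[0],
        n_cols=presence.shape[1],
        sea_mask=presence,
        coast_distance=_coast_distance(presence),
    )
    return region, stressors, habitats, vuln, mcas


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns a results dict and writes products.

    Stops after classification when the config has no ``scenario``
    section. Deterministic given config + seed.
    """
    validate_config(config)
    out = Path(out_dir or config.get("out_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with the stage
                (out / "failed_stage.txt").write_text(f"{name}: {exc}\n")
                raise PipelineError(name, exc) from exc

        return deco

    region, stressors, habitats, vuln, mca_records = stage("inputs")(
        lambda: _load_inputs(config)
    )
    results["n_stressors"] = len(stressors)
    results["n_habitats"] = len(habitats)
    results["n_mca_records"] = len(mca_records)

    def _score():
        cube = impact_scores(stressors, habitats, vuln)
        ci = cumulative_impact(cube)
        sector_rasters, sector_props = sector_decompose(cube)
        cio.write_raster(out / "ci.asc", ci.ci)
        for sec, ras in sector_rasters.items():
            cio.write_raster(out / f"ci_{sec.lower()}.asc", ras.ci)
        return cube, ci, sector_rasters

    cube, ci, sector_rasters = stage("score")(_score)
    region_values = ci.ci[region.sea_mask]
    results["regional_mean_ci"] = float(region_values.mean())

    def _overlay():
        merged = merge_zones(mca_records)
        kept = filter_mcas(
            merged,
            governance_allow=set(config.get("governance_allow", ["federal", "joint"])),
            min_area=float(config.get("min_area_km2", 1.0)),
        )
        excluded = [m.mca_id for m in merged if m.mca_id not in {k.mca_id for k in kept}]
        summaries = []
        masks = {}
        for rec in kept:
            vals = extract_cells(ci, rec, region)
            summaries.append(summarize_mca(rec.mca_id, vals, rec.footprint.area))
            masks[rec.mca_id] = rasterize_footprint(region, rec.footprint)
        return kept, summaries, masks, excluded

    kept, summaries, masks, excluded = stage("overlay")(_overlay)
    status_of = {r.mca_id: r.status for r in kept}
    existing = [s for s in summaries if status_of[s.mca_id] == "existing"]
    results["n_mcas_kept"] = len(kept)
    results["n_mcas_excluded"] = len(excluded)
    results["n_existing"] = len(existing)

    def _classify():
        breaks = jenks_breaks(region_values, int(config.get("k_classes", 3)))
        alpha = float(config.get("alpha", 0.05))
        rows = []
        for s in existing:
            cmp_res = compare_mca_to_region(s.cell_values, region_values, alpha=alpha)
            rows.append(
                {
                    "mca_id": s.mca_id,
                    "n_cells": s.n_cells,
                    "area_km2": s.area,
                    "mean_ci": s.mean_ci,
                    "ci95": s.ci95_halfwidth,
                    "impact_class": assign_class(s.mean_ci, breaks),
                    "F": cmp_res.F,
                    "p": cmp_res.p,
                    "direction": cmp_res.direction,
                }
            )
        table = pd.DataFrame(rows)
        table.to_csv(out / "mca_classification.csv", index=False)
        with open(out / "class_breaks.json", "w") as fh:
            json.dump(
                {
                    "k": breaks.k,
                    "boundaries": list(breaks.boundaries),
                    "data_min": breaks.data_min,
                    "data_max": breaks.data_max,
                },
                fh,
                indent=2,
            )
        # representativeness: MCA-network cells vs full region
        if existing:
            net_cells = np.concatenate([s.cell_values for s in existing])
            ov = distribution_overlap(net_cells, region_values)
            overlap = {"total": ov.overlap_pct}
            for sec, ras in sector_rasters.items():
                sec_region = ras.ci[region.sea_mask]
                sec_net = np.concatenate(
                    [ras.ci[masks[s.mca_id]] for s in existing]
                )
                overlap[sec] = distribution_overlap(sec_net, sec_region).overlap_pct
        else:
            overlap = {}
        with open(out / "overlap.json", "w") as fh:
            json.dump(overlap, fh, indent=2)
        return breaks, table, overlap

    breaks, class_table, overlap = stage("classify")(_classify)
    results["class_breaks"] = list(breaks.boundaries)
    results["overlap_pct"] = overlap
    if len(class_table):
        results["n_above"] = int((class_table["direction"] == "above").sum())
        results["n_below"] = int((class_table["direction"] == "below").sum())
        results["class_counts"] = class_table["impact_class"].value_counts().to_dict()

    cio.write_provenance(out / "provenance.json", config, seed)
    if "scenario" not in config:
        return results

    def _scenario():
        sc = config["scenario"]
        spec = ScenarioSpec(
            name=sc.get("name", "scenario"),
            prohibited_activities=frozenset(sc["prohibited_activities"]),
            target_mcas=frozenset(sc["target_mcas"]) if "target_mcas" in sc else None,
        )
        cube_after = apply_scenario(cube, spec, masks)
        ci_after = cumulative_impact(cube_after)
        cell_pct = percent_decline_cell(ci, ci_after)
        cio.write_raster(out / "cell_pct_decline.asc", cell_pct)
        declines = {}
        current_mean = {}
        for s in summaries:
            mask = masks[s.mca_id]
            declines[s.mca_id] = mca_decline(ci.ci[mask], ci_after.ci[mask])
            current_mean[s.mca_id] = s.mean_ci
        net = network_summary(declines, cell_pct, masks)
        pp = protection_potential(
            {m: (current_mean[m], declines[m]) for m in declines}
        )
        pp_table = pd.DataFrame(
            [
                {
                    "mca_id": p.mca_id,
                    "status": status_of[p.mca_id],
                    "current_mean_ci": p.current_mean_ci,
                    "pct_decline": p.pct_decline,
                    "label": p.label,
                    "median_ci": p.median_ci,
                    "median_decline": p.median_decline,
                }
                for p in pp
            ]
        )
        pp_table.to_csv(out / "scenario_mcas.csv", index=False)
        with open(out / "network_summary.json", "w") as fh:
            json.dump(
                {
                    "scenario": spec.name,
                    "n_mcas": net.n_mcas,
                    "mean_pct_decline": net.mean_pct_decline,
                    "min_pct_decline": net.min_pct_decline,
                    "max_pct_decline": net.max_pct_decline,
                    "n_zero_change": net.n_zero_change,
                    "n_mcas_with_cell_over_50": net.n_mcas_with_cell_over_50,
                    "max_cell_pct_decline": net.max_cell_pct_decline,
                    "n_high_potential": sum(p.label == "high_potential" for p in pp),
                },
                fh,
                indent=2,
            )
        return net, pp

    net, pp = stage("scenario")(_scenario)
    results["network_mean_pct_decline"] = net.mean_pct_decline
    results["network_max_pct_decline"] = net.max_pct_decline
    results["n_zero_change"] = net.n_zero_change
    results["n_mcas_with_cell_over_50"] = net.n_mcas_with_cell_over_50
    results["max_cell_pct_decline"] = net.max_cell_pct_decline
    results["n_high_potential"] = sum(p.label == "high_potential" for p in pp)
    return results
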
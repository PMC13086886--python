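"""Readers and writers for the pipeline's file formats.

Rasters are ESRI ASCII grids (.asc) on the shared grid convention:
row-major, origin top-left, half-open 1 km cells, coordinates in grid
units (x = column, y = row). Vector MCA footprints are GeoJSON
FeatureCollections in the same grid coordinates. Tabular products are
CSV; configuration is YAML; summaries and provenance are JSON.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .engine import HabitatLayer, StressorLayer, VulnerabilityMatrix
from .overlay import MCARecord

_NODATA = -9999.0


# ---------------------------------------------------------------------------
# rasters


def write_raster(path, grid: np.ndarray) -> None:
    """Write a 2D array as an ESRI ASCII grid."""
    grid = np.asarray(grid, dtype=float)
    n_rows, n_cols = grid.shape
    header = (
        f"ncols {n_cols}\nnrows {n_rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize 1.0\nNODATA_value {_NODATA}\n"
    )
    body = grid.copy()
    body[np.isnan(body)] = _NODATA
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.17g")


def read_raster(path) -> tuple[np.ndarray, int]:
    """Read an ESRI ASCII grid; NODATA and NaN cells become 0.

    Returns (grid, nan_count) where nan_count is the number of replaced
    cells.
    """
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh, ndmin=2)
    if "ncols" in header:
        grid = grid.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", _NODATA)
    bad = np.isnan(grid) | (grid == nodata)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{path}: {n_bad} NODATA/NaN cells read as 0", stacklevel=2)
        grid = np.where(bad, 0.0, grid)
    return grid, n_bad


def write_layer_manifest(path, rows: list[dict]) -> None:
    """Manifest CSV with columns id, sector (optional), path."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_raster_stack(manifest_path, kind: str = "stressor"):
    """Load the layers listed in a manifest CSV.

    Columns: ``id``, ``path`` and (for stressors) ``sector``; paths are
    resolved relative to the manifest. All rasters must share one grid
    shape; a mismatch raises naming the offending layer. Returns
    (layers, nan_counts) where nan_counts maps layer id to the number of
    NaN/NODATA cells read as 0.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    if "id" not in table.columns or "path" not in table.columns:
        raise ValueError(f"{manifest_path}: manifest needs 'id' and 'path' columns")
    layers = []
    nan_counts: dict[str, int] = {}
    shape_seen = None
    for _, row in table.iterrows():
        raster_path = Path(row["path"])
        if not raster_path.is_absolute():
            raster_path = manifest_path.parent / raster_path
        if not raster_path.exists():
            raise FileNotFoundError(f"layer {row['id']!r}: missing raster {raster_path}")
        grid, n_bad = read_raster(raster_path)
        nan_counts[str(row["id"])] = n_bad
        if shape_seen is None:
            shape_seen = grid.shape
        elif grid.shape != shape_seen:
            raise ValueError(
                f"layer {row['id']!r} has shape {grid.shape}, expected {shape_seen}"
            )
        if kind == "stressor":
            layers.append(
                StressorLayer(
                    activity_id=str(row["id"]),
                    sector=str(row.get("sector", "")),
                    intensity=grid,
                )
            )
        else:
            layers.append(
                HabitatLayer(habitat_id=str(row["id"]), presence=grid.astype(np.uint8))
            )
    return layers, nan_counts


# ---------------------------------------------------------------------------
# vulnerability matrix


def write_vulnerability(path, vuln: VulnerabilityMatrix) -> None:
    vuln.weights.to_csv(path, index_label="habitat_id")


def read_vulnerability(path) -> VulnerabilityMatrix:
    table = pd.read_csv(path, index_col=0)
    return VulnerabilityMatrix(table.astype(float))


# ---------------------------------------------------------------------------
# MCA GeoJSON


def write_mcas(path, records: list[MCARecord]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(rec.footprint),
            "properties": {
                "mca_id": rec.mca_id,
                "zone_id": rec.zone_id,
                "governance": rec.governance,
                "status": rec.status,
                "bioregion": rec.bioregion,
            },
        }
        for rec in records
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_mcas(path) -> list[MCARecord]:
    with open(path) as fh:
        collection = json.load(fh)
    records = []
    for feat in collection["features"]:
        props = feat["properties"]
        records.append(
            MCARecord(
                mca_id=props["mca_id"],
                zone_id=props["zone_id"],
                footprint=shape(feat["geometry"]),
                governance=props["governance"],
                status=props["status"],
                bioregion=props.get("bioregion", ""),
            )
        )
    return records


# ---------------------------------------------------------------------------
# config / provenance


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable sha256 of a config mapping (canonical YAML form)."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_provenance(path, config: dict, seed: int) -> dict:
    import cimnet

    prov = {
        "config_hash": config_hash(config),
        "seed": seed,
        "cimnet_version": cimnet.__version__,
        "numpy_version": np.__version__,
    }
    with open(path, "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    return prov
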
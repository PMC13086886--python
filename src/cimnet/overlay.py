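"""MCA selection, zone merging, and zonal extraction of CI values.

Cell membership uses the zonal-statistics convention: a cell belongs to a
footprint when its centre lies strictly inside the geometry; cells are
half-open unit boxes [x, x+1) x [y, y+1) in grid coordinates (x = column,
y = row), so every point belongs to exactly one cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import stats
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .engine import CIRaster


@dataclass(frozen=True)
class MCARecord:
    """One zone of a marine conservation area."""

    mca_id: str
    zone_id: str
    footprint: BaseGeometry
    governance: str  # federal | provincial | private | joint
    status: str  # existing | proposed
    bioregion: str = ""

    def __post_init__(self) -> None:
        if self.footprint.is_empty:
            raise ValueError(f"empty footprint for ({self.mca_id}, {self.zone_id})")


@dataclass(frozen=True)
class MCASummary:
    """Per-MCA zonal statistics of the CI raster."""

    mca_id: str
    n_cells: int
    mean_ci: float
    ci95_halfwidth: float
    cell_values: np.ndarray
    area: float


DEFAULT_GOVERNANCE_ALLOW = frozenset({"federal", "joint"})


def merge_zones(records: list[MCARecord]) -> list[MCARecord]:
    """Merge all zones sharing an mca_id into a single record.

    The footprint is the geometric union of the zones; attributes come
    from the first zone (input order), with a warning when zones disagree.
    """
    out: list[MCARecord] = []
    seen: dict[str, int] = {}
    grouped: dict[str, list[MCARecord]] = {}
    for rec in records:
        if rec.mca_id not in seen:
            seen[rec.mca_id] = len(seen)
        grouped.setdefault(rec.mca_id, []).append(rec)
    for mca_id in sorted(grouped, key=seen.__getitem__):
        zones = grouped[mca_id]
        first = zones[0]
        for z in zones[1:]:
            if (z.governance, z.status, z.bioregion) != (
                first.governance,
                first.status,
                first.bioregion,
            ):
                warnings.warn(
                    f"MCA {mca_id!r}: zone {z.zone_id!r} attributes disagree with "
                    f"zone {first.zone_id!r}; keeping the first zone's attributes",
                    stacklevel=2,
                )
        out.append(
            MCARecord(
                mca_id=mca_id,
                zone_id="merged",
                footprint=unary_union([z.footprint for z in zones]),
                governance=first.governance,
                status=first.status,
                bioregion=first.bioregion,
            )
        )
    return out


def filter_mcas(
    records: list[MCARecord],
    governance_allow: frozenset[str] | set[str] = DEFAULT_GOVERNANCE_ALLOW,
    min_area: float = 1.0,
) -> list[MCARecord]:
    """Keep zones of MCAs with allowed governance and merged area >= min_area.

    The area threshold applies to the zone-merged total area of each
    mca_id (areas strictly below ``min_area`` are excluded), computed on
    the footprint geometry before any clipping to a raster.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    merged_area: dict[str, float] = {}
    for rec in merge_zones(records):
        merged_area[rec.mca_id] = rec.footprint.area
    kept = [
        rec
        for rec in records
        if rec.governance in governance_allow and merged_area[rec.mca_id] >= min_area
    ]
    if records and not kept:
        warnings.warn("no MCA records pass the governance/area filters", stacklevel=2)
    return kept


def rasterize_footprint(region, footprint: BaseGeometry) -> np.ndarray:
    """Boolean mask of cells whose centre lies inside the footprint."""
    rows = np.arange(region.n_rows)
    cols = np.arange(region.n_cols)
    cc, rr = np.meshgrid(cols + 0.5, rows + 0.5)
    shapely.prepare(footprint)
    return shapely.contains_xy(footprint, cc.ravel(), rr.ravel()).reshape(region.shape)


def extract_cells(ci: CIRaster, record: MCARecord, region) -> np.ndarray:
    """CI values of all cells whose centre falls inside the MCA footprint.

    Raises ``ValueError`` when no cell centre is covered — such records
    should have been removed by the minimum-area filter.
    """
    mask = rasterize_footprint(region, record.footprint)
    if not mask.any():
        raise ValueError(
            f"MCA {record.mca_id!r} covers no cell centre; apply the minimum-area "
            "filter before extraction"
        )
    return ci.ci[mask]


def summarize_mca(mca_id: str, values: np.ndarray, area: float) -> MCASummary:
    """Mean CI and t-based 95% confidence half-width for one MCA.

    Half-width = t(0.975, n-1) * sd / sqrt(n); defined as 0 when n = 1 or
    the values are constant.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    n = values.size
    mean = float(values.mean())
    if n == 1:
        half = 0.0
    else:
        sd = float(values.std(ddof=1))
        half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return MCASummary(
        mca_id=mca_id,
        n_cells=n,
        mean_ci=mean,
        ci95_halfwidth=half,
        cell_values=values,
        area=float(area),
    )
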
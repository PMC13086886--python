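"""Synthetic seascape generation.

Builds region grids, stressor intensity layers, habitat presence layers,
habitat x stressor vulnerability weights, and marine conservation area
(MCA) footprints with the statistical structure the downstream cumulative
impact analysis assumes, so every stage is testable without external data.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64);
one explicitly seeded stream per operation, so fixed seeds give
bit-identical output across runs and platforms.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .engine import HabitatLayer, StressorLayer, VulnerabilityMatrix
from .overlay import MCARecord

SECTORS = ("Climate", "Fishing", "Marine", "Coastal", "Land")

#: footprint kinds each sector may use
_SECTOR_FOOTPRINTS = {
    "Climate": {"regionwide"},
    "Fishing": {"patchy"},
    "Marine": {"patchy", "corridor"},
    "Coastal": {"shore_decay"},
    "Land": {"shore_decay"},
}


@dataclass(frozen=True)
class RegionGrid:
    """A rectangular 1 km^2 analysis grid with a sea mask.

    ``coast_distance`` holds, for every sea cell, the breadth-first
    (4-neighbour) distance in cells to the nearest land-adjacent sea cell
    (0 on those cells themselves). If the grid contains no land, distance
    is measured from sea cells on the grid edge. Land cells hold +inf.
    """

    n_rows: int
    n_cols: int
    sea_mask: np.ndarray
    coast_distance: np.ndarray
    cell_area: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_sea(self) -> int:
        return int(self.sea_mask.sum())


@dataclass(frozen=True)
class SectorConfig:
    """Number, footprint style and intensity scale of one sector's layers."""

    sector: str
    n_layers: int
    footprint_kind: str
    intensity_scale: float = 1.0
    marginal: str = "uniform"  # pre-rescaling intensity marginal: uniform | lognormal

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ValueError(f"unknown sector {self.sector!r}; expected one of {SECTORS}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.footprint_kind not in _SECTOR_FOOTPRINTS[self.sector]:
            raise ValueError(
                f"footprint_kind {self.footprint_kind!r} invalid for sector "
                f"{self.sector!r}; allowed: {sorted(_SECTOR_FOOTPRINTS[self.sector])}"
            )
        if self.marginal not in ("uniform", "lognormal"):
            raise ValueError("marginal must be 'uniform' or 'lognormal'")


def default_sector_configs() -> list[SectorConfig]:
    """Sector layout emulating the published regional cumulative impact maps:
    45 activity layers across five sectors, fishing the largest."""
    return [
        SectorConfig("Climate", 6, "regionwide"),
        SectorConfig("Fishing", 15, "patchy"),
        SectorConfig("Marine", 6, "patchy"),
        SectorConfig("Marine", 4, "corridor"),
        SectorConfig("Coastal", 8, "shore_decay"),
        SectorConfig("Land", 6, "shore_decay"),
    ]


# ---------------------------------------------------------------------------
# region


def _coast_distance(sea: np.ndarray) -> np.ndarray:
    """Multi-source BFS (4-neighbourhood) from land-adjacent sea cells;
    from edge sea cells when the grid has no land."""
    n_rows, n_cols = sea.shape
    dist = np.full(sea.shape, np.inf)
    queue: deque[tuple[int, int]] = deque()
    has_land = bool((~sea).any())
    for r in range(n_rows):
        for c in range(n_cols):
            if not sea[r, c]:
                continue
            if has_land:
                adjacent_land = any(
                    0 <= rr < n_rows and 0 <= cc < n_cols and not sea[rr, cc]
                    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                )
            else:
                adjacent_land = r in (0, n_rows - 1) or c in (0, n_cols - 1)
            if adjacent_land:
                dist[r, c] = 0.0
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < n_rows and 0 <= cc < n_cols and sea[rr, cc] and np.isinf(dist[rr, cc]):
                dist[rr, cc] = dist[r, c] + 1
                queue.append((rr, cc))
    return dist


def make_region(n_rows: int, n_cols: int, land_fraction: float, seed: int) -> RegionGrid:
    """Generate a region grid with blobby land and a single connected sea.

    Land is a thresholded smoothed Gaussian field (threshold at the
    ``land_fraction`` quantile); disconnected sea pockets are converted to
    land so the sea forms one 4-connected component.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8x8")
    if not 0 <= land_fraction < 1:
        raise ValueError("land_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if land_fraction == 0:
        sea = np.ones((n_rows, n_cols), dtype=bool)
    else:
        noise = rng.standard_normal((n_rows, n_cols))
        smooth = ndimage.gaussian_filter(noise, sigma=max(n_rows, n_cols) / 12)
        sea = smooth >= np.quantile(smooth, land_fraction)
        # keep only the largest sea component; absorb the rest into land
        labels, n_comp = ndimage.label(sea)
        if n_comp == 0:
            raise ValueError("degenerate grid: all land")
        sizes = ndimage.sum_labels(sea, labels, index=np.arange(1, n_comp + 1))
        sea = labels == (1 + int(np.argmax(sizes)))
    return RegionGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        sea_mask=sea,
        coast_distance=_coast_distance(sea),
    )


# ---------------------------------------------------------------------------
# stressors


def _base_field(region: RegionGrid, rng: np.random.Generator, marginal: str) -> np.ndarray:
    if marginal == "lognormal":
        return rng.lognormal(mean=0.0, sigma=0.75, size=region.shape)
    return rng.uniform(0.2, 1.0, size=region.shape)


def _regionwide(region: RegionGrid, rng: np.random.Generator, marginal: str) -> np.ndarray:
    rough = _base_field(region, rng, marginal)
    smooth = ndimage.gaussian_filter(rough, sigma=2.0)
    return 0.05 + np.abs(smooth)  # strictly positive everywhere


def _patchy(region: RegionGrid, rng: np.random.Generator, marginal: str) -> np.ndarray:
    """Union of random discs centred on sea cells; sparse by construction."""
    out = np.zeros(region.shape)
    sea_idx = np.argwhere(region.sea_mask)
    rows = np.arange(region.n_rows)[:, None]
    cols = np.arange(region.n_cols)[None, :]
    target = 0.15 * region.n_sea  # cover well under half the sea
    n_discs = max(3, int(target / 20))
    amp = _base_field(region, rng, marginal)
    for _ in range(n_discs):
        r0, c0 = sea_idx[rng.integers(len(sea_idx))]
        radius = rng.uniform(1.5, 4.0)
        disc = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
        out[disc] = np.maximum(out[disc], amp[disc])
    return out


def _corridor(region: RegionGrid, rng: np.random.Generator, marginal: str) -> np.ndarray:
    """A thickened random polyline, e.g. a shipping lane."""
    out = np.zeros(region.shape)
    n_pts = 4
    pts = np.column_stack(
        [
            rng.uniform(0, region.n_rows - 1, n_pts),
            rng.uniform(0, region.n_cols - 1, n_pts),
        ]
    )
    pts = pts[np.argsort(pts[:, 1])]
    width = rng.uniform(0.8, 1.6)
    rows = np.arange(region.n_rows)[:, None]
    cols = np.arange(region.n_cols)[None, :]
    amp = _base_field(region, rng, marginal)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        # distance of every cell centre to the segment
        dr, dc = r1 - r0, c1 - c0
        denom = dr * dr + dc * dc
        t = np.clip(((rows - r0) * dr + (cols - c0) * dc) / max(denom, 1e-12), 0, 1)
        d2 = (rows - (r0 + t * dr)) ** 2 + (cols - (c0 + t * dc)) ** 2
        band = d2 <= width**2
        out[band] = np.maximum(out[band], amp[band])
    return out


def _shore_decay(region: RegionGrid, rng: np.random.Generator, marginal: str) -> np.ndarray:
    """Intensity decaying exponentially with distance from the coast."""
    scale = rng.uniform(2.0, 5.0)
    decay = np.zeros(region.shape)
    sea = region.sea_mask
    decay[sea] = np.exp(-region.coast_distance[sea] / scale)
    rough = 0.5 + 0.5 * _base_field(region, rng, marginal)
    return decay * rough


_FOOTPRINT_FN = {
    "regionwide": _regionwide,
    "patchy": _patchy,
    "corridor": _corridor,
    "shore_decay": _shore_decay,
}


def simulate_stressors(
    region: RegionGrid, configs: list[SectorConfig], seed: int
) -> list[StressorLayer]:
    """Generate one intensity layer per activity, grouped by sector.

    Each layer is zero on land, rescaled to unit maximum over sea cells,
    then multiplied by the sector's ``intensity_scale`` and clipped to
    [0, 1]; a scale of 0 yields all-zero layers.
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    rng = np.random.default_rng(seed)
    layers: list[StressorLayer] = []
    counters: dict[str, int] = {}
    for cfg in configs:
        for _ in range(cfg.n_layers):
            idx = counters.get(cfg.sector, 0)
            counters[cfg.sector] = idx + 1
            raw = _FOOTPRINT_FN[cfg.footprint_kind](region, rng, cfg.marginal)
            raw = np.where(region.sea_mask, raw, 0.0)
            peak = raw.max()
            if peak > 0:
                raw = raw / peak
            intensity = np.clip(raw * cfg.intensity_scale, 0.0, 1.0)
            layers.append(
                StressorLayer(
                    activity_id=f"{cfg.sector.lower()}_{idx:02d}",
                    sector=cfg.sector,
                    intensity=intensity,
                )
            )
    return layers


# ---------------------------------------------------------------------------
# habitats


def simulate_habitats(
    region: RegionGrid, n_habitats: int, mean_coverage: float, seed: int
) -> list[HabitatLayer]:
    """Generate binary habitat presence layers whose union covers the sea.

    Each habitat is a thresholded smooth field occupying about
    ``mean_coverage`` of the sea; any sea cell left uncovered is assigned
    to the habitat with the strongest field value there.
    """
    if n_habitats < 1:
        raise ValueError("n_habitats must be >= 1")
    if not 0 < mean_coverage <= 1:
        raise ValueError("mean_coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sea = region.sea_mask
    fields = np.empty((n_habitats, *region.shape))
    presence = np.zeros((n_habitats, *region.shape), dtype=np.uint8)
    for j in range(n_habitats):
        f = ndimage.gaussian_filter(rng.standard_normal(region.shape), sigma=3.0)
        fields[j] = f
        if mean_coverage >= 1:
            keep = sea
        else:
            thr = np.quantile(f[sea], 1 - mean_coverage)
            keep = sea & (f >= thr)
        presence[j][keep] = 1
    uncovered = sea & (presence.sum(axis=0) == 0)
    if uncovered.any():
        best = np.argmax(fields, axis=0)
        for j in range(n_habitats):
            presence[j][uncovered & (best == j)] = 1
    return [
        HabitatLayer(habitat_id=f"hab_{j:02d}", presence=presence[j])
        for j in range(n_habitats)
    ]


# ---------------------------------------------------------------------------
# vulnerability


def simulate_vulnerability(
    n_habitats: int, n_stressors: int, sparsity: float, seed: int
) -> VulnerabilityMatrix:
    """Sparse non-negative habitat x stressor weights.

    About ``sparsity`` of entries are exactly zero; every stressor keeps at
    least one positive weight so no activity is globally inert.
    """
    if n_habitats < 1 or n_stressors < 1:
        raise ValueError("dimensions must be >= 1")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    weights = rng.gamma(shape=2.0, scale=1.0, size=(n_habitats, n_stressors))
    zero = rng.random((n_habitats, n_stressors)) < sparsity
    weights[zero] = 0.0
    for i in range(n_stressors):
        if not (weights[:, i] > 0).any():
            weights[rng.integers(n_habitats), i] = rng.gamma(2.0, 1.0)
    habitat_ids = [f"hab_{j:02d}" for j in range(n_habitats)]
    stressor_ids = [f"act_{i:02d}" for i in range(n_stressors)]
    return VulnerabilityMatrix.from_array(weights, habitat_ids, stressor_ids)


# ---------------------------------------------------------------------------
# MCAs


def _cells_under(region: RegionGrid, geom: BaseGeometry) -> np.ndarray:
    from .overlay import rasterize_footprint

    return rasterize_footprint(region, geom)


def simulate_mcas(region: RegionGrid, n_mcas: int, seed: int) -> list[MCARecord]:
    """Generate non-overlapping MCA footprints on the sea.

    The set deliberately contains at least one sub-cell (area < 1 km^2)
    record, one multi-zone MCA, and a governance mix spanning federal,
    provincial, private and joint, mirroring the bookkeeping a protected
    area registry requires (zone merging, ownership filtering, minimum
    area exclusion).
    """
    if n_mcas < 1:
        raise ValueError("n_mcas must be >= 1")
    rng = np.random.default_rng(seed)
    sea_idx = np.argwhere(region.sea_mask)
    claimed = np.zeros(region.shape, dtype=bool)
    records: list[MCARecord] = []
    governances = ["federal", "federal", "joint", "provincial", "private"]
    statuses = ["existing", "proposed"]

    def place(radius: float, max_tries: int = 200) -> BaseGeometry | None:
        for _ in range(max_tries):
            r0, c0 = sea_idx[rng.integers(len(sea_idx))]
            geom = Point(c0 + 0.5, r0 + 0.5).buffer(radius, quad_segs=16)
            cells = _cells_under(region, geom)
            inside = cells & region.sea_mask
            if cells.sum() == 0 and radius < 1:
                # sub-cell footprint: centre cell only needs to be sea/unclaimed
                if region.sea_mask[r0, c0] and not claimed[r0, c0]:
                    claimed[r0, c0] = True
                    return geom
                continue
            if cells.sum() > 0 and (cells == inside).all() and not (cells & claimed).any():
                claimed[cells] = True
                return geom
        return None

    i = 0
    while len({r.mca_id for r in records}) < n_mcas:
        mca_id = f"mca_{i:03d}"
        gov = governances[i % len(governances)]
        status = statuses[(i // 2) % 2]
        if i == 0:
            geom = place(radius=0.4)  # area ~0.5 km^2 < 1 cell
        elif i == 1:
            # multi-zone MCA: two adjacent zones
            g1 = place(radius=rng.uniform(2.0, 3.0))
            g2 = place(radius=rng.uniform(1.5, 2.5))
            if g1 is None or g2 is None:
                i += 1
                continue
            records.append(
                MCARecord(mca_id, "zone_a", g1, "federal", "existing", "synthetic")
            )
            records.append(
                MCARecord(mca_id, "zone_b", g2, "federal", "existing", "synthetic")
            )
            i += 1
            continue
        else:
            geom = place(radius=rng.uniform(1.0, 4.0))
        if geom is not None:
            records.append(MCARecord(mca_id, "zone_a", geom, gov, status, "synthetic"))
        i += 1
        if i > 20 * n_mcas:  # give up gracefully on crowded grids
            break
    return records
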
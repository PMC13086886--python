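"""Additive cumulative impact (CI) scoring.

The model follows the standard cumulative impact mapping formulation:
for activity i with intensity D_i(x) in cell x, habitat j with presence
E_j(x) and vulnerability weight mu(j, i),

    impact_i(x) = D_i(x) * sum_j E_j(x) * mu(j, i)
    CI(x)       = sum_i impact_i(x)

Scores are habitat-summed (no division by habitat count) and purely
local: each cell's score depends only on that cell's layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StressorLayer:
    """One activity's intensity per grid cell, in [0, 1], zero on land."""

    activity_id: str
    sector: str
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if (self.intensity < 0).any():
            raise ValueError(f"negative intensity in layer {self.activity_id!r}")


@dataclass(frozen=True)
class HabitatLayer:
    """Binary presence per grid cell for one habitat class."""

    habitat_id: str
    presence: np.ndarray

    def __post_init__(self) -> None:
        vals = np.unique(self.presence)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"habitat {self.habitat_id!r} presence must be 0/1")


@dataclass(frozen=True)
class VulnerabilityMatrix:
    """Non-negative weight per (habitat, stressor) pair.

    Backed by a DataFrame: rows indexed by habitat id, columns by
    stressor activity id. Complete over the declared id sets.
    """

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.weights.to_numpy() < 0).any():
            raise ValueError("vulnerability weights must be non-negative")

    @classmethod
    def from_array(
        cls, weights: np.ndarray, habitat_ids: list[str], stressor_ids: list[str]
    ) -> "VulnerabilityMatrix":
        return cls(pd.DataFrame(np.asarray(weights, dtype=float),
                                index=list(habitat_ids), columns=list(stressor_ids)))

    @property
    def habitat_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def stressor_ids(self) -> list[str]:
        return list(self.weights.columns)

    def weight(self, habitat_id: str, stressor_id: str) -> float:
        return float(self.weights.at[habitat_id, stressor_id])


@dataclass
class ImpactCube:
    """Habitat-summed impact of each activity in each cell.

    ``impact`` has shape (n_activities, n_rows, n_cols); ``sector_of``
    maps each activity id to its sector.
    """

    activity_ids: list[str]
    impact: np.ndarray
    sector_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.impact.shape[0] != len(self.activity_ids):
            raise ValueError("impact first axis must match activity_ids")

    def index_of(self, activity_id: str) -> int:
        return self.activity_ids.index(activity_id)

    def copy(self) -> "ImpactCube":
        return ImpactCube(list(self.activity_ids), self.impact.copy(), dict(self.sector_of))


@dataclass(frozen=True)
class CIRaster:
    """Per-cell cumulative impact score (unitless, relative)."""

    ci: np.ndarray


def impact_scores(
    stressors: list[StressorLayer],
    habitats: list[HabitatLayer],
    vuln: VulnerabilityMatrix,
) -> ImpactCube:
    """Compute per-cell, per-activity impact scores.

    Raises ``KeyError`` naming any stressor or habitat id absent from the
    vulnerability matrix.
    """
    for s in stressors:
        if s.activity_id not in vuln.weights.columns:
            raise KeyError(f"stressor {s.activity_id!r} missing from vulnerability matrix")
    for h in habitats:
        if h.habitat_id not in vuln.weights.index:
            raise KeyError(f"habitat {h.habitat_id!r} missing from vulnerability matrix")
    if stressors:
        shape = stressors[0].intensity.shape
        for layer in stressors[1:]:
            if layer.intensity.shape != shape:
                raise ValueError(f"layer {layer.activity_id!r} grid shape mismatch")
        for h in habitats:
            if h.presence.shape != shape:
                raise ValueError(f"habitat {h.habitat_id!r} grid shape mismatch")

    activity_ids = [s.activity_id for s in stressors]
    shape = stressors[0].intensity.shape if stressors else (0, 0)
    impact = np.zeros((len(stressors), *shape))
    for k, s in enumerate(stressors):
        weighted_presence = np.zeros(shape)
        for h in habitats:
            w = vuln.weight(h.habitat_id, s.activity_id)
            if w:
                weighted_presence += w * h.presence
        impact[k] = s.intensity * weighted_presence
    return ImpactCube(
        activity_ids=activity_ids,
        impact=impact,
        sector_of={s.activity_id: s.sector for s in stressors},
    )


def cumulative_impact(cube: ImpactCube) -> CIRaster:
    """Sum impact scores over activities, per cell."""
    if cube.impact.shape[0] == 0:
        return CIRaster(ci=np.zeros(cube.impact.shape[1:]))
    return CIRaster(ci=cube.impact.sum(axis=0))


def sector_decompose(
    cube: ImpactCube,
) -> tuple[dict[str, CIRaster], dict[str, np.ndarray]]:
    """Split the CI raster by sector.

    Returns per-sector CI rasters (summing cell-wise to the total) and
    per-cell sector proportions (summing to 1 where CI > 0, 0 elsewhere).
    """
    for a in cube.activity_ids:
        if a not in cube.sector_of:
            raise KeyError(f"activity {a!r} has no sector mapping")
    sectors = sorted({cube.sector_of[a] for a in cube.activity_ids})
    total = cumulative_impact(cube).ci
    rasters: dict[str, CIRaster] = {}
    proportions: dict[str, np.ndarray] = {}
    for sec in sectors:
        idx = [k for k, a in enumerate(cube.activity_ids) if cube.sector_of[a] == sec]
        sec_ci = cube.impact[idx].sum(axis=0)
        rasters[sec] = CIRaster(ci=sec_ci)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(total > 0, sec_ci / np.where(total > 0, total, 1.0), 0.0)
        proportions[sec] = prop
    return rasters, proportions
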
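"""Protection-standard scenario engine.

Models the removal of prohibited activities (e.g. bottom-contact fishing
gear, dredging, disposal at sea) from inside conservation-area
footprints, recomputes the additive CI score from the remaining
activities, and quantifies the resulting per-cell, per-MCA and
network-level percent declines. Removed activity is not displaced or
reallocated outside MCA boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CIRaster, ImpactCube


@dataclass(frozen=True)
class ScenarioSpec:
    """Which activities are prohibited, and inside which MCAs."""

    name: str
    prohibited_activities: frozenset[str]
    target_mcas: frozenset[str] | None = None  # None = all MCAs supplied

    def targets(self, mca_ids) -> list[str]:
        if self.target_mcas is None:
            return list(mca_ids)
        return [m for m in mca_ids if m in self.target_mcas]


@dataclass(frozen=True)
class ProtectionPotential:
    """Quadrant label of one MCA in current-CI x percent-decline space."""

    mca_id: str
    current_mean_ci: float
    pct_decline: float
    label: str  # high_potential | other
    median_ci: float
    median_decline: float


def apply_scenario(
    cube: ImpactCube,
    spec: ScenarioSpec,
    mca_masks: dict[str, np.ndarray],
) -> ImpactCube:
    """Zero prohibited activities' impacts inside target MCA footprints.

    Every other (activity, cell) entry is returned bit-identical to the
    input. Unknown activity ids in the spec raise ``KeyError``.
    """
    unknown = spec.prohibited_activities - set(cube.activity_ids)
    if unknown:
        raise KeyError(f"prohibited activities not in impact cube: {sorted(unknown)}")
    out = cube.copy()
    target_ids = spec.targets(mca_masks.keys())
    if not target_ids or not spec.prohibited_activities:
        return out
    union = np.zeros(cube.impact.shape[1:], dtype=bool)
    for mca_id in target_ids:
        union |= mca_masks[mca_id]
    for act in spec.prohibited_activities:
        out.impact[cube.index_of(act)][union] = 0.0
    return out


def percent_decline_cell(ci_before: CIRaster, ci_after: CIRaster) -> np.ndarray:
    """Per-cell percent CI reduction, 100*(before-after)/before; 0 where
    before = 0. Any cell with after > before violates the scenario's
    monotonicity and raises."""
    before = ci_before.ci
    after = ci_after.ci
    if (after > before).any():
        raise ValueError("ci_after exceeds ci_before; scenario must only remove impact")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(before > 0, 100.0 * (before - after) / np.where(before > 0, before, 1.0), 0.0)
    return pct


def mca_decline(
    before_values: np.ndarray,
    after_values: np.ndarray,
    method: str = "mean_ratio",
) -> float:
    """Percent decline in an MCA's CI from paired per-cell samples.

    ``mean_ratio`` (default): 100 * (mean(before) - mean(after)) / mean(before),
    i.e. the percent change of the MCA's mean CI. ``mean_of_cell_pct``:
    the mean of per-cell percent changes. Both return 0 when mean(before)
    is 0.
    """
    before = np.asarray(before_values, dtype=float)
    after = np.asarray(after_values, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must be paired over the same cells")
    if method == "mean_ratio":
        mb = before.mean()
        if mb == 0:
            return 0.0
        return float(100.0 * (mb - after.mean()) / mb)
    if method == "mean_of_cell_pct":
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(
                before > 0, 100.0 * (before - after) / np.where(before > 0, before, 1.0), 0.0
            )
        return float(pct.mean())
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class NetworkSummary:
    """Network-level protection-potential statistics."""

    n_mcas: int
    mean_pct_decline: float
    min_pct_decline: float
    max_pct_decline: float
    n_zero_change: int
    n_mcas_with_cell_over_50: int
    max_cell_pct_decline: float


def network_summary(
    declines: dict[str, float],
    cell_declines: np.ndarray,
    mca_masks: dict[str, np.ndarray],
) -> NetworkSummary:
    """Summarise per-MCA declines across the conservation network.

    The network mean is the unweighted mean over MCAs (not area-weighted).
    Also counts MCAs containing at least one cell with a >50% cell-level
    decline.
    """
    if not declines:
        raise ValueError("at least one MCA required")
    vals = np.array(list(declines.values()), dtype=float)
    n_over_50 = 0
    max_cell = 0.0
    for mca_id in declines:
        mask = mca_masks[mca_id]
        if mask.any():
            cell_max = float(cell_declines[mask].max())
            max_cell = max(max_cell, cell_max)
            if (cell_declines[mask] > 50.0).any():
                n_over_50 += 1
    return NetworkSummary(
        n_mcas=len(declines),
        mean_pct_decline=float(vals.mean()),
        min_pct_decline=float(vals.min()),
        max_pct_decline=float(vals.max()),
        n_zero_change=int((vals == 0).sum()),
        n_mcas_with_cell_over_50=n_over_50,
        max_cell_pct_decline=max_cell,
    )


def protection_potential(
    table: dict[str, tuple[float, float]],
) -> list[ProtectionPotential]:
    """Label MCAs whose current mean CI and percent decline both strictly
    exceed the network medians as having high protection potential.

    ``table`` maps mca_id -> (current_mean_ci, pct_decline); medians are
    computed over this same table (existing + proposed MCAs together).
    """
    if len(table) < 2:
        raise ValueError("at least two MCAs required to compute medians")
    cis = np.array([v[0] for v in table.values()], dtype=float)
    decs = np.array([v[1] for v in table.values()], dtype=float)
    med_ci = float(np.median(cis))
    med_dec = float(np.median(decs))
    out = []
    for mca_id, (ci, dec) in table.items():
        label = "high_potential" if (ci > med_ci and dec > med_dec) else "other"
        out.append(
            ProtectionPotential(
                mca_id=mca_id,
                current_mean_ci=float(ci),
                pct_decline=float(dec),
                label=label,
                median_ci=med_ci,
                median_decline=med_dec,
            )
        )
    return out
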
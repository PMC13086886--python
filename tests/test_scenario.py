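"""Protection-standard scenario: activity removal inside MCA footprints
only, percent-decline bookkeeping, network summaries and the two-median
protection-potential quadrant rule."""

import numpy as np
import pytest

from cimnet import (
    CIRaster,
    HabitatLayer,
    ImpactCube,
    ScenarioSpec,
    StressorLayer,
    VulnerabilityMatrix,
    apply_scenario,
    cumulative_impact,
    impact_scores,
    mca_decline,
    network_summary,
    percent_decline_cell,
    protection_potential,
)


@pytest.fixture
def small_cube():
    rng = np.random.default_rng(0)
    impact = rng.random((3, 5, 5)) + 0.1
    return ImpactCube(
        ["trawl", "dredge", "shipping"],
        impact,
        {"trawl": "Fishing", "dredge": "Fishing", "shipping": "Marine"},
    )


def one_mca_mask(shape, cells):
    mask = np.zeros(shape, dtype=bool)
    for r, c in cells:
        mask[r, c] = True
    return mask


class TestApplyScenario:
    def test_empty_prohibited_set_is_identity(self, small_cube):
        spec = ScenarioSpec("noop", frozenset())
        masks = {"m1": one_mca_mask((5, 5), [(1, 1)])}
        out = apply_scenario(small_cube, spec, masks)
        assert np.array_equal(out.impact, small_cube.impact)

    def test_all_prohibited_everywhere_zeroes_all(self, small_cube):
        spec = ScenarioSpec("wipe", frozenset(small_cube.activity_ids))
        masks = {"m1": np.ones((5, 5), dtype=bool)}
        out = apply_scenario(small_cube, spec, masks)
        assert (out.impact == 0).all()

    def test_single_cell_single_activity(self, small_cube):
        small_cube.impact[0, 2, 3] = 4.0
        spec = ScenarioSpec("one", frozenset(["trawl"]))
        masks = {"m1": one_mca_mask((5, 5), [(2, 3)])}
        out = apply_scenario(small_cube, spec, masks)
        assert out.impact[0, 2, 3] == 0.0
        touched = np.zeros_like(small_cube.impact, dtype=bool)
        touched[0, 2, 3] = True
        assert np.array_equal(out.impact[~touched], small_cube.impact[~touched])

    def test_unknown_activity_rejected(self, small_cube):
        spec = ScenarioSpec("bad", frozenset(["longline"]))
        with pytest.raises(KeyError, match="longline"):
            apply_scenario(small_cube, spec, {"m1": np.ones((5, 5), dtype=bool)})

    def test_outside_mca_bit_identical(self, small_cube):
        spec = ScenarioSpec("zone", frozenset(["trawl", "dredge"]))
        mask = one_mca_mask((5, 5), [(0, 0), (0, 1), (4, 4)])
        out = apply_scenario(small_cube, spec, {"m1": mask})
        outside = ~mask
        assert np.array_equal(out.impact[:, outside], small_cube.impact[:, outside])
        assert (cumulative_impact(out).ci <= cumulative_impact(small_cube).ci).all()


class TestPercentDecline:
    def test_simple_cases(self):
        before = CIRaster(np.array([[10.0, 0.0, 5.0]]))
        after = CIRaster(np.array([[9.0, 0.0, 0.0]]))
        pct = percent_decline_cell(before, after)
        assert pct.tolist() == [[10.0, 0.0, 100.0]]

    def test_increase_rejected(self):
        with pytest.raises(ValueError):
            percent_decline_cell(
                CIRaster(np.array([[1.0]])), CIRaster(np.array([[2.0]]))
            )

    def test_mca_decline_mean_ratio(self):
        assert mca_decline([10.0, 10.0], [9.0, 9.0]) == pytest.approx(10.0)
        assert mca_decline([10.0, 0.0], [5.0, 0.0]) == pytest.approx(50.0)
        assert mca_decline([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_mca_decline_no_overlap_zero(self):
        vals = np.array([3.0, 4.0])
        assert mca_decline(vals, vals) == 0.0

    def test_mean_of_cell_pct_variant(self):
        got = mca_decline([10.0, 0.0], [5.0, 0.0], method="mean_of_cell_pct")
        assert got == pytest.approx(25.0)  # mean(50%, 0%)


class TestNetworkSummary:
    def test_basic(self):
        declines = {"a": 0.0, "b": 10.0, "c": 20.0}
        cells = np.zeros((2, 3))
        masks = {k: np.zeros((2, 3), dtype=bool) for k in declines}
        for i, k in enumerate(declines):
            masks[k][0, i] = True
        net = network_summary(declines, cells, masks)
        assert net.mean_pct_decline == pytest.approx(10.0)
        assert (net.min_pct_decline, net.max_pct_decline) == (0.0, 20.0)
        assert net.n_zero_change == 1

    def test_all_zero(self):
        declines = {"a": 0.0, "b": 0.0}
        masks = {k: np.ones((1, 2), dtype=bool) for k in declines}
        net = network_summary(declines, np.zeros((1, 2)), masks)
        assert net.mean_pct_decline == 0.0
        assert net.n_zero_change == 2

    def test_cell_over_50_count_matches_direct_scan(self):
        rng = np.random.default_rng(11)
        cells = rng.uniform(0, 100, (10, 10))
        masks = {}
        declines = {}
        for i in range(4):
            mask = np.zeros((10, 10), dtype=bool)
            mask[rng.integers(0, 10, 6), rng.integers(0, 10, 6)] = True
            masks[f"m{i}"] = mask
            declines[f"m{i}"] = float(i)
        net = network_summary(declines, cells, masks)
        direct = sum((cells[m] > 50).any() for m in masks.values())
        assert net.n_mcas_with_cell_over_50 == direct


class TestProtectionPotential:
    def test_two_median_quadrant(self):
        table = {f"m{i}": (float(i), float(i)) for i in range(1, 5)}
        out = {p.mca_id: p.label for p in protection_potential(table)}
        assert out == {
            "m1": "other",
            "m2": "other",
            "m3": "high_potential",
            "m4": "high_potential",
        }

    def test_all_equal_strict_inequality_gives_none(self):
        table = {f"m{i}": (2.0, 5.0) for i in range(4)}
        assert all(p.label == "other" for p in protection_potential(table))

    def test_single_dominator(self):
        table = {"a": (1.0, 1.0), "b": (2.0, 2.0), "c": (3.0, 1.5), "d": (9.0, 9.0)}
        out = {p.mca_id: p.label for p in protection_potential(table)}
        assert out["d"] == "high_potential"
        assert sum(v == "high_potential" for v in out.values()) <= 2

    def test_matches_direct_scan_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = rng.integers(2, 12)
            table = {
                f"m{i}": (float(rng.uniform(0, 10)), float(rng.uniform(0, 40)))
                for i in range(n)
            }
            med_ci = np.median([v[0] for v in table.values()])
            med_d = np.median([v[1] for v in table.values()])
            for p in protection_potential(table):
                expect = (
                    "high_potential"
                    if table[p.mca_id][0] > med_ci and table[p.mca_id][1] > med_d
                    else "other"
                )
                assert p.label == expect


class TestEndToEndRecovery:
    @pytest.mark.parametrize("q", [0.0, 0.25, 0.5, 1.0])
    def test_known_prohibited_fraction_recovered(self, q):
        """Seascape built so prohibited activities contribute exactly
        fraction q of the CI inside every MCA."""
        shape = (8, 8)
        intensity = np.ones(shape)
        stressors = [
            StressorLayer("prohibited", "Fishing", intensity),
            StressorLayer("kept", "Climate", intensity),
        ]
        habitats = [HabitatLayer("h", np.ones(shape, dtype=np.uint8))]
        vuln = VulnerabilityMatrix.from_array(
            np.array([[q, 1.0 - q]]), ["h"], ["prohibited", "kept"]
        )
        cube = impact_scores(stressors, habitats, vuln)
        before = cumulative_impact(cube)
        mask = np.zeros(shape, dtype=bool)
        mask[2:5, 2:5] = True
        spec = ScenarioSpec("q", frozenset(["prohibited"]))
        after_cube = apply_scenario(cube, spec, {"m": mask})
        after = cumulative_impact(after_cube)
        decline = mca_decline(before.ci[mask], after.ci[mask])
        assert decline == pytest.approx(100 * q, abs=1e-9)
        assert np.array_equal(after.ci[~mask], before.ci[~mask])
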
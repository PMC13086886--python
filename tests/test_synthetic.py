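"""The generated seascapes must have the structure the analysis assumes:
zero on land, connected sea, coast distances from a BFS, covering
habitats, sparse vulnerabilities, and a registry-like MCA set."""

import numpy as np
import pytest

from cimnet import (
    SectorConfig,
    make_region,
    rasterize_footprint,
    simulate_habitats,
    simulate_mcas,
    simulate_stressors,
    simulate_vulnerability,
)
from cimnet.synthetic import default_sector_configs


def bfs_oracle(sea):
    """Independent coast-distance check: dense min-plus relaxation."""
    n_rows, n_cols = sea.shape
    dist = np.full(sea.shape, np.inf)
    has_land = (~sea).any()
    for r in range(n_rows):
        for c in range(n_cols):
            if not sea[r, c]:
                continue
            neighbours = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            if has_land:
                coastal = any(
                    0 <= rr < n_rows and 0 <= cc < n_cols and not sea[rr, cc]
                    for rr, cc in neighbours
                )
            else:
                coastal = r in (0, n_rows - 1) or c in (0, n_cols - 1)
            if coastal:
                dist[r, c] = 0
    changed = True
    while changed:
        changed = False
        for r in range(n_rows):
            for c in range(n_cols):
                if not sea[r, c]:
                    continue
                for rr, cc in [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]:
                    if 0 <= rr < n_rows and 0 <= cc < n_cols and sea[rr, cc]:
                        if dist[rr, cc] + 1 < dist[r, c]:
                            dist[r, c] = dist[rr, cc] + 1
                            changed = True
    return dist


class TestRegion:
    def test_all_sea_distance_measured_from_edge(self, region_all_sea):
        region = region_all_sea
        assert region.sea_mask.all()
        # closed form for an open 16x16 grid: distance to nearest edge
        r = np.arange(16)
        m = np.minimum(r, 15 - r)
        expected = np.minimum.outer(m, m)
        assert np.array_equal(region.coast_distance, expected)

    def test_seed_determinism(self):
        a = make_region(32, 32, 0.3, 1)
        b = make_region(32, 32, 0.3, 1)
        assert np.array_equal(a.sea_mask, b.sea_mask)
        assert np.array_equal(a.coast_distance, b.coast_distance)

    def test_coast_distance_matches_bfs_oracle(self, region32):
        oracle = bfs_oracle(region32.sea_mask)
        sea = region32.sea_mask
        assert np.array_equal(region32.coast_distance[sea], oracle[sea])
        assert region32.coast_distance[sea].max() == oracle[sea].max()

    def test_sea_single_connected_component(self, region32):
        from scipy import ndimage

        _, n_comp = ndimage.label(region32.sea_mask)
        assert n_comp == 1

    def test_coast_distance_finite_on_sea_infinite_on_land(self, region32):
        assert np.isfinite(region32.coast_distance[region32.sea_mask]).all()
        assert np.isinf(region32.coast_distance[~region32.sea_mask]).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_region(4, 4, 0.0, 1)
        with pytest.raises(ValueError):
            make_region(16, 16, 1.0, 1)


class TestStressors:
    def test_layer_count_and_bounds(self, region32):
        layers = simulate_stressors(region32, default_sector_configs(), seed=2)
        assert len(layers) == 45
        for layer in layers:
            assert layer.intensity.min() >= 0
            assert layer.intensity.max() <= 1
            assert (layer.intensity[~region32.sea_mask] == 0).all()

    def test_regionwide_positive_on_most_sea(self, region32):
        layers = simulate_stressors(
            region32, [SectorConfig("Climate", 3, "regionwide")], seed=2
        )
        sea = region32.sea_mask
        for layer in layers:
            assert (layer.intensity[sea] > 0).mean() >= 0.95

    def test_patchy_mostly_zero(self, region32):
        layers = simulate_stressors(
            region32, [SectorConfig("Fishing", 5, "patchy")], seed=2
        )
        sea = region32.sea_mask
        for layer in layers:
            assert (layer.intensity[sea] == 0).mean() > 0.5

    def test_shore_decay_decreases_offshore(self):
        region = make_region(64, 64, 0.0, seed=1)  # distances reach 31 cells
        layers = simulate_stressors(
            region, [SectorConfig("Coastal", 3, "shore_decay")], seed=1
        )
        sea = region.sea_mask
        d = region.coast_distance
        near = sea & (d <= 2)
        far = sea & (d >= 10)
        assert far.any()
        for layer in layers:
            assert layer.intensity[near].mean() >= layer.intensity[far].mean()

    def test_zero_intensity_scale_gives_zero_layers(self, region32):
        layers = simulate_stressors(
            region32, [SectorConfig("Marine", 2, "patchy", intensity_scale=0.0)], seed=4
        )
        for layer in layers:
            assert (layer.intensity == 0).all()

    def test_seed_determinism(self, region32):
        cfgs = default_sector_configs()
        a = simulate_stressors(region32, cfgs, seed=9)
        b = simulate_stressors(region32, cfgs, seed=9)
        for la, lb in zip(a, b):
            assert la.activity_id == lb.activity_id
            assert np.array_equal(la.intensity, lb.intensity)

    def test_invalid_sector_footprint_pairing_rejected(self):
        with pytest.raises(ValueError):
            SectorConfig("Climate", 2, "patchy")


class TestHabitats:
    def test_single_full_habitat(self, region32):
        (hab,) = simulate_habitats(region32, 1, 1.0, seed=0)
        assert np.array_equal(hab.presence.astype(bool), region32.sea_mask)

    def test_union_covers_sea(self, region32):
        habs = simulate_habitats(region32, 8, 0.2, seed=5)
        union = np.zeros(region32.shape, dtype=bool)
        for h in habs:
            assert set(np.unique(h.presence)) <= {0, 1}
            assert (h.presence[~region32.sea_mask] == 0).all()
            union |= h.presence.astype(bool)
        assert (union == region32.sea_mask).all()

    def test_realized_coverage_near_target(self):
        region = make_region(64, 64, 0.0, seed=1)
        habs = simulate_habitats(region, 10, 0.3, seed=3)
        realized = np.mean([h.presence[region.sea_mask].mean() for h in habs])
        assert 0.15 <= realized <= 0.45  # within +-50% of the target


class TestVulnerability:
    def test_zero_sparsity_all_positive(self):
        v = simulate_vulnerability(5, 6, 0.0, seed=2)
        assert (v.weights.to_numpy() > 0).all()

    def test_zero_fraction_matches_direct_count(self):
        v = simulate_vulnerability(3, 4, 0.5, seed=5)
        w = v.weights.to_numpy()
        assert (w >= 0).all()
        frac = (w == 0).sum() / 12
        assert frac == pytest.approx((w == 0).mean())
        assert 0.1 <= frac <= 0.9  # roughly the requested sparsity

    def test_every_stressor_has_positive_weight(self):
        v = simulate_vulnerability(4, 10, 0.9, seed=0)
        assert (v.weights.to_numpy() > 0).any(axis=0).all()

    def test_seed_determinism(self):
        a = simulate_vulnerability(6, 7, 0.4, seed=11)
        b = simulate_vulnerability(6, 7, 0.4, seed=11)
        assert a.weights.equals(b.weights)


class TestMCAs:
    @pytest.fixture
    def mcas(self, region32):
        return simulate_mcas(region32, 12, seed=3)

    def test_single_mca(self, region32):
        recs = simulate_mcas(region32, 1, seed=0)
        assert len({r.mca_id for r in recs}) == 1

    def test_required_variety(self, mcas):
        govs = {r.governance for r in mcas}
        assert "provincial" in govs and "federal" in govs
        by_id = {}
        for r in mcas:
            by_id.setdefault(r.mca_id, []).append(r)
        assert any(len(zones) > 1 for zones in by_id.values())
        assert any(r.footprint.area < 1 for r in mcas)

    def test_footprints_on_sea_and_disjoint(self, region32, mcas):
        union = np.zeros(region32.shape, dtype=bool)
        total = 0
        for r in mcas:
            mask = rasterize_footprint(region32, r.footprint)
            assert (mask <= region32.sea_mask).all()
            total += mask.sum()
            union |= mask
        # distinct MCAs never share cells, so the union count is the sum
        assert union.sum() == total
        covered = union.sum() / region32.sea_mask.sum()
        assert covered == pytest.approx(union[region32.sea_mask].mean())
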
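import numpy as np
import pytest

from cimnet import (
    HabitatLayer,
    StressorLayer,
    VulnerabilityMatrix,
    make_region,
)


@pytest.fixture(scope="session")
def region32():
    return make_region(32, 32, 0.3, seed=1)


@pytest.fixture(scope="session")
def region_all_sea():
    return make_region(16, 16, 0.0, seed=7)


def random_seascape(rng, n_rows=6, n_cols=6, n_activities=3, n_habitats=3):
    """Small random inputs for engine equivalence checks."""
    sectors = ["Climate", "Fishing", "Marine", "Coastal", "Land"]
    stressors = [
        StressorLayer(
            activity_id=f"a{i}",
            sector=sectors[i % 5],
            intensity=rng.random((n_rows, n_cols)),
        )
        for i in range(n_activities)
    ]
    habitats = [
        HabitatLayer(
            habitat_id=f"h{j}",
            presence=(rng.random((n_rows, n_cols)) < 0.6).astype(np.uint8),
        )
        for j in range(n_habitats)
    ]
    weights = rng.random((n_habitats, n_activities)) * 3
    weights[rng.random(weights.shape) < 0.3] = 0.0
    vuln = VulnerabilityMatrix.from_array(
        weights, [h.habitat_id for h in habitats], [s.activity_id for s in stressors]
    )
    return stressors, habitats, vuln


def naive_impact(stressors, habitats, vuln):
    """Reference triple-loop CI: independent of the vectorised engine."""
    shape = stressors[0].intensity.shape
    ci = np.zeros(shape)
    per_activity = {}
    for s in stressors:
        acc = np.zeros(shape)
        for r in range(shape[0]):
            for c in range(shape[1]):
                total = 0.0
                for h in habitats:
                    total += float(h.presence[r, c]) * vuln.weight(
                        h.habitat_id, s.activity_id
                    )
                acc[r, c] = s.intensity[r, c] * total
        per_activity[s.activity_id] = acc
        ci += acc
    return per_activity, ci
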
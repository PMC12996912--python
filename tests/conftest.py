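import numpy as np
import pandas as pd
import pytest

import corticov as cv


@pytest.fixture(scope="session")
def atlas68():
    return cv.make_atlas(34, rng_seed=7)


@pytest.fixture(scope="session")
def atlas4():
    """Tiny hand-built atlas: 2 regions per hemisphere."""
    c = np.array(
        [
            [-1.0, 0.0, 0.0],
            [-0.5, 0.5, np.sqrt(0.5)],
            [1.0, 0.0, 0.0],
            [0.5, 0.5, np.sqrt(0.5)],
        ]
    )
    c = c / np.linalg.norm(c, axis=1, keepdims=True)
    return cv.ParcelAtlas(
        region_names=("lA", "lB", "rA", "rB"),
        hemispheres=("L", "L", "R", "R"),
        centroids=c,
    )


@pytest.fixture(scope="session")
def connectome68(atlas68):
    return cv.simulate_connectome(atlas68, rng_seed=7)


@pytest.fixture(scope="session")
def cohort98(atlas68, connectome68):
    cohort, truth = cv.simulate_cohort(atlas68, connectome68, n_per_group=49, rng_seed=11)
    return cv.compute_dimensions(cohort), truth


@pytest.fixture(scope="session")
def residuals98(cohort98):
    cohort, _ = cohort98
    return cv.residualize(cohort)


@pytest.fixture(scope="session")
def spins300(atlas68):
    return cv.make_spins(atlas68, n_rot=300, rng_seed=5)


@pytest.fixture()
def toy_cohort_frame():
    """3-subject cohort table builder for a given atlas."""

    def _build(atlas, **overrides):
        n = overrides.pop("n", 3)
        rng = np.random.default_rng(overrides.pop("rng_seed", 0))
        tab = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "diagnosis": ["SCZ"] * n,
                "age": rng.uniform(21, 50, n),
                "sex": rng.integers(0, 2, n),
                "site": ["site1"] * n,
                "dose": rng.uniform(0, 10, n),
                "sans_avolition_apathy": rng.integers(0, 6, n),
                "sans_anhedonia_asociality": rng.integers(0, 6, n),
                "sans_alogia": rng.integers(0, 6, n),
                "sans_blunted_affect": rng.integers(0, 6, n),
                "saps_delusion": rng.integers(0, 6, n),
                "saps_hallucination": rng.integers(0, 6, n),
                "saps_bizarre_behavior": rng.integers(0, 6, n),
                "saps_formal_thought": rng.integers(0, 6, n),
                "hamd": rng.integers(0, 30, n),
            }
        )
        for name in atlas.region_names:
            tab[name] = 2.5 + 0.1 * rng.standard_normal(n)
        for key, val in overrides.items():
            tab[key] = val
        return tab

    return _build
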
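import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from methpanel.simulate import CohortConfig, generate_cohort, generate_reference

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_small():
    return generate_reference(
        n_islands=4, island_len=600, inter_island_len=400,
        xmai_density=4.0, bsthhi_density=8.0, seed=7,
    )


@pytest.fixture(scope="session")
def cohort_small(ref_small):
    specs = [
        ("GENE_01", 0.85, 0.15),
        ("GENE_02", 0.80, 0.20),
        ("GENE_03", 0.70, 0.30),
        ("GENE_04", 0.50, 0.50),
    ]
    cfg = CohortConfig(
        n_responders=15, n_nonresponders=10, marker_specs=specs,
        n_background_cpgs=60, seed=11,
    )
    betas, ann = generate_cohort(ref_small, cfg)
    return betas, ann, specs


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
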
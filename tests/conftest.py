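import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirscreen as ms

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel() -> ms.PanelDefinition:
    return ms.PanelDefinition()


@pytest.fixture(scope="session")
def small_fireplex():
    """A compact mouse cohort: 4 controls + 4 tumor animals, 3 timepoints x3."""
    cfg = ms.SyntheticConfig(
        n_control=4,
        n_tumor_per_group=4,
        groups=[("LineA", 500_000)],
        seed=11,
    )
    matrix, meta, out_panel = ms.simulate_fireplex_cohort(cfg)
    return cfg, matrix, meta, out_panel


@pytest.fixture(scope="session")
def small_human():
    """A compact sequencing cohort with the default signature effects."""
    cfg = ms.HumanCohortConfig(
        n_cancer=30, n_benign=30, n_healthy=30, n_extra_probes=30, seed=7
    )
    tpm, meta = ms.simulate_human_cohort(cfg)
    return cfg, tpm, meta


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
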
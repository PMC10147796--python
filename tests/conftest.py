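import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from ps6quant import CohortSpec, StainFieldSpec  # noqa: E402


@pytest.fixture(scope="session")
def small_field() -> StainFieldSpec:
    """Reduced synthetic field for fast simulation (96 px ~ 154 um square)."""
    return StainFieldSpec(image_shape=(96, 96), seed=0)


@pytest.fixture(scope="session")
def tiny_cohort_spec(small_field) -> CohortSpec:
    return CohortSpec(regions=("NDI", "TOp"), groups=("control", "trained"),
                      n_per_group=3, rois_per_region=2,
                      activation_multiplier={("trained", "NDI"): 2.0},
                      base_field=small_field, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
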
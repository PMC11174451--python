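import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sicmtools import (
    ApproachCurveParams,
    GrayImage,
    ScanConfig,
    SurfaceSpec,
    height_to_gray,
    make_surface,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def curve_params() -> ApproachCurveParams:
    return ApproachCurveParams()


@pytest.fixture(scope="session")
def scan_cfg() -> ScanConfig:
    return ScanConfig()


@pytest.fixture(scope="session")
def surface48():
    """The 48x48 five-feature reference topography (0-30 µm, seed 7)."""
    return make_surface(SurfaceSpec(shape=(48, 48), n_features=5,
                                    height_range=(0.0, 30.0), seed=7))


@pytest.fixture(scope="session")
def clean_gray48(surface48) -> GrayImage:
    return height_to_gray(surface48, 8, (0.0, 30.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
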
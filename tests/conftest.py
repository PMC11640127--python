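import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petgrow import PhantomSpec, Lesion, make_phantom, make_suite
from petgrow.segment import calibrate_stop_threshold

settings.register_profile(
    "petgrow",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("petgrow")


def random_region(rng: np.random.Generator, shape=(8, 8, 8),
                  fill: float = 0.5) -> np.ndarray:
    """Random non-empty boolean mask."""
    m = rng.random(shape) < fill
    if not m.any():
        m[tuple(d // 2 for d in shape)] = True
    return m


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One blurred noisy 20 mm sphere on a small grid (fast unit-test bed)."""
    spec = PhantomSpec(
        shape=(48, 48, 24),
        spacing=(4.0, 4.0, 5.0),
        lesions=[Lesion(center_mm=(98.0, 98.0, 62.5),
                        semiaxes_mm=(10.0, 10.0, 10.0), activity=4.0)],
        rng_seed=7,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def calibration_suite():
    return make_suite("calibration")


@pytest.fixture(scope="session")
def evaluation_suite():
    return make_suite("evaluation")


@pytest.fixture(scope="session")
def le_calibration(calibration_suite):
    phantoms = [(p.volume, p.truth_masks[0], p.seeds[0])
                for p in calibration_suite]
    return calibrate_stop_threshold(phantoms, "le")
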
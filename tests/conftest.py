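import numpy as np
import pytest
from hypothesis import settings

from swayrqa.io_sessions import CoPTrace
from swayrqa.synthetic_data import CohortSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_trace(rng: np.random.Generator, n: int = 1000, rate: float = 100.0,
               scale: float = 5.0) -> CoPTrace:
    """A seeded random-walk-free noise trace for exercising the measures."""
    return CoPTrace(
        time=np.arange(n) / rate,
        ap=rng.normal(0.0, scale, n),
        ml=rng.normal(0.0, scale, n),
        rate=rate,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def noise_trace(rng) -> CoPTrace:
    return make_trace(rng)


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """A scaled-down cohort for I/O and pipeline round-trip tests: short
    traces and blocks, but the full session structure."""
    return CohortSpec(
        n_subjects=2,
        duration=4.0,
        block_duration=2.0,
        n_trials=2,
        master_seed=99,
    )


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory, small_cohort_spec):
    from swayrqa.synthetic_data import gen_cohort

    out = tmp_path_factory.mktemp("cohort")
    gen_cohort(small_cohort_spec, out)
    return out
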
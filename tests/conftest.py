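import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aavsnap as av

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref():
    """Default 4700 nt synthetic reference."""
    return av.build_reference()


@pytest.fixture(scope="session")
def aligner(ref):
    return av.Aligner(ref)


@pytest.fixture(scope="session")
def toy_ref():
    """A 300 nt random sequence used as a minimal alignment target."""
    rng = np.random.default_rng(7)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=300)])


@pytest.fixture(scope="session")
def clean_pop_1k(ref):
    """Error-free 1000-read quota population with its classifications."""
    cfg = av.SimulationConfig(n_reads=1000, sub_rate=0.0, ins_rate=0.0,
                              del_rate=0.0, seed=11)
    reads, truth = av.simulate_population(ref, cfg)
    calls = av.classify_population(reads, ref)
    return reads, truth, calls


@pytest.fixture(scope="session")
def noisy_pop_10k(ref):
    """Default-error 10,000-read quota population with its classifications."""
    cfg = av.SimulationConfig(n_reads=10_000, seed=23)
    reads, truth = av.simulate_population(ref, cfg)
    calls = av.classify_population(reads, ref)
    return reads, truth, calls
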
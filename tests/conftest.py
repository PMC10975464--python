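import numpy as np
import pytest

from gelkin.kinetics import EinsteinMap, LogisticParams
from gelkin.ripening import standard_fluid


@pytest.fixture(scope="session")
def undersat_params() -> LogisticParams:
    """The undersaturated 1%-agar preset kinetics (sigmoidal rise)."""
    return LogisticParams.from_equilibrium(k1=1e-2, B_inf=0.2, B0=0.02)


@pytest.fixture(scope="session")
def supersat_params() -> LogisticParams:
    """Supersaturated start (exponential decay branch)."""
    return LogisticParams.from_equilibrium(k1=1e-2, B_inf=0.2, B0=0.45)


@pytest.fixture(scope="session")
def einstein30() -> EinsteinMap:
    return EinsteinMap(eta0=30.0, kE=2.5)


@pytest.fixture(scope="session")
def fluid():
    return standard_fluid()


def assert_monotone(values, decreasing: bool = False) -> None:
    """Monotone along the whole curve, strictly so through the transient.

    At double precision a fully converged logistic tail produces exactly
    constant samples, so strictness is only required over the first half.
    """
    d = np.diff(np.asarray(values, dtype=float))
    if decreasing:
        d = -d
    assert np.all(d >= 0)
    assert np.all(d[: d.size // 2] > 0)


def random_logistic_params(rng: np.random.Generator) -> LogisticParams:
    """Draw physically valid parameters spanning both saturation branches."""
    k1 = 10 ** rng.uniform(-3.5, -1.5)
    B_inf = rng.uniform(0.05, 0.5)
    s0 = rng.uniform(0.05, 0.45) if rng.random() < 0.5 else rng.uniform(1.2, 1.9)
    return LogisticParams.from_equilibrium(k1=k1, B_inf=B_inf, B0=s0 * B_inf)
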
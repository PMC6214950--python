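import numpy as np
import pytest

from hettasep.model import LatticeSpec, RateSet, build_random, fixture


@pytest.fixture(scope="session")
def fig4():
    """Figure-caption K=10 asymmetric heterogeneous rate set, p_i = 1."""
    rates, spec = fixture("fig4")
    return rates, spec


@pytest.fixture(scope="session")
def asym_k3():
    """Small fully asymmetric 3-lane rate set used across exact tests."""
    return RateSet(
        3,
        omega_up=np.array([0.2, 0.4, 0.6]),
        omega_down=np.array([0.3, 0.5, 0.7]),
        p=np.array([1.0, 1.0, 1.0]),
    )


@pytest.fixture(scope="session")
def random_ratesets():
    """100 seeded random rate sets of varying lane count, p_i = 1."""
    out = []
    for seed in range(100):
        K = 3 + seed % 8
        r = build_random(K, seed=seed)
        out.append(RateSet(K, r.omega_up, r.omega_down, np.ones(K)))
    return out


@pytest.fixture(scope="session")
def tiny_homog_spec():
    return LatticeSpec(K=3, L=2, N=3)
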
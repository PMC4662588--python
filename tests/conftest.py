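"""Shared fixtures: banks and the heavier simulations, computed once."""

import numpy as np
import pytest

import reedbank as rb
from reedbank.bank import KAPPA_MS2


@pytest.fixture(scope="session")
def wilson_2500():
    return rb.build_wilson_bank(2500.0, 0.014)


@pytest.fixture(scope="session")
def greenwood_k200():
    """The 201-oscillator bank at the reference coupling of the kHz runs."""
    return rb.build_greenwood_bank(kappa=200.0 * KAPPA_MS2)


@pytest.fixture(scope="session")
def greenwood_k400():
    return rb.build_greenwood_bank(kappa=400.0 * KAPPA_MS2)


@pytest.fixture(scope="session")
def spatial_response_k200(greenwood_k200):
    """Steady-state response of the 201-reed bank to parallel 1.75 kHz forcing."""
    return rb.solve_phasors(greenwood_k200, 1750.0)


@pytest.fixture(scope="session")
def impulse_traj_k200(greenwood_k200):
    """50 ms impulse run of the 201-reed bank (the heaviest shared input)."""
    return rb.simulate_impulse(greenwood_k200, 0.05)


@pytest.fixture(scope="session")
def wilson_forced_5s(wilson_2500):
    """Full 5 s switch-on run of the 21-reed bank at 50 Hz."""
    return rb.simulate_forced(wilson_2500, rb.DriveSpec(50.0, 5.0))


def random_bank(seed: int, n_max: int = 20) -> rb.ReedBank:
    """Small random bank with uniform coupling, for engine cross-checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    freqs = np.sort(rng.uniform(40.0, 60.0, size=n))[::-1]
    freqs += np.arange(n)[::-1] * 1e-6
    return rb.ReedBank(
        natural_freq_hz=freqs,
        gamma=float(rng.uniform(0.005, 0.05)),
        coupling=np.full(n - 1, float(rng.uniform(0.0, 5000.0))),
        f0=1000.0,
    )
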
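"""Shared fixtures: small synthetic networks and short sessions.

Everything is generated programmatically with fixed seeds; session layouts
are scaled down (shorter durations, smaller windows) where the operation
under test is generic in those sizes.
"""

import numpy as np
import pytest

from wbhopf import (
    BifurcationSchedule,
    Connectome,
    FrequencyTable,
    SimConfig,
    WindowSpec,
    make_connectome,
    make_frequencies,
)


@pytest.fixture(scope="session")
def small_net() -> Connectome:
    return make_connectome(8, density=0.4, seed=11)


@pytest.fixture(scope="session")
def small_freqs() -> FrequencyTable:
    return make_frequencies(8, seed=12)


@pytest.fixture(scope="session")
def short_cfg() -> SimConfig:
    """240-s session, 30-s burn-in: enough for several 30/10-s windows."""
    return SimConfig(duration=240.0, burn_in=30.0, seed=5)


@pytest.fixture(scope="session")
def short_spec() -> WindowSpec:
    return WindowSpec(length=30.0, step=10.0)


@pytest.fixture(scope="session")
def flat_schedule() -> BifurcationSchedule:
    return BifurcationSchedule(a0=0.07, t_inject=120.0, lam=0.0)


def rng_series(n_regions: int, n_samples: int, seed: int, tr: float = 2.0):
    """White-noise BOLD-like series for metric-level tests."""
    from wbhopf import BOLDLikeSeries

    rng = np.random.default_rng(seed)
    return BOLDLikeSeries(rng.standard_normal((n_regions, n_samples)), tr=tr)
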
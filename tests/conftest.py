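import numpy as np
import pytest

from bgsr import (
    KickStimulus,
    NoiseSpec,
    SRParams,
    supersample_and_smooth,
    sweep_P_vs_D,
)

# Monte-Carlo scale used by the slower end-to-end tests: 300 trials/point
# gives a binomial standard error below 0.03 everywhere, small against the
# asserted margins.
N_TRIALS = 300


@pytest.fixture(scope="session")
def params():
    return SRParams()


@pytest.fixture(scope="session")
def white_sweep_t1000(params):
    """Raw white-noise P-vs-D curve at T = 1000 on the default grid."""
    return sweep_P_vs_D(
        params, KickStimulus(T=1000), NoiseSpec("white", 0.0),
        n_trials=N_TRIALS, seed=11,
    )


@pytest.fixture(scope="session")
def white_smooth_t1000(white_sweep_t1000):
    return supersample_and_smooth(white_sweep_t1000, 9)


@pytest.fixture(scope="session")
def colored_sweep_t1000(params):
    """Raw colored-noise P-vs-D curve at T = 1000 on the default grid."""
    return sweep_P_vs_D(
        params, KickStimulus(T=1000), NoiseSpec("colored", 0.0),
        n_trials=N_TRIALS, seed=12,
    )


@pytest.fixture(scope="session")
def colored_smooth_t1000(colored_sweep_t1000):
    return supersample_and_smooth(colored_sweep_t1000, 15)
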
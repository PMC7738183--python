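import numpy as np
import pytest

from granulekit import synthetic, tirf


@pytest.fixture(scope="session")
def untreated():
    return synthetic.make_scenario("untreated", seed=1)


@pytest.fixture(scope="session")
def syt7_pop():
    return synthetic.make_scenario("syt7_only", seed=0).populations[0]


@pytest.fixture(scope="session")
def syt9_pop():
    return synthetic.make_scenario("syt9_only", seed=0).populations[0]


@pytest.fixture(scope="session")
def small_stack(untreated):
    """A 30-granule TIRF stack with ground truth, shared across tests."""
    stack, truth = synthetic.simulate_stack(
        untreated, calcium_um=100.0, shape=(128, 128), n_granules=30, seed=7
    )
    return stack, truth


def noisy_event_trace(pop, seed, noise_sd=20.0, n_frames=400, dt=0.05):
    """One noisy two-step event trace with its ground truth."""
    rng = np.random.default_rng(seed)
    onset = float(rng.integers(40, 120)) * dt
    ev = synthetic.event_params(pop, onset_s=onset)
    values, truth = synthetic.simulate_trace(ev, dt, n_frames, noise_sd=noise_sd, seed=seed)
    return tirf.IntensityTrace(values, dt, (0.0, 0.0)), truth
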
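import numpy as np
import pytest

import painsync as ps


@pytest.fixture(scope="session")
def small_population():
    """20-neuron population with moderate ensemble co-activation."""
    cfg = ps.PopulationSimConfig(n_neurons=20, duration_s=150.0,
                                 frame_rate_hz=1.5, background_rate_hz=0.03,
                                 ensemble_rate_hz=0.08,
                                 participation_prob=0.7, noise_sd=0.5,
                                 seed=7)
    tm, gt = ps.gen_population_traces(cfg)
    return cfg, tm, gt


@pytest.fixture(scope="session")
def small_dff(small_population):
    _, tm, _ = small_population
    dff = ps.compute_dff(tm)
    activity = ps.detect_active(dff)
    return dff, activity


def brute_force_pearson(a, b):
    """Direct-summation Pearson oracle, no library calls."""
    a = list(map(float, a))
    b = list(map(float, b))
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return cov / (va * vb) ** 0.5


@pytest.fixture
def rng():
    return np.random.default_rng(0)
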
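import numpy as np
import pandas as pd
import pytest

from cyanoclock.containers import ExpressionMatrix
from cyanoclock.synthetic import (
    default_clock_spec,
    gen_clock_profiles,
    make_schedule,
)


@pytest.fixture(scope="session")
def schedule():
    """The study design: three 12 h L/D cycles + 24 h LL, 4 h sampling."""
    return make_schedule(3, 24.0, 4.0)


@pytest.fixture(scope="session")
def clock(schedule):
    """Noisy 12-gene clock matrix on the default schedule (fixed seed)."""
    return gen_clock_profiles(default_clock_spec(11, schedule=schedule))


@pytest.fixture(scope="session")
def clean_clock(schedule):
    """Noise-free clock matrix (exact sinusoids)."""
    return gen_clock_profiles(default_clock_spec(11, noise_sd=0.0, schedule=schedule))


def expr_from_array(values, times=None, experiment="E1", split="train"):
    """Build a minimal single-experiment ExpressionMatrix from a 2-D array."""
    values = np.atleast_2d(np.asarray(values, float))
    n_genes, n_samples = values.shape
    times = np.arange(n_samples, dtype=float) if times is None else np.asarray(times, float)
    ids = [f"s{i:03d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "time_h": times,
            "condition": "LL",
            "experiment": experiment,
            "split": split,
        },
        index=ids,
    )
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=ids)
    return ExpressionMatrix(frame, samples)
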
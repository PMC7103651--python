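import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import icpscreen as ic

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240331)


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy two-level cohort, small enough for per-test reuse."""
    params = ic.SimParams(n_pairs=20, n_module=20, n_null=60,
                          sigma=0.5, rng_seed=7)
    return ic.simulate_cohort(params)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """sigma=0 cohort whose module contains only ICPs + planted candidates."""
    params = ic.SimParams(n_pairs=20, n_module=9, n_null=60,
                          sigma=0.0, rng_seed=11)
    return ic.simulate_cohort(params)


@pytest.fixture
def tiny_matrix():
    df = pd.DataFrame(
        [[0.0, 1.0], [2.0, 3.0]],
        index=["G1", "G2"], columns=["S1", "S2"])
    return ic.ExpressionMatrix(df)


def make_sample_table(n_pairs: int) -> ic.SampleTable:
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append((f"T{i}", f"P{i}", "tumor", f"P{i}", ""))
        rows.append((f"N{i}", f"P{i}", "normal", f"P{i}", ""))
    return ic.SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue", "pair_id", "stage_group"]))


@pytest.fixture
def paired_samples():
    return make_sample_table(4)
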
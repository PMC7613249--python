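import numpy as np
import pandas as pd
import pytest

from lipidmr.simulate import (SimulationParams, simulate_cohort,
                              simulate_summary_stats, simulate_two_sample)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest confounded cohort shared by read-only tests."""
    params = SimulationParams(n_individuals=4000, n_variants=40, seed=11)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def clean_summary():
    """A clean (no-pleiotropy) harmonized summary set, truth beta = 0.5."""
    return simulate_summary_stats(n_variants=50, causal_beta=0.5, seed=7)


@pytest.fixture(scope="session")
def two_sample_sets():
    """Full individual-level two-sample summary statistics (smaller sizes
    than the defaults to keep the suite fast)."""
    params = SimulationParams(n_variants=60, causal_beta=0.5, seed=19)
    exp_sum, out_sum, variants = simulate_two_sample(
        params, n_exposure=40000, n_outcome=12000, seeds=(5, 6))
    return exp_sum, out_sum, variants, params
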
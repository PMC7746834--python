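import numpy as np
import pytest

from msatpop.simdata import SimConfig, simulate_population


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulated dataset shared across tests."""
    truth, reps, sex_calls, loci = simulate_population(SimConfig(seed=7))
    return dict(truth=truth, reps=reps, sex_calls=sex_calls, loci=loci)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation: every replicate equals the true genotype."""
    cfg = SimConfig(seed=11, p_ado=0.0, p_fa=0.0, p_amp_fail=0.0)
    truth, reps, sex_calls, loci = simulate_population(cfg)
    return dict(truth=truth, reps=reps, sex_calls=sex_calls, loci=loci)
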
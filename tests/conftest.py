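import pytest

from surrobayes import MCMCSettings, PriorConfig, SimulationConfig, simulate_meta_dataset


@pytest.fixture(scope="session")
def mixed_dataset():
    """7 RCT + 4 cRWE + 2 sRWE studies at the default (mCRC-like) truth."""
    cfg = SimulationConfig(seed=5)
    return [s.effect for s in simulate_meta_dataset(cfg)]


@pytest.fixture(scope="session")
def rct_dataset(mixed_dataset):
    return [e for e in mixed_dataset if e.design == "RCT"]


@pytest.fixture()
def fast_mcmc():
    """Short chains for functional tests (not for reported estimates)."""
    return MCMCSettings(n_iter=2500, n_burnin=800, n_chains=1, seed=7)


@pytest.fixture()
def fixed_rho_priors():
    return PriorConfig().with_rho_w_fixed(0.52)
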
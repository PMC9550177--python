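import numpy as np
import pytest

from kappavelo import kinetics as kin
from kappavelo import simulate


@pytest.fixture(scope="session")
def two_branch_gene():
    """Noiseless cells on both branches of a beta=1 phase portrait."""
    rng = np.random.default_rng(0)
    params = kin.GeneParams(alpha=3.0, beta=1.0, gamma=0.6, t_switch=2.5)
    n = 300
    k = rng.integers(0, 2, n)
    tau_up = rng.uniform(0, 2.5, n)
    tau_dn = rng.uniform(0, 4.0, n)
    u = np.where(k == 1, kin.unspliced_at(params, tau_up, 1), kin.unspliced_at(params, tau_dn, 0))
    s = np.where(k == 1, kin.spliced_at(params, tau_up, 1), kin.spliced_at(params, tau_dn, 0))
    return {"params": params, "u": u, "s": s, "k": k}


@pytest.fixture(scope="session")
def small_sim():
    """A small noiseless trajectory simulation shared across tests."""
    rates = simulate.sample_gene_rates(20, (1.0, 10.0), rng_seed=7, shared_beta=True)
    adata, truth = simulate.simulate_cells(rates, n_cells=200, noise_sd=0.0, rng_seed=8)
    return adata, truth
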
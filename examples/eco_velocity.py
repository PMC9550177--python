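"""Heuristic velocities from mutual nearest neighbours across modalities.

When splicing and degradation rates are shared across genes, a cell's
unspliced profile is proportional to its own spliced profile one
degradation time later -- so the future state can be looked up directly by
matching U against S, with no rate fitting at all.
"""

import warnings

import numpy as np

from kappavelo import eco, processing, projection, simulate

# shared-rate regime: the heuristic's assumption holds exactly
rates = simulate.sample_gene_rates(30, (1.0, 1.0), rng_seed=7, shared_splicing=True)
adata, truth = simulate.simulate_cells(rates, n_cells=500, noise_sd=0.0, rng_seed=8)

diag = eco.future_state_check(truth.U_clean, truth.S_clean, truth.scaled_beta, truth.scaled_gamma)
print(f"shared-rate future-state identity holds: {diag.passed} "
      f"(max per-gene error {diag.per_gene_error.max():.2e})")

U_norm, S_norm = processing.eco_normalise(adata)
mnn = eco.mutual_nearest_neighbors(U_norm, S_norm, k=5)
arrows, _ = projection.pca_project(adata.layers["spliced"], adata.layers["true_velocity"])
start, end, has = eco.eco_arrows(mnn, arrows.start, scale=1.0)
cos, _ = projection.evaluate((end - start)[has], arrows.delta[has])
print(f"cells with mutual neighbours: {has.sum()}/{len(has)}")
print(f"median cosine of arrow directions to true velocity directions: {np.nanmedian(cos):.3f}")

# heterogeneous rates: the documented failure mode
rates_h = simulate.sample_gene_rates(30, (1.0, 15.0), rng_seed=9)
_, truth_h = simulate.simulate_cells(rates_h, n_cells=300, noise_sd=0.0, rng_seed=10)
diag_h = eco.future_state_check(truth_h.U_clean, truth_h.S_clean, truth_h.scaled_beta, truth_h.scaled_gamma)
print(f"with heterogeneous rates the diagnostic reports failure: passed={diag_h.passed}")
print("A high median cosine under shared rates, and an explicit failure flag")
print("otherwise, is exactly the operating envelope of the heuristic.")
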
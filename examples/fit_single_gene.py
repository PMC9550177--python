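"""Fit the phase-portrait kinetics of one gene and compare with truth.

The fit recovers the beta = 1 member of the gene's rate family: alpha and
gamma are identified only relative to beta, because jointly rescaling all
rates and time leaves the u-s curve unchanged.
"""

import numpy as np

from kappavelo import fit, kinetics

# a gene with a transcriptional switch: induction for t < 2.5, then shutdown
params = kinetics.GeneParams(alpha=3.0, beta=1.0, gamma=0.6, t_switch=2.5)
rng = np.random.default_rng(0)
n = 300
phase = rng.integers(0, 2, n)
tau = np.where(phase == 1, rng.uniform(0, 2.5, n), rng.uniform(0, 4.0, n))
u = np.where(phase == 1, kinetics.unspliced_at(params, tau, 1), kinetics.unspliced_at(params, tau, 0))
s = np.where(phase == 1, kinetics.spliced_at(params, tau, 1), kinetics.spliced_at(params, tau, 0))

result = fit.fit_gene_em(u, s)

print(f"alpha: fitted {result.alpha:.4f}  true {params.alpha}")
print(f"gamma: fitted {result.gamma:.4f}  true {params.gamma}")
print(f"m:     fitted {result.m:.4f}  true 1 (no unspliced undercount here)")
u_sw = float(kinetics.unspliced_at(params, params.t_switch, 1))
print(f"switch point u: fitted {result.u_switch:.4f}  true {u_sw:.4f}")
print(f"phase assignments correct: {(result.k == phase).mean():.1%}")
print(f"mean log-likelihood: {result.log_likelihood:.2f} (comparable across genes)")
print("Fitted values match the generating kinetics because the noiseless")
print("cells lie exactly on the two-branch portrait curve.")
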
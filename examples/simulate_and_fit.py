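"""Simulate a low-coverage full-sibling pair and re-estimate its relatedness.

Generates genotype likelihoods for two full siblings (expected relatedness
coefficients k = (0.25, 0.5, 0.25)) at 4x coverage on a thinned genome-wide
map, fits (k0, k1, k2, alpha) by maximum likelihood, and compares the
estimate with the truth and with the realized IBD fractions of the simulated
path (the quantity the data actually contain).
"""

import numpy as np

from ibdpair import genome_config, simulate
from ibdpair.estimation import fit

cfg = genome_config("full_siblings", depth=4.0, seed=1, n_sites=20_000)
sim = simulate(cfg)

realized = np.bincount(sim.truth_path, minlength=3) / len(sim.truth_path)
result = fit(sim.pair, sim.sites, seed=1)
p = result.params_hat

print(f"truth     k = (0.250, 0.500, 0.250)   alpha = {cfg.params.alpha:.1f}/Morgan")
print(f"realized  k = ({realized[0]:.3f}, {realized[1]:.3f}, {realized[2]:.3f})")
print(f"estimated k = ({p.k0:.3f}, {p.k1:.3f}, {p.k2:.3f})   alpha = {p.alpha:.2f}/Morgan")
print(f"log-likelihood {result.loglik_hat:.1f} from {result.n_restarts_used} restarts")
print()
print("The estimate tracks the realized fractions: with ~35 Morgans of genome")
print("the realized IBD proportions of one sibling pair wander a few percent")
print("around their pedigree expectation, and that is the recoverable signal.")
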
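"""Decode local IBD state along the genome and call segments.

Fits a half-sibling pair at 2x coverage, runs posterior decoding, extracts
IBD tracts with a 0.95 posterior cutoff, and reports how well the decoded
path matches the simulated truth.
"""

import numpy as np

from ibdpair import (
    call_segments_posterior,
    compare_assignments,
    emission_matrix,
    genome_config,
    simulate,
)
from ibdpair.estimation import fit
from ibdpair.hmm_engine import decode

cfg = genome_config("half_siblings", depth=2.0, seed=3, n_sites=20_000)
sim = simulate(cfg)

result = fit(sim.pair, sim.sites, seed=1)
dec = decode(emission_matrix(sim.pair, sim.sites), sim.sites, result.params_hat)
segs = call_segments_posterior(dec.posteriors, sim.sites, cutoff=0.95)

metrics = compare_assignments(dec.viterbi_path, sim.truth_path)
assigned = sum(s.n_sites for s in segs)
print(f"Viterbi accuracy vs simulated truth: {metrics['accuracy']:.3f}")
print(f"{len(segs)} segments cover {assigned} of {len(sim.sites)} sites at cutoff 0.95")
print()
print("First five segments (BED-style half-open coordinates):")
for s in segs[:5]:
    span_cm = (s.end - s.start) / 1e6  # 1 cM/Mb map
    print(
        f"  {s.chrom}:{s.start}-{s.end}  state {s.state}  "
        f"{s.n_sites} sites  ~{span_cm:.1f} cM  mean posterior {s.mean_posterior:.3f}"
    )
print()
print("State 1 tracts are genomic stretches where the pair shares one allele")
print("IBD; unassigned gaps are sites whose posterior confidence fell below 0.95.")
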
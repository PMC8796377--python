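# Methods

## The model

For a non-inbred pair of diploids, the IBD state at locus `l`,
`X_l ∈ {0, 1, 2}`, counts alleles shared identical by descent. `X` is
modelled as a continuous-time Markov chain in genetic distance with
generator

```
Q = α · ⎡ −k1      k1        0  ⎤
        ⎢  k0    −(k0+k2)    k2 ⎥
        ⎣  0       k1       −k1 ⎦
```

`R = (k0, k1, k2)` is both the stationary distribution and the genome-wide
expected fraction of loci in each state; `α > 0` (per Morgan) sets how fast
the state switches. Direct 0↔2 jumps are excluded — losing or gaining two
shared alleles at one point requires two recombination events. The spectrum
of `Q` is `{0, −α·k1, −α}`, so the chain decorrelates over distances of
order `1/(α·k1)`.

Conditional on `X_l` and the allele-A frequency `f_l`, the genotype pair
(counting copies of allele A) is:

* individual *i*: Hardy–Weinberg, `((1−f)², 2f(1−f), f²)`;
* individual *j* given `gi`: Hardy–Weinberg again for `X=0`; equal to `gi`
  for `X=2`; for `X=1`, one allele of *j* is a uniformly chosen allele of
  *i* and the other is a fresh population draw.

These conditionals form a proper, exchangeable joint law: the 9-entry joint
genotype distribution sums to 1 and is symmetric in the two individuals for
every `f` and `X` (both properties are tested on a grid). Sequencing data
enter only via genotype likelihoods `P(D | G)`, so per-site emissions are
9-term sums weighted by the pair's two GL triples. Sites are assumed
independent given `X` (no LD), and frequencies are treated as known.

## Inference

* **Likelihood**: scaled forward algorithm; per-site normalisation with
  stored log scale factors, whose sum is the log-likelihood (exact for
  chains of any length; no underflow at `L ~ 10⁶`).
* **Estimation**: `(R, α)` are mapped to `ℝ³` by
  `(log k1/k0, log k2/k0, log α)` and maximised by BFGS with
  central-difference gradients (step `1e-5` in transformed space,
  gradient-norm tolerance `1e-5`, max 500 iterations). The panel of start
  points — the five canonical relationship configurations crossed with
  `α ∈ {0.01, 0.1, 1}` — is scored once and BFGS is run from the three
  best-scoring points; the best optimum is kept and is never worse than any
  start point. Any of `k0, k1, k2, α` may be held fixed; the free simplex
  mass is then reparametrised with fewer logits.
* **Decoding**: posterior decoding by scaled forward–backward, Viterbi in
  log space with ties broken toward the lower state index (deterministic
  output). Segment calling run-length encodes either the Viterbi path or the
  posterior argmax restricted to sites whose maximum posterior reaches a
  cutoff (default 0.95; sites below the cutoff are unassigned and break
  runs). Output coordinates are BED-style 0-based half-open spans from the
  first to the last member site — segments are never extrapolated over
  unobserved flanking gaps, which users can post-process if midpoints are
  preferred.

### Numerical choices

* `exp(Q·d)` by eigendecomposition (batched over the deduplicated distance
  set), falling back to scipy's scaling-and-squaring when the eigenvector
  matrix is ill-conditioned (near-degenerate spectrum, e.g. `k1 → 1`).
  Entries are clamped to `[0, 1]` and rows renormalised provided the row sum
  is within `1e-9` of 1; a larger discrepancy is a hard error.
* `k` components (and `α`) are floored at `1e-8` and renormalised before
  building `Q`, so boundary relationships such as parent–offspring
  (`k0 = k2 = 0`) keep the chain irreducible; reported estimates may still
  round to the boundary.
* Chromosomes are independent: the chain restarts from `R` at the first
  site of each chromosome (equivalent to `d = ∞`). One global `(R, α)` is
  fitted across all chromosomes jointly.
* Genetic distance per site comes from physical positions via a constant
  rate (default 1 cM/Mb) or a user-supplied cumulative genetic map with
  linear interpolation (terminal slopes extrapolate beyond the mapped
  range); `α` is therefore per Morgan. The forward pass recomputes
  transitions per likelihood evaluation but exponentiates each *distinct*
  distance once — thinned data repeat few gap values.
* Genotype coding counts copies of beagle `allele1`, and the frequency file
  refers to that same allele; a flag accepts log10-scaled GLs. Missing data
  are all-equal GL triples and need no special-casing. All inference is
  invariant to rescaling any site's GL triple by a positive constant.

## The synthetic-data generator

`simulate` draws, in order: site grid and frequencies (uniform on
[0.05, 0.95] by default), an IBD path from the CTMC (stationary start per
chromosome), genotypes from the conditional law above, and reads as
`c ~ Poisson(depth)` with each read reporting allele A with probability
`1−err`, `½`, `err` for genotypes 2, 1, 0; GLs are the exact binomial
likelihoods of those counts (uninformative at `c = 0`). A master seed is
split into independent substreams per stage, so e.g. the same path can be
re-sequenced at a different depth.

**Default study conditions** (`genome_config`): 20,000 sites on 22
chromosomes at one site per 175 kb under a 1 cM/Mb map — roughly the human
autosomes (~35 Morgans) at the marker density left after LD thinning — with
per-base error 0.01 and a single switch rate `α = 4`/Morgan for all
relationship classes. That rate is the crossover-driven switch rate of a
half-sib pair and the low end of the full-sib range; it gives mean tract
lengths of 33–50 cM. The genome scale matters in both directions: estimates
of `R` can only be as close to the pedigree expectation as the pair's
*realized* IBD fractions (standard deviation `≈ √(2k(1−k)/(rate·T))` for
genome length `T`), while Viterbi errors are dominated by tract-boundary
localisation (~20 sites per boundary at 4× with these frequencies), which
grows with the number of tracts. 20,000 sites over 35 Morgans with `α = 4`
leaves comfortable room on both sides, and keeps one maximum-likelihood fit
at a fraction of a second so the full five-relationships × three-depths ×
ten-replicates sweep runs in about a minute.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: LD between sites (the model's own assumption, so
self-consistency is what is being tested), crossover-interference or
pedigree-realistic tract-length distributions (paths come from the fitted
CTMC, not from meioses), frequency misspecification (truth frequencies are
handed to the model), population structure, and non-uniform or biased
sequencing error. Robustness to those belongs to evaluation on real data,
not to this test bed.

## Known limitations

* Inbred individuals need the 9-state condensed-identity extension; this
  implementation is strictly 3-state/non-inbred.
* `α̂` is mildly biased upward at very low depth (noise absorbs into
  apparent switching); `R̂` is not noticeably affected in the tested range.
* Estimation error in `R` is bounded below by realized-path fluctuation:
  on short genomes (or single chromosomes) estimates track the realized IBD
  fractions, not the pedigree expectation.
* No standard errors or likelihood-ratio relationship tests are provided.
* Frequencies are plug-in values; their estimation error (EM from GLs) is
  not propagated into the IBD posteriors.
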
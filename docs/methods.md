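# Methods

## The problem

High-throughput evidence for protein–protein interactions (PPIs) arrives
from heterogeneous sources — ortholog interactions, coexpression, shared
domains, functional annotation — each summarised per protein pair as a
likelihood-ratio (LR) score. The classical integration rule, naive Bayes,
multiplies the per-source LRs and a prior odds ratio and calls a pair
interacting when the posterior odds exceed 1. Because every source enters
with equal weight, a single biased or noisy source can overturn the
combined call, and reported false-positive rates for such pipelines run
from 50% to 85%.

This package implements a nonparametric Bayes latent-class alternative
(NBEL, nonparametric Bayes ensemble learning) that *learns* each source's
interacting and non-interacting score distributions and thereby weights
sources by how well the two distributions separate, together with the
naive-Bayes and logistic-regression baselines and a simulation benchmark
with controlled label-reversal contamination.

## Model

Let `Y` be the n×p matrix of scores (pairs × sources), column-standardised,
and `z_i ∈ {0,1}` the latent interaction status of pair i with prior
probability ν. Scores are modelled by a truncated stick-breaking mixture
shared across sources:

    y_ij | z_i, comp_i = h  ~  Normal(μ_{h,z_i,j}, 1/τ_h)
    μ_{h,1,j} = μ_{h,0,j} + δ_{hj},   δ_{hj} ≥ 0
    comp_i ~ Categorical(π),  π from stick-breaking with concentration α

The nonnegative offsets δ enforce stochastic ordering per source — the
interacting score distribution f_1j places at least as much mass above any
threshold as f_0j — which identifies the direction of the labels. Component
weights π_h and precisions τ_h are shared across sources and statuses; only
the locations carry the (component, status, source) structure. The pair-level
posterior interaction probability is

    P(z_i=1 | y_i) = ν Π_j f_1j(y_ij) / [ν Π_j f_1j(y_ij) + (1−ν) Π_j f_0j(y_ij)]

evaluated in log space. A source whose f_0j ≈ f_1j contributes a flat
likelihood ratio and drops out of the product automatically — this is the
mechanism by which uninformative or corrupted sources are down-weighted.
Because the learned f's are mixtures, the per-source log likelihood ratio is
*bounded* (a score deep in the "wrong" region meets the minority mode rather
than a Gaussian tail), so a single corrupted source casts a bounded negative
vote instead of vetoing the pair: classification degrades gracefully, like a
majority vote over informative sources.

Priors: μ_{h0j} ~ N(μ₀, 1/κ); δ_{hj} ~ half-Normal(0, a_delta_var) per
(h, j); τ_h ~ Gamma(a_τ, b_τ) (shape/rate); ν ~ Beta(a_ν, b_ν) unless fixed;
stick fractions V_h ~ Beta(1, α), V_H = 1.

### Default hyperparameters

All on column-standardised scores:

| parameter | default | role |
|---|---|---|
| H | 20 | truncation level (components); doubling it leaves results unchanged |
| α | 1.0 | stick-breaking concentration |
| μ₀, κ | 0, 1 | baseline-location prior centre / precision |
| a_τ, b_τ | 1, 1 | precision prior (vague around 1) |
| a_delta_var | 4.0 | offset prior variance: offsets are group separations, O(1–3) on standardised scores, so the half-normal uses sd 2 — a unit-variance prior over-shrinks the ordered explanation and can leave chains in a weakly-identified mode with δ ≈ 0 and near-random labels |
| a_ν, b_ν | 1, 1 | uniform hyperprior on the interaction proportion |
| n_iter / n_burn | 5000 / 1000 | chain length / burn-in (library default; the benchmark uses 600/100) |

## Posterior computation

A blocked Gibbs sampler on the truncated representation; each sweep updates
(1) allocations comp_i | z (multinomial), (2) statuses z_i | comp_i,
recording P(z_i=1 | …) before sampling — the Rao-Blackwellised quantities
whose post-burn-in average is the reported posterior probability — then
conjugate blocks for (3) sticks, (4) baseline locations, (5) offsets
(normal truncated below zero, inverse-CDF with 1e-12 tail clamping),
(6) precisions, and (7) ν.

Two numerical choices matter in practice and were settled by experiments
recorded here as the package's design:

* **Initialization.** Chains start deterministically from a moment-matched
  split: statuses from the mode-separating (variance-minimising) threshold
  of the row sums, locations/offsets/precision from that split's group
  moments, allocations cycling over components. A median split (which
  forces a 50% interacting start) biases ν through the burn-in and, at
  contaminated levels, can feed a degenerate mode in which ν drifts toward
  0 or 0.5 and the offsets die; the informed start removes this failure
  across all tested conditions.
* **Status update conditions on the allocation.** Updating z_i given
  comp_i (rather than with the allocation marginalised out) makes small,
  local moves; combined with the informed start it keeps every chain in
  the ordered, well-identified region. The marginalised variant mixes
  faster nominally but let a minority of chains spiral into ν-collapse on
  contaminated data.
* **Multi-chain averaging.** The benchmark estimator averages the
  Rao-Blackwellised probabilities of two independent chains (`n_chains=2`),
  the standard guard against one chain lingering in a minor mode; it
  roughly halves replicate-to-replicate variance at contaminated levels.

Classification applies the 0–1-loss Bayes rule `ẑ_i = 1(p̂_i > 0.5)`; ties
classify non-interacting. The "alternative threshold" (used for naive
Bayes, whose score scale is uncalibrated) is the two-class within-variance
minimising cut over all midpoints of consecutive sorted values — an
Otsu-style criterion on raw values, binning-free and deterministic; for
naive Bayes it is applied to log final scores.

## Synthetic-data generator

`simulate.SimDesign` draws one latent component per pair (shared across
sources, exactly as the fitted model assumes) and then per-source normal
scores with mean `mean0_hj + z_i·δ_hj`. The frozen default design — a
synthetic stand-in, since no canonical parameter table exists for this
kind of benchmark — uses 5000 pairs (1250 interacting; the benchmark
scales to 1000/250), four sources and two equally weighted components:

* sources 1–3: baseline −0.5, offset 1.62, sds 0.55 / 0.65 by component
  (separations ≈ 2.9 and 2.5 within-group sds — substantial overlap);
* source 4: baseline 0, offset 0.55, sds 2.30 / 2.69 — weakly informative
  with large dispersion, the kind of source an unweighted LR product
  cannot discount but an adaptive method shrinks away.

Contamination emulates error-prone sources: per source independently, a
planned number of interacting and non-interacting pairs have that source's
score redrawn from the opposite-status mixture (levels 1–5 reverse
2/4/8/16/32% of each group per source; the induced error rate — the mean of
the fractions of each group affected in ≥1 source — then spans ≈8% to
≈79%). True labels never change. Redrawing from the opposite-status
distribution (rather than negating) is the only reversal consistent with
the generative model.

What the generator does **not** emulate: dependence between sources beyond
the shared latent class (real annotation and domain evidence share
information), heavy-tailed or discrete LR distributions, and missing
scores. Passing benchmarks therefore demonstrate the adaptive-weighting
mechanism under the model family's own assumptions, not performance on any
particular real pipeline's LR tables.

The benchmark protocols:

* **NBEL**: column-standardise, two 600-sweep chains (100 burn-in), 0.5
  threshold, ν learned (or fixed when stated).
* **Naive Bayes**: row sum of scores (the log of the LR product), cut at
  the alternative threshold.
* **Logistic regression**: trained on the *apparent* labels (reversed for
  any pair affected in ≥1 source) of a random 3% subset of pairs — the
  scale of curated gold-standard overlaps (≈2% of the 79k-pair human set) —
  ridge-stabilised, threshold 0.5.

Misclassification is the mean of the false-positive and false-negative
rates, weighting the two error types equally regardless of the 1:3 class
imbalance.

## Behaviour under the benchmark (recomputed by `scripts/acceptance.py`)

On clean data NBEL sits near 1–2% misclassification, below logistic
(~2–3%) and far below naive Bayes (~17%, dragged by the noisy fourth
source); the posterior mean of ν recovers 0.25 within ±0.02. At ~28%
induced error NBEL holds near 9–10% while naive Bayes reaches ~21% and
logistic ~14–18%. At ~79% induced error all methods deteriorate; NBEL
stays near 33–35%.

## Known limitations

* At extreme contamination (level V) this implementation remains clearly
  better than random (~0.33–0.35). A sampler without the informed start
  and local status update instead drifts to a degenerate mode and
  classifies near-randomly (~0.5) there, in which case pinning ν at its
  true value recovers several points; with the scheme adopted here the
  unknown-ν chain does not degenerate and fixing ν = 0.25 brings no
  further gain (~0.35). The acceptance check that expects near-random
  behaviour with a fixed-ν rescue therefore fails by construction and is
  left failing rather than degrading the sampler to reproduce it.
* Short chains with an informed start trade exploration for stability:
  posterior uncertainty in the mixture structure is under-represented
  (probabilities are averaged conditionals, not a full exploration of
  label-switching modes). For point classification this is immaterial.
* Conditional independence of sources given (z, comp) is assumed
  throughout, as in the model the package implements.
* The per-(h, j) offset prior treats sources symmetrically; a hierarchical
  (shared-across-sources) offset scale was not explored.
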
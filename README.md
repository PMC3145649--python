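# nbel — nonparametric Bayes ensemble learning for PPI prediction

`nbel` predicts protein–protein interactions (PPIs) by integrating
likelihood-ratio (LR) evidence from multiple genomic data sources —
ortholog interactions, coexpression, shared domains, functional annotation
and the like. It is aimed at computational biologists who have a table of
per-pair, per-source scores and want interaction calls that are robust to
biased, noisy or contaminated evidence sources, plus the two classical
baselines (naive-Bayes LR multiplication and logistic regression) and a
simulation benchmark for stress-testing all three.

## The model in brief

For pair *i* with latent status *z_i* ∈ {0,1} (interacting or not) and
score *y_ij* from source *j*,

  y_ij | z_i  ~  f_{z_i, j},   with  f_0j ≤st f_1j,

each density an H-component Gaussian mixture with shared stick-breaking
weights π_h and precisions τ_h, and ordered locations
μ_{h1j} = μ_{h0j} + δ_{hj}, δ_{hj} ≥ 0 (a truncated restricted dependent
Dirichlet process construction). The posterior interaction probability

  P(z_i = 1 | y_i) = ν Π_j f_1j(y_ij) / [ν Π_j f_1j(y_ij) + (1−ν) Π_j f_0j(y_ij)]

is estimated by a blocked Gibbs sampler, Rao-Blackwellised over the chain.
Sources whose two learned densities barely separate contribute a flat
likelihood ratio and are automatically down-weighted — unlike naive Bayes,
which multiplies every source's LR at full strength. Pairs are called
interacting when the averaged posterior probability exceeds 0.5 (the
0–1-loss Bayes rule).

## Worked example

Simulate a contaminated four-source benchmark data set, fit the model, and
score the calls against the simulation truth:

```
$ nbel simulate --n-pairs 1000 --n-interacting 250 -p 4 \
      --contamination-level 3 --seed 11 --out pairs.tsv
induced error rate: 28.93%
wrote 1000 pairs x 4 sources to pairs.tsv

$ nbel fit --input pairs.tsv --config cfg.yaml --seed 11 --out posterior.tsv
fit 1000 pairs x 4 sources; posterior mean nu = 0.3183; predicted 262 interacting

$ nbel evaluate --pred posterior.tsv --truth pairs.tsv --out report.json
FP 0.0613  FN 0.1360  misclassification 0.0987
```

(`cfg.yaml` here holds `n_iter: 600` / `n_burn: 100`; without a config the
fit uses the full 5000/1000 default.) Reading the output: roughly 29% of
pairs had their apparent status reversed in at least one source, yet the
model still classifies at a 9.9% misclassification rate — the average of
the 6.1% false-positive and 13.6% false-negative rates — and estimates
that ~32% of pairs look interacting (the true 25% plus contamination).
`posterior.tsv` lists one pair per row:

```
pair_id	posterior_prob	predicted
pair_000000	0.9828974972	1
pair_000001	0.9539644905	1
```

The same machinery is available as a library (`nbel.gibbs_fit`,
`nbel.simulate_scores`, `nbel.contaminate`, `nbel.naive_bayes_predict`,
`nbel.logistic_fit_predict`, `nbel.misclassification`, ...), and
`nbel experiment` runs whole replicate × contamination-level grids from a
YAML config, writing per-cell JSON reports and a manifest.

Real LR tables (strictly positive, right-skewed) should be read with
`nbel.io.read_pairs_tsv` and passed through
`normalize_columns(..., log_transform=True)`; `nbel fit --log-lr` does the
same from the command line.

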
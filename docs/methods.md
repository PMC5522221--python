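# Methods

This note describes what `chromexpr` computes and the conventions behind each
stage. Symbols: gene *i*, factor *k*, bin *j*; expression is RPKM `L_i`; the
modelled response is `y_i = log2(L_i + sigma)` with pseudocount `sigma = 1`.

## 1. Signal binning

Every factor is represented by a set of sequencing-tag positions on one
chromosome. Around each gene's transcription start site (TSS) we count tags in
fixed 200-bp bins:

- transcription factors (TF): ±10 kb window, 100 bins;
- histone modifications (HM) and DNase: ±2 kb window, 20 bins.

Windows are strand-oriented: for minus-strand genes the bin order is reversed
so that bin 0 is always the most 5' bin. Bins are left-closed, right-open; a
tag on a bin boundary is counted exactly once. Raw counts `n_ijk` are
normalized for sequencing depth and bin width:

```
N_ijk = n_ijk * 1e9 / (n_tags_k * 200)
```

where `n_tags_k` is the factor's total tag count. A track with zero tags is
rejected rather than silently normalized.

## 2. Association strengths

Each factor is collapsed to one scalar per gene.

**TFAS** (TF association strength) weights bins by a Gaussian kernel of the
bin-midpoint distance `d_j` from the TSS:

```
a_ik = sum_j N_ijk * F(d_j),   F(d) = exp(-d^2 / (2 h^2)) / (h * sqrt(2*pi))
```

The bandwidth `h` is Silverman's rule of thumb,
`h = 0.9 * min(sd, IQR/1.34) * n^(-1/5)`, computed from the pooled
strand-oriented tag-to-nearest-TSS distances of that track, restricted to the
TF window. This lets each TF's own spatial spread set how sharply its signal
is focused at the TSS.

**HMAS** (HM/DNase association strength) is the plain sum of the 20
normalized bins — broad marks are not distance-weighted.

Model features are `x_ik = log2(a_ik + sigma)`, matching the response
transform.

## 3. Expression models

Two regressors relate features to `y`:

- **log-linear**: ordinary least squares on the logged features (the
  coefficients are elasticities on the log2 scale);
- **epsilon-SVR** with an RBF kernel (C = 1, epsilon = 0.1, gamma = `scale`),
  with features standardized inside each training fold.

Both are scored by 10-fold cross-validation. The headline statistic is the
squared Pearson correlation between out-of-fold predictions and observed `y`
(`cv_r2`), with the coefficient of determination reported alongside. Model
stability is summarized as the root-mean-square gap between each fold's
training and test R².

## 4. Stepwise TF selection

When many TFs are available, a bidirectional stepwise search (forward
addition, backward elimination after every addition) selects at most 15 TFs.
The default criterion is AIC on the OLS fit; a classical F-test variant
(p-enter 0.05, p-remove 0.10) is available. Candidate order is made
deterministic by sorting names, so results do not depend on column order.

## 5. Combination modes

For a factor class with `n` factors, all `2^n - 1` non-empty subsets
("modes") are fitted with the SVR under shared fold assignments, giving a
comparable PCC per subset. Summaries:

- the maximum PCC attainable at each cardinality (a saturation curve);
- "top modes": subsets at a reference cardinality (default 4) whose PCC is at
  least 95% of the all-factor PCC;
- per-factor frequency and pairwise co-occurrence within the top modes, which
  expose which factors are individually necessary and which are
  interchangeable.

Enumeration is capped at 20 factors (about one million subsets) by a guard.

## 6. Redundancy and the partial-correlation network

Marginal correlation between two factors can reflect a shared upstream signal
rather than a direct relationship. We therefore estimate the
factor/expression network from partial correlations. The correlation matrix
is first stabilized by Schäfer–Strimmer shrinkage toward the identity, with
analytic intensity

```
lambda* = sum_ij var(r_ij) / sum_ij r_ij^2    (floored at 1e-3, capped at 1)
```

The partial correlations are read off the scaled inverse of the shrunk
matrix. Edges are ranked by absolute partial correlation; the top edges
(default 60 for full-size studies) form the network. Robustness is assessed
by repeatedly removing a fixed number of genes at random (default 200, 50
repetitions) and recording the Jaccard similarity between each replicate's
edge set and the full-data edge set.

Cross-class redundancy is quantified as the Pearson correlation between the
out-of-fold predictions of a TF-only and an HM-only SVR — a high value means
the two classes carry largely the same expression information.

## 7. Gene-set TF/HM ratio

High-expressed genes are the top 15% by RPKM (ties broken by gene id). Each
curated gene set is intersected with the high-expressed genes; sets with
fewer than 30 remaining genes are discarded. For each surviving set, TF-only
and HM-only SVR models are fitted within the set, and their out-of-fold PCCs
give the ratio `TF_PCC / HM_PCC`. P-values of the out-of-fold correlations
are Benjamini–Hochberg corrected separately per model class; a set is flagged
significant when both corrected values fall below 0.05. Ratios are banded:

- `< 0.90` — HM-superior,
- `[0.90, 1.10]` — similar,
- `> 1.10` — TF-superior.

## 8. Synthetic data generator

The generator produces a single synthetic chromosome with:

- gene TSSs placed on slots with jitter, guaranteeing > 24 kb spacing so the
  ±10 kb windows never overlap;
- expression `y ~ N(2, 2^2)` on the log2 scale, back-transformed to RPKM;
- per-factor latent intensities `u_k = w_k * z(y) + 0.5 * eps`, i.e. factor
  signal tracks standardized expression with factor-specific strength `w_k` —
  this is what creates realistic cross-class redundancy;
- optional engineered redundant pairs: the second factor's latent vector is
  remixed with the first's to hit an exact in-sample correlation (default
  TF02/TF03 at 0.9);
- tags drawn multinomially with probability proportional to `2^u`, placed at
  strand-oriented offsets from the TSS with factor-specific spread, plus 10%
  uniform background.

Gene sets with known bias ("TF-favoured", "HM-favoured", "neutral") are drawn
by scoring each gene's class-specific residual noise and sampling a Gumbel
top-k, so set membership favours genes whose expression is better explained
by one class. Every stage derives its random stream from
`(seed, stage, factor)` tuples, making all outputs reproducible from one
integer seed.

## Deliberate deviations from common practice

- The network estimator is implemented in-package (shrinkage + inversion)
  rather than delegated to an external R package, and is validated against an
  OLS-residual oracle and an analytic precision matrix in the tests.
- `cv_r2` is the squared out-of-fold Pearson correlation, not the coefficient
  of determination; the latter is reported in `extras` for comparison.
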
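# Methods

## Problem setting

Three independent DNA-methylation studies of monozygotic (MZ) twin
pairs discordant for major depressive disorder — one study per region,
processed in different laboratories — are to be combined into a single
cohort and used to classify the affected twin of each pair from blood
methylation alone.  Merging the raw matrices violates the i.i.d.
assumption behind standard learning-theory guarantees in three distinct
ways that this package models and removes:

1. **Batch (region) effects** — per-feature additive shifts and
   multiplicative variance changes shared by all samples of one study;
2. **Stratification / broad unwanted variance** — low-rank structure
   (population stratification, global technical drift) spread across
   many features;
3. **Pair correlation** — twins share genetic background and
   environment, so samples are dependent within pairs.

The disease signal itself is expected to be sparse and weak in
peripheral blood, which is why the per-study cohorts are individually
underpowered and the merge is worth the trouble.

## Data model

A cohort is a feature x sample matrix `Y` of log-normalized methylation
levels with per-sample metadata (twin-pair id, region id, affection
status).  Every pair must be discordant — exactly one affected, one
unaffected member — and both twins belong to the same region.  The pair
is the unit of resampling throughout.

The batch model is the classical location/scale formulation

    Y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg,

where `g` indexes features, `i` batches, `j` samples; `alpha_g` is the
overall level, `X` a design of biological covariates (affection status
by default), `gamma_ig` / `delta_ig` the additive / multiplicative
batch effects and `eps_ijg ~ N(0, sigma_g^2)`.

## Consolidation methods

* **RAW** — concatenate regions over the common feature panel (the
  intersection of feature sets, in the first region's order).
* **NormMean / NormScale** — per-region feature centering, or centering
  plus scaling to unit sample sd (N-1 denominator).  Zero-variance
  features are centered and left unscaled, with a warning.
* **PCA.k** — per region, feature-center the matrix, subtract the
  rank-k truncated-SVD reconstruction, restore the feature means.  The
  removed axes are the region's leading principal directions, where
  stratification-like variance concentrates.  `k = 0` is the identity;
  `k` up to the numerical rank of the centered matrix is allowed (at
  `k = rank` the centered matrix is annihilated); larger `k` errors.
  Centering before decomposition is a deliberate choice the operation's
  published description leaves open: uncentered axes confound the
  feature-mean profile with the structure to be removed.
* **ComBat** (nonparametric empirical Bayes) — three steps on the
  merged data:
  1. *Standardize.* Per feature, least-squares fit of batch means and
     covariate effects under the constraint `sum_i (n_i/N) gamma_ig = 0`;
     pooled variance `sigma_g^2` is the mean squared residual (1/N
     denominator); `Z = (Y - alpha - X beta) / sigma` keeps the batch
     structure.
  2. *Shrink.* Per batch, raw estimates are the batch mean
     (`gamma_hat`) and batch variance (`delta2_hat`, N-1 denominator)
     of `Z`.  The nonparametric posterior for feature `g` is the
     likelihood-weighted average of every **other** feature's raw
     estimates, with weights proportional to the Gaussian likelihood of
     feature `g`'s batch data under the donor's `(gamma_hat,
     delta2_hat)`.  Weights are computed from sufficient statistics in
     log space with max-subtraction; zero-variance features are
     excluded as donors and their posterior scale floored at 1e-8.
  3. *Adjust.* `Y* = sigma/delta_star * (Z - gamma_star) + alpha + X beta`.

  Affection status is included in the design by default so the
  biological contrast is protected during standardization (toggleable
  for sensitivity analysis).  A conjugate parametric variant
  (normal/inverse-gamma priors, method-of-moments hyperparameters,
  iterated posterior solve) is implemented as an independent
  cross-check; the pipeline always uses the nonparametric scheme, which
  is additionally verified against `sva::ComBat(par.prior=FALSE)` in the
  test suite (agreement to ~1e-13 on a 60-feature cohort).
* **PCA.k + ComBat** — per-region PCA subtraction, merge, then the
  empirical-Bayes adjustment; removal of broad unwanted variance first,
  feature-level batch location/scale second.

ComBat is fitted once on the full merged matrix before train/test
splitting, matching the study workflow this package reproduces.  The
resulting leakage is mild (the fit never sees labels beyond the
protected covariate) but real; refitting within training folds is
possible by composing the library functions per fold.

### A note on the nonparametric zero-noise limit

Exact identities one might expect of a batch adjustment — equal
per-batch feature means after adjustment on noiseless additive data,
and idempotence — hold for the parametric posterior but **not** for the
leave-one-out nonparametric posterior, which by construction replaces
each feature's estimate with a weighted average of other features'.
The test suite asserts the exact identities on the parametric variant
and checks the nonparametric scheme by shrinkage properties, the
two-feature leave-one-out identity, large-batch consistency, the
batch-ANOVA criterion and the `sva` cross-check.

## Feature filters

Six training-fold-only scores, selection always top-n:

* absolute Welch t; two-sided Welch p (Welch–Satterthwaite df);
* absolute class-mean difference;
* absolute Pearson correlation with the 0/1 label;
* moderated-t p-value: per-feature two-group fit, residual variances
  shrunk toward a common prior value, `s2_tilde = (d0 s0^2 + d s2) /
  (d0 + d)`, with `(d0, s0^2)` estimated by method of moments on the
  log residual variances (digamma/trigamma matching, Newton inversion
  of the trigamma), p from t with `d0 + d` df.  This is the defining
  computation of the limma single-covariate fit and matches
  `limma::eBayes` to ~1e-15 in the cross-check test.  The `d0 = 0`
  limit recovers the ordinary pooled-variance t-test.
* paired rank product: per pair, the affected-minus-unaffected
  difference (the data is already on a log scale, so this is the pair
  log-ratio); features are ranked per pair in each direction, and the
  score is `min(RP_up, RP_down)` of the geometric-mean ranks, making it
  symmetric under label reversal.  Ranks use average tie-handling;
  permutation p-values are out of scope since selection is top-n.

Zero-variance degeneracies (infinite t) map to a large finite sentinel
so such features sort first deterministically instead of crashing.

## Classification harness

Each resample draws an 80/20 split **of pairs** (round-half-away
rounding, at least one pair per side), so both twins stay on the same
side and every fold is exactly half affected.  Scores are computed on
the training fold, the top-n features selected, per-feature
standardization fitted on the training fold (applied to both folds;
soft-margin SVMs are scale-sensitive, and the published workflow leaves
this unstated), the classifier fitted and test accuracy recorded.

* Linear SVM with soft margin `C = 0.05` (the study's cross-validated
  value), paired by default with the Welch-t filter.
* Random forest with 500 trees and `ceil(0.1 * n_features)` candidate
  features per split (the study's tuned ratio; the tree count is not
  stated there and is a config knob here), paired with the moderated-p
  filter.

Accuracy is the primary metric; mean and sd are aggregated over
resamples (200 by default; smaller counts used where noted for
runtime).  Resample `r` uses split seed `base + r` and forest seed
`base + 10^6 + r`, so each resample is individually reproducible, and
grid cells derive their base seed from a stable hash of the cell
coordinates, making results independent of evaluation order.

## Synthetic cohort generator

`simulate_cohort` draws, per feature: baseline `alpha_g ~ N(0,1)`;
per-batch `gamma_ig ~ N(0, batch_additive_sd^2)` and `delta2_ig ~
InvGamma(shape, shape-1)` (mean ~1); a rank-r stratification term
(loadings `N(0,1)` x per-sample scores `N(0, strat_sd^2)`); a shared
pair effect `N(0, pair_sd^2)`; residual `sqrt(delta2) * N(0,
noise_sd^2)`; and `+signal_effect` for the affected twin on a random
sparse signal set.  Batches draw from independent deterministic
substreams of the seed, so extending the cohort does not perturb
existing batches.

Default conditions (`gse37579_like_config`): 14/40/43 pairs in three
regions (194 samples), 8448 features, 100 signal features with effect
0.5, `batch_additive_sd = 2.0`, inverse-gamma shape 4, three
stratification components with `strat_sd = 4.0`, `pair_sd = 1.0`,
`noise_sd = 1`.  The confounding strength is deliberately set so that
the regime of the original study is reproduced qualitatively: each
region alone and the RAW merge classify near chance, while
consolidation recovers the signal.  A linear SVM can partially cancel
purely low-rank confounding by itself, so visibly separating RAW from
the consolidated pipelines requires confounding of roughly this
magnitude.  The planted effect is a tunable, not an estimate — the
original study reports no effect sizes — and with these defaults the
consolidated accuracy (~0.85 at 2000 features) is far above the ~0.58
reported on the real data: passing tests demonstrate the *ordering* of
methods and the correctness of the machinery, not the real-data effect
size.  The generator also omits probe-level chemistry, cell-type
composition and age/sex structure; conclusions about those do not
follow from these simulations.

## Problem sizes and numerical choices

Analyses and acceptance checks run on a 2000-feature panel (the
generator supports the full 8448) with 50 resamples per cell; these
sizes keep the complete evaluation grid comfortably reproducible on a
laptop while leaving all power conclusions unchanged.  Null-calibration
quantities are averaged over three cohort seeds because a single
97-pair cohort carries visible draw-level variability (~±0.04) in its
null accuracy.  Numerical details: SVD-based PCA with a
`max(G,N)*eps*s1` rank tolerance; empirical-Bayes weights in log space;
residual variances below `1e-24 * mean(Y^2)` treated as zero (floored,
warned); selection ties broken by feature order; TSV round-trips at
`%.17g` with round-trip float parsing.

## Known limitations

* The nonparametric posterior is O(G^2) per batch in memory-chunked
  closed form; at the full 8448 features it costs a few seconds, but
  the quadratic scaling is real.
* ComBat requires >= 2 batches with >= 2 samples each, and errors when
  batch and covariate are confounded (impossible under the discordant
  design, which balances status within every batch).
* The whole-cohort ComBat fit implies the mild leakage noted above.
* Accuracy under the synthetic defaults is not calibrated to the
  real-data accuracy level; only orderings and calibration properties
  are asserted.
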
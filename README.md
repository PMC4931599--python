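# twinmeth

Consolidation and classification of multi-site DNA-methylation cohorts
of monozygotic twins discordant for major depressive disorder.

Three regional twin studies (UK, Australia, Netherlands; 97 discordant
pairs, 194 samples, 8448 CpG-island probes) measure blood methylation
with the same array but in different laboratories.  Individually the
studies are underpowered; naively merging them violates the i.i.d.
assumption — per-region batch effects, stratification-like low-rank
variance and within-pair correlation all distort a merged analysis.
This package implements the full consolidation-and-classification
pipeline for that design and a synthetic-cohort generator with known
ground truth to validate every step.

## The method

Under the location/scale batch model

    Y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg,

the pipeline combines:

* **PCA.k subtraction** per region: feature-center, subtract the rank-k
  truncated-SVD reconstruction (stripping the leading unwanted-variance
  axes), restore means;
* **nonparametric empirical-Bayes batch adjustment (ComBat)** on the
  merged data: standardize per feature under the constraint
  `sum_i (n_i/N) gamma_ig = 0`, shrink per-batch location/scale
  estimates by leave-one-out likelihood-weighted averaging across
  features, then remove them;
* **mixtures** PCA.k + ComBat, plus the NormMean / NormScale / RAW
  baselines;
* **six filter scores** (|Welch t|, |mean difference|, Welch p,
  |Pearson r|, moderated-t p with empirical-Bayes variance shrinkage,
  paired rank product), computed on training folds only;
* a **twin-pair-balanced resampling harness**: 80/20 splits of pairs
  (every fold exactly half affected), in-fold selection and
  standardization, linear SVM (C = 0.05) and random forest
  (split-candidate ratio 0.1), accuracy aggregated over independent
  resamples.

See `docs/methods.md` for the model, estimators, defaults and
limitations.

## Worked example

```python
import twinmeth as tm

# a study-shaped synthetic cohort: 3 regions, 97 discordant pairs
cfg = tm.gse37579_like_config(seed=11, n_features=2000)
cohort, truth = tm.simulate_cohort(cfg)
regions = cohort.split_by_batch()

svm = tm.ClassifierSpec("linear_svm")          # C = 0.05
for label, spec in [("RAW", tm.ConsolidationSpec("RAW")),
                    ("PCA.3+ComBat", tm.ConsolidationSpec("PCA_ComBat", 3))]:
    merged = tm.consolidate(regions, spec)
    s = tm.resample_evaluate(merged, "welch_t", 100, svm,
                             n_resamples=50, base_seed=7)
    print(f"{label:>13}: {s.mean_accuracy:.3f} (sd {s.sd_accuracy:.3f})")
```

prints

```
          RAW: 0.619 (sd 0.075)
 PCA.3+ComBat: 0.844 (sd 0.048)
```

the study's qualitative result on synthetic ground truth: the raw merge
is barely above chance because batch and stratification variance
swamps in-fold feature selection, while removing three principal
components per region and then the per-feature batch location/scale
recovers the planted sparse signal.  Each individual region evaluates
near chance (the 14-pair region at 0.483 here).

The same pipeline is scripted as an analysis sequence under
`analysis/` (simulate -> consolidation diagnostics -> filter
comparison -> classification grid -> feature report), writing its
tables to `results/`, and is available as a CLI:

```sh
twinmeth simulate --preset gse37579-like --seed 7 -o out/
twinmeth run-grid --config grid.yaml
```

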
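#!/usr/bin/env python
"""Compare the six filter scores for each classifier.

On the consolidated (PCA.3 + empirical-Bayes) study cohort, every
filter is paired with both the linear SVM and the random forest at a
selection depth of 50 features, 50 resamples each.  Writes
results/filter_comparison.tsv; the best filter per classifier feeds the
main grid (04).
"""

from pathlib import Path

import pandas as pd

import twinmeth as tm
from twinmeth.classify import ClassifierSpec, resample_evaluate
from twinmeth.consolidate import ConsolidationSpec
from twinmeth.scores import METHOD_NAMES

STUDY_SEED = 11
N_FEATURES = 2000
DEPTH = 50
N_RESAMPLES = 50

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    cfg = tm.gse37579_like_config(STUDY_SEED, n_features=N_FEATURES)
    cohort, _ = tm.simulate_cohort(cfg)
    adjusted = tm.consolidate(
        cohort.split_by_batch(), ConsolidationSpec("PCA_ComBat", 3)
    )
    rows = []
    for clf in (ClassifierSpec("linear_svm"), ClassifierSpec("random_forest")):
        for method in METHOD_NAMES:
            summary = resample_evaluate(
                adjusted, method, DEPTH, clf,
                n_resamples=N_RESAMPLES, base_seed=STUDY_SEED,
            )
            rows.append(
                {
                    "classifier": clf.algorithm,
                    "filter": method,
                    "mean_accuracy": summary.mean_accuracy,
                    "sd_accuracy": summary.sd_accuracy,
                }
            )
            print(
                f"{clf.algorithm:>14} + {method:<12} "
                f"{summary.mean_accuracy:.3f} (sd {summary.sd_accuracy:.3f})"
            )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(
        RESULTS / "filter_comparison.tsv", sep="\t", index=False,
        float_format="%.4f",
    )
    for algo, sub in table.groupby("classifier"):
        best = sub.sort_values("mean_accuracy", ascending=False).iloc[0]
        print(f"best filter for {algo}: {best['filter']} "
              f"({best['mean_accuracy']:.3f})")


if __name__ == "__main__":
    main()
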
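"""Twin-pair-balanced resampling evaluation of linear SVM and random forest.

Each resample draws an 80/20 split *of twin pairs* (both members of a
pair always land on the same side, so every fold is exactly half
affected), computes the filter score on training samples only, selects
the top-n features, optionally standardizes per feature (fitted on the
training fold), fits the classifier and records test accuracy.

Defaults follow the tuned study settings: soft-margin C = 0.05 for the
linear SVM and a 0.1 split-candidate feature ratio for the random
forest, with 200 independent resamples.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .datasets import LabeledDataset, SampleMetadata, ValidationError
from . import scores as _scores

ALGORITHMS = ("linear_svm", "random_forest")

#: offset separating split seeds from forest seeds within one resample
RF_SEED_OFFSET = 10**6


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: str = "linear_svm"
    svm_C: float = 0.05
    rf_feature_ratio: float = 0.1
    rf_n_trees: int = 500
    standardize_features: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown algorithm {self.algorithm!r}; expected {ALGORITHMS}"
            )
        if self.svm_C <= 0:
            raise ValidationError("svm_C must be positive")
        if not 0 < self.rf_feature_ratio <= 1:
            raise ValidationError("rf_feature_ratio must lie in (0, 1]")
        if self.rf_n_trees < 1:
            raise ValidationError("rf_n_trees must be positive")


@dataclass
class ResampleResult:
    resample_index: int
    accuracy: float
    selected_feature_ids: list[str]
    train_pair_ids: frozenset
    test_pair_ids: frozenset


@dataclass
class AccuracySummary:
    mean_accuracy: float
    sd_accuracy: float
    n_resamples: int
    results: list[ResampleResult]
    feature_frequency: dict[str, int]
    feature_order: list[str] = field(default_factory=list)

    @classmethod
    def from_results(
        cls, results: list[ResampleResult], feature_order: list[str]
    ) -> "AccuracySummary":
        acc = np.array([r.accuracy for r in results])
        freq: Counter = Counter()
        for r in results:
            freq.update(r.selected_feature_ids)
        return cls(
            mean_accuracy=float(acc.mean()),
            sd_accuracy=float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
            n_resamples=len(results),
            results=results,
            feature_frequency=dict(freq),
            feature_order=feature_order,
        )


def split_pairs(
    metadata: list[SampleMetadata], train_fraction: float, rng_seed: int
) -> tuple[frozenset, frozenset]:
    """Sample twin pairs without replacement into train/test sets.

    The train size is round(train_fraction * P) with half rounded away
    from zero, clamped so both sides keep at least one pair.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie in (0, 1)")
    pairs = sorted({m.pair_id for m in metadata})
    if len(pairs) < 2:
        raise ValidationError("need >= 2 pairs to split")
    n_train = int(math.floor(train_fraction * len(pairs) + 0.5))
    n_train = min(max(n_train, 1), len(pairs) - 1)
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(pairs))
    train = frozenset(pairs[i] for i in perm[:n_train])
    test = frozenset(pairs[i] for i in perm[n_train:])
    return train, test


def classifier_fit_predict(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    test_values: np.ndarray,
    clf: ClassifierSpec,
    rng_seed: int,
) -> np.ndarray:
    """Fit the configured classifier and predict test labels.

    Matrices are samples x features.  The random forest draws
    ``ceil(rf_feature_ratio * n_features)`` candidate features per split.
    """
    if len(np.unique(train_labels)) < 2:
        raise ValidationError("training set contains a single class")
    if clf.algorithm == "linear_svm":
        est = SVC(kernel="linear", C=clf.svm_C)
    else:
        n_feat = train_values.shape[1]
        est = RandomForestClassifier(
            n_estimators=clf.rf_n_trees,
            max_features=max(1, math.ceil(clf.rf_feature_ratio * n_feat)),
            random_state=rng_seed % (2**32),
        )
    est.fit(train_values, train_labels)
    return est.predict(test_values)


def train_eval_once(
    data: LabeledDataset,
    filter_method: str,
    n_features: int,
    clf: ClassifierSpec,
    rng_seed: int,
    train_fraction: float = 0.8,
    rf_seed: int | None = None,
    leak_feature_selection: bool = False,
) -> ResampleResult:
    """One split -> filter -> fit -> test-accuracy evaluation.

    ``leak_feature_selection=True`` scores features on the full dataset
    (train + test) instead of the training fold; it exists only as a
    diagnostic of what that leakage would inflate and is never used by
    the resampling harness.
    """
    if n_features < 1:
        raise ValidationError("n_features must be >= 1")
    if n_features > data.n_features:
        raise ValidationError(
            f"n_features={n_features} exceeds the {data.n_features} features"
        )
    train_pairs, test_pairs = split_pairs(data.metadata, train_fraction, rng_seed)
    pair_arr = np.array(data.pair_ids())
    train_mask = np.isin(pair_arr, list(train_pairs))
    labels = data.labels()
    values = data.values

    if leak_feature_selection:
        sc, direction = _scores.score_arrays(
            values, labels, filter_method, pair_arr
        )
    else:
        sc, direction = _scores.score_arrays(
            values[:, train_mask],
            labels[train_mask],
            filter_method,
            pair_arr[train_mask],
        )
    sel = _scores.select_top_indices(sc, direction, n_features)

    x_train = values[np.ix_(sel, train_mask)].T
    x_test = values[np.ix_(sel, ~train_mask)].T
    if clf.standardize_features:
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        x_train = (x_train - mu) / sd
        x_test = (x_test - mu) / sd

    if rf_seed is None:
        rf_seed = rng_seed + RF_SEED_OFFSET
    pred = classifier_fit_predict(
        x_train, labels[train_mask], x_test, clf, rf_seed
    )
    accuracy = float(np.mean(pred == labels[~train_mask]))
    return ResampleResult(
        resample_index=0,
        accuracy=accuracy,
        selected_feature_ids=[data.feature_ids[i] for i in sel],
        train_pair_ids=train_pairs,
        test_pair_ids=test_pairs,
    )


def resample_evaluate(
    data: LabeledDataset,
    filter_method: str,
    n_features: int,
    clf: ClassifierSpec,
    n_resamples: int = 200,
    base_seed: int = 0,
    train_fraction: float = 0.8,
) -> AccuracySummary:
    """Mean/sd accuracy and feature-selection counts over independent
    resamples; resample r uses split seed base_seed + r and forest seed
    base_seed + RF_SEED_OFFSET + r, so every resample is individually
    reproducible."""
    if n_resamples < 2:
        raise ValidationError("n_resamples must be >= 2")
    results = []
    for r in range(1, n_resamples + 1):
        res = train_eval_once(
            data,
            filter_method,
            n_features,
            clf,
            rng_seed=base_seed + r,
            train_fraction=train_fraction,
            rf_seed=base_seed + RF_SEED_OFFSET + r,
        )
        res.resample_index = r
        results.append(res)
    return AccuracySummary.from_results(results, list(data.feature_ids))
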
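"""Orchestration of the full study grid: consolidation methods x
classifiers x feature-selection depths, plus the per-region baselines
and the selection-frequency feature report.

Each grid cell is one :func:`twinmeth.classify.resample_evaluate` run.
Cell seeds are derived from the base seed and the cell's coordinates by
a stable hash, so results do not depend on the order cells are visited
and a single cell can be reproduced in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import AccuracySummary, ClassifierSpec, resample_evaluate
from .consolidate import ConsolidationSpec, consolidate
from .datasets import LabeledDataset, ValidationError

DEFAULT_DEPTHS = (25, 50, 100, 200)
DEFAULT_FILTERS = {"linear_svm": "welch_t", "random_forest": "moderated_p"}


def default_consolidation_specs() -> list[ConsolidationSpec]:
    specs = [
        ConsolidationSpec("RAW"),
        ConsolidationSpec("NormMean"),
        ConsolidationSpec("NormScale"),
    ]
    specs += [ConsolidationSpec("PCA", k) for k in range(1, 6)]
    specs.append(ConsolidationSpec("ComBat"))
    specs += [ConsolidationSpec("PCA_ComBat", k) for k in range(1, 6)]
    return specs


@dataclass
class GridSpec:
    consolidation_specs: list[ConsolidationSpec] = field(
        default_factory=default_consolidation_specs
    )
    classifiers: list[ClassifierSpec] = field(
        default_factory=lambda: [
            ClassifierSpec("linear_svm"),
            ClassifierSpec("random_forest"),
        ]
    )
    feature_depths: tuple[int, ...] = DEFAULT_DEPTHS
    filter_by_classifier: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FILTERS)
    )
    n_resamples: int = 200
    base_seed: int = 0
    include_per_region_baselines: bool = True

    def __post_init__(self) -> None:
        if not self.consolidation_specs and not self.include_per_region_baselines:
            raise ValidationError("empty grid")
        if not self.classifiers:
            raise ValidationError("no classifiers configured")
        if any(d <= 0 for d in self.feature_depths):
            raise ValidationError("feature depths must be positive")


@dataclass
class GridResult:
    table: pd.DataFrame  # one row per cell
    summaries: dict[tuple[str, str, int], AccuracySummary]
    failures: dict[str, str]  # consolidation label -> error message


def cell_seed(base_seed: int, label: str, algorithm: str, depth: int) -> int:
    """Order-independent per-cell seed below 2**31."""
    tag = f"{label}|{algorithm}|{depth}".encode()
    return (base_seed + zlib.crc32(tag)) % (2**31 - 1)


def run_grid(regions: list[LabeledDataset], spec: GridSpec) -> GridResult:
    """Evaluate every (consolidation, classifier, depth) cell.

    Per-region baselines evaluate each region unmerged under the label
    ``region:<batch>``.  A consolidation that fails is recorded and
    skipped without aborting the rest of the grid.
    """
    if not regions:
        raise ValidationError("run_grid needs at least one region")
    jobs: list[tuple[str, LabeledDataset | None, str | None]] = []
    failures: dict[str, str] = {}
    if spec.include_per_region_baselines:
        for region in regions:
            jobs.append((f"region:{region.batches()[0]}", region, None))
    for cs in spec.consolidation_specs:
        try:
            jobs.append((cs.label, consolidate(regions, cs), None))
        except Exception as exc:  # noqa: BLE001 - record-and-continue policy
            failures[cs.label] = str(exc)
            jobs.append((cs.label, None, str(exc)))

    rows = []
    summaries: dict[tuple[str, str, int], AccuracySummary] = {}
    for label, dataset, error in jobs:
        for clf in spec.classifiers:
            filt = spec.filter_by_classifier[clf.algorithm]
            for depth in spec.feature_depths:
                row = {
                    "consolidation": label,
                    "classifier": clf.algorithm,
                    "filter": filt,
                    "n_features": depth,
                }
                if error is not None:
                    row.update(
                        mean_accuracy=np.nan, sd_accuracy=np.nan, status=error
                    )
                    rows.append(row)
                    continue
                seed = cell_seed(spec.base_seed, label, clf.algorithm, depth)
                try:
                    summary = resample_evaluate(
                        dataset,
                        filt,
                        depth,
                        clf,
                        n_resamples=spec.n_resamples,
                        base_seed=seed,
                    )
                except Exception as exc:  # noqa: BLE001
                    row.update(
                        mean_accuracy=np.nan, sd_accuracy=np.nan, status=str(exc)
                    )
                    failures[f"{label}|{clf.algorithm}|{depth}"] = str(exc)
                    rows.append(row)
                    continue
                summaries[(label, clf.algorithm, depth)] = summary
                row.update(
                    mean_accuracy=summary.mean_accuracy,
                    sd_accuracy=summary.sd_accuracy,
                    status="ok",
                )
                rows.append(row)
    return GridResult(pd.DataFrame(rows), summaries, failures)


def feature_report(summary: AccuracySummary, top_n: int) -> pd.DataFrame:
    """Features ranked by in-fold selection count across resamples.

    ``selection_probability = count / n_resamples``; ties break by the
    feature's position in the dataset.
    """
    order = summary.feature_order or sorted(summary.feature_frequency)
    counts = np.array([summary.feature_frequency.get(f, 0) for f in order])
    rank = np.argsort(-counts, kind="stable")[:top_n]
    return pd.DataFrame(
        {
            "feature_id": [order[i] for i in rank],
            "selection_count": counts[rank],
            "selection_probability": counts[rank] / summary.n_resamples,
        }
    )


def compare_baselines(
    regions: list[LabeledDataset],
    spec: GridSpec,
    consolidation: ConsolidationSpec | None = None,
) -> pd.DataFrame:
    """Side-by-side table of the unadjusted baselines (per-region, RAW,
    NormMean, NormScale) against one consolidation method."""
    specs = [
        ConsolidationSpec("RAW"),
        ConsolidationSpec("NormMean"),
        ConsolidationSpec("NormScale"),
    ]
    if consolidation is not None:
        specs.append(consolidation)
    restricted = GridSpec(
        consolidation_specs=specs,
        classifiers=spec.classifiers,
        feature_depths=spec.feature_depths,
        filter_by_classifier=spec.filter_by_classifier,
        n_resamples=spec.n_resamples,
        base_seed=spec.base_seed,
        include_per_region_baselines=True,
    )
    return run_grid(regions, restricted).table
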
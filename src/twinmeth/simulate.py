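"""Synthetic discordant-twin methylation cohorts with known ground truth.

The generator produces the statistical structure the consolidation and
classification pipeline is designed to handle:

* per-batch additive shifts ``gamma_ig ~ N(0, batch_additive_sd^2)`` and
  multiplicative variance factors ``delta2_ig ~ InvGamma(shape, shape-1)``
  (mean ~ 1), the location/scale batch model empirical-Bayes adjustment
  assumes;
* a low-rank stratification component (random feature loadings times
  per-sample scores), the kind of broad unwanted variance that
  leading-principal-component subtraction removes;
* a shared within-pair random effect (twins are correlated);
* a sparse additive disease signal: affected twins are shifted by
  ``signal_effect`` on ``n_signal_features`` randomly chosen features.

Generation is a pure function of ``config.seed``.  Each batch draws from
its own deterministic substream, so adding a batch to the config leaves
earlier batches' samples unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets import (
    AFFECTED,
    UNAFFECTED,
    LabeledDataset,
    MethylationDataset,
    SampleMetadata,
    ValidationError,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the cohort generator.

    All effect sizes are on the log-methylation scale.  Setting
    ``batch_multiplicative_shape`` to ``None`` disables multiplicative
    batch effects (``delta2 == 1``).
    """

    pairs_per_batch: tuple[int, ...]
    n_features: int = 8448
    n_signal_features: int = 100
    signal_effect: float = 0.5
    batch_additive_sd: float = 2.0
    batch_multiplicative_shape: float | None = 4.0
    n_strat_components: int = 3
    strat_sd: float = 4.0
    pair_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    batch_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.pairs_per_batch or any(p <= 0 for p in self.pairs_per_batch):
            raise ValidationError("pairs_per_batch must be positive integers")
        if self.n_features <= 0:
            raise ValidationError("n_features must be positive")
        if not 0 <= self.n_signal_features <= self.n_features:
            raise ValidationError(
                "n_signal_features must lie in [0, n_features]"
            )
        for name in ("batch_additive_sd", "strat_sd", "pair_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if (
            self.batch_multiplicative_shape is not None
            and self.batch_multiplicative_shape <= 2
        ):
            raise ValidationError(
                "batch_multiplicative_shape must exceed 2 (finite variance)"
            )
        if self.n_strat_components < 0:
            raise ValidationError("n_strat_components must be non-negative")
        if self.batch_labels is not None and len(self.batch_labels) != len(
            self.pairs_per_batch
        ):
            raise ValidationError("batch_labels length must match pairs_per_batch")

    def labels_for_batches(self) -> tuple[str, ...]:
        if self.batch_labels is not None:
            return tuple(self.batch_labels)
        return tuple(f"B{i + 1}" for i in range(len(self.pairs_per_batch)))


@dataclass
class SyntheticTruth:
    """Planted parameters retained for recovery tests."""

    signal_feature_ids: set[str]
    gamma: np.ndarray  # batch x feature additive effects
    delta2: np.ndarray  # batch x feature multiplicative effects
    strat_loadings: np.ndarray  # feature x component
    strat_scores: np.ndarray  # sample x component


def gse37579_like_config(seed: int, **overrides) -> SyntheticConfig:
    """Config emulating the three-region twin cohort: 14/40/43 pairs
    (28/80/86 samples, 194 total) over 8448 features."""
    params = dict(
        pairs_per_batch=(14, 40, 43),
        batch_labels=("UK", "AU", "NL"),
        n_features=8448,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def _batch_rng(seed: int, batch_index: int) -> np.random.Generator:
    # spawn_key keeps batch substreams independent of how many batches exist
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(batch_index,))
    )


def simulate_cohort(config: SyntheticConfig) -> tuple[LabeledDataset, SyntheticTruth]:
    """Generate one cohort and its ground truth.

    Per batch i, pair p, feature g, twin value is
    ``alpha_g + b_pg + sum_r L_gr s_jr + gamma_ig + Delta*1[affected, signal]
    + sqrt(delta2_ig) * eps`` with ``eps ~ N(0, noise_sd^2)``.
    """
    g = config.n_features
    r = config.n_strat_components
    labels = config.labels_for_batches()

    grng = _batch_rng(config.seed, 0)  # global stream
    alpha = grng.normal(0.0, 1.0, g)
    loadings = grng.normal(0.0, 1.0, (g, r)) if r else np.zeros((g, 0))
    signal_idx = np.sort(
        grng.choice(g, size=config.n_signal_features, replace=False)
    )
    signal_mask = np.zeros(g)
    signal_mask[signal_idx] = 1.0

    feature_ids = [f"cpg{i + 1:05d}" for i in range(g)]

    columns: list[np.ndarray] = []
    metadata: list[SampleMetadata] = []
    sample_ids: list[str] = []
    gamma_rows = []
    delta2_rows = []
    score_rows = []

    for bi, (n_pairs, batch) in enumerate(zip(config.pairs_per_batch, labels)):
        rng = _batch_rng(config.seed, bi + 1)
        gamma_i = rng.normal(0.0, config.batch_additive_sd, g)
        if config.batch_multiplicative_shape is None:
            delta2_i = np.ones(g)
        else:
            shape = config.batch_multiplicative_shape
            # InvGamma(shape, scale=shape-1): mean = 1
            delta2_i = (shape - 1.0) / rng.gamma(shape, 1.0, g)
        gamma_rows.append(gamma_i)
        delta2_rows.append(delta2_i)
        sd_i = np.sqrt(delta2_i)

        for p in range(n_pairs):
            pair_id = f"{batch}_p{p + 1:03d}"
            b_pg = rng.normal(0.0, config.pair_sd, g) if config.pair_sd else 0.0
            for status, suffix in ((AFFECTED, "a"), (UNAFFECTED, "u")):
                scores = rng.normal(0.0, config.strat_sd, r) if r else np.zeros(0)
                eps = rng.normal(0.0, config.noise_sd, g)
                col = alpha + b_pg + gamma_i + sd_i * eps
                if r:
                    col = col + loadings @ scores
                if status == AFFECTED and config.n_signal_features:
                    col = col + config.signal_effect * signal_mask
                sid = f"{pair_id}{suffix}"
                columns.append(col)
                score_rows.append(scores)
                sample_ids.append(sid)
                metadata.append(SampleMetadata(sid, pair_id, batch, status))

    values = np.column_stack(columns)
    dataset = LabeledDataset(
        MethylationDataset(values, feature_ids, sample_ids), metadata
    )
    truth = SyntheticTruth(
        signal_feature_ids={feature_ids[i] for i in signal_idx},
        gamma=np.vstack(gamma_rows),
        delta2=np.vstack(delta2_rows),
        strat_loadings=loadings,
        strat_scores=np.vstack(score_rows) if score_rows else np.zeros((0, r)),
    )
    return dataset, truth


def write_truth(
    truth: SyntheticTruth,
    feature_ids: list[str],
    batch_labels: list[str],
    path,
) -> None:
    """Write planted per-feature parameters as a TSV (one row per feature)."""
    cols: dict[str, object] = {"feature_id": feature_ids}
    cols["is_signal"] = [int(f in truth.signal_feature_ids) for f in feature_ids]
    for i, b in enumerate(batch_labels):
        cols[f"gamma_{b}"] = truth.gamma[i]
        cols[f"delta2_{b}"] = truth.delta2[i]
    for rcomp in range(truth.strat_loadings.shape[1]):
        cols[f"loading_{rcomp + 1}"] = truth.strat_loadings[:, rcomp]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def config_to_dict(config: SyntheticConfig) -> dict:
    """JSON-serialisable echo of a config (for provenance records)."""
    d = asdict(config)
    d["pairs_per_batch"] = list(d["pairs_per_batch"])
    if d["batch_labels"] is not None:
        d["batch_labels"] = list(d["batch_labels"])
    return d
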
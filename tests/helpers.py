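"""Shared test utilities: dataset builders and independent brute-force
oracles (python loops + scipy, no shared code with the implementation)."""

from __future__ import annotations

import numpy as np
from scipy import stats

from twinmeth.datasets import (
    AFFECTED,
    UNAFFECTED,
    LabeledDataset,
    MethylationDataset,
    SampleMetadata,
)


def make_dataset(
    values,
    pair_ids,
    statuses,
    batch_ids,
    feature_ids=None,
    sample_ids=None,
) -> LabeledDataset:
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(g)]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    meta = [
        SampleMetadata(sample_ids[j], pair_ids[j], batch_ids[j], statuses[j])
        for j in range(n)
    ]
    return LabeledDataset(MethylationDataset(values, feature_ids, sample_ids), meta)


def random_paired_dataset(
    rng: np.random.Generator,
    n_features: int,
    n_pairs: int,
    delta: float = 0.0,
    noise: float = 1.0,
    batch: str = "B1",
) -> LabeledDataset:
    """Minimal discordant-pair generator, independent of the package's
    cohort simulator: iid Gaussian noise plus an optional affected shift
    on every feature."""
    n = 2 * n_pairs
    values = rng.normal(0.0, noise, (n_features, n))
    statuses, pairs = [], []
    for p in range(n_pairs):
        pairs += [f"p{p}", f"p{p}"]
        statuses += [AFFECTED, UNAFFECTED]
    aff_cols = [2 * p for p in range(n_pairs)]
    values[:, aff_cols] += delta
    return make_dataset(values, pairs, statuses, [batch] * n)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _split(values, labels):
    aff = [j for j, l in enumerate(labels) if l == 1]
    un = [j for j, l in enumerate(labels) if l == 0]
    return values[:, aff], values[:, un]


def brute_welch_t(values, labels):
    aff, un = _split(values, labels)
    out = []
    for g in range(values.shape[0]):
        t, _ = stats.ttest_ind(aff[g], un[g], equal_var=False)
        out.append(abs(t))
    return np.array(out)


def brute_welch_p(values, labels):
    aff, un = _split(values, labels)
    out = []
    for g in range(values.shape[0]):
        _, p = stats.ttest_ind(aff[g], un[g], equal_var=False)
        out.append(p)
    return np.array(out)


def brute_mean_diff(values, labels):
    aff, un = _split(values, labels)
    return np.array(
        [abs(np.mean(aff[g]) - np.mean(un[g])) for g in range(values.shape[0])]
    )


def brute_correlation(values, labels):
    out = []
    y = np.asarray(labels, dtype=float)
    for g in range(values.shape[0]):
        r, _ = stats.pearsonr(values[g], y)
        out.append(abs(r))
    return np.array(out)


def brute_rank_product(values, labels, pair_codes):
    """Exhaustive rank product: explicit tie-averaged ranks per pair,
    geometric mean over pairs, min of the up/down directions."""
    pair_codes = list(pair_codes)
    labels = list(labels)
    diffs = []
    for p in sorted(set(pair_codes)):
        idx = [j for j, q in enumerate(pair_codes) if q == p]
        a = next(j for j in idx if labels[j] == 1)
        u = next(j for j in idx if labels[j] == 0)
        diffs.append(values[:, a] - values[:, u])
    g = values.shape[0]
    n_pairs = len(diffs)
    rp_up = np.ones(g)
    rp_down = np.ones(g)
    for d in diffs:
        for i in range(g):
            greater = np.sum(d > d[i])
            equal = np.sum(d == d[i]) - 1
            less = np.sum(d < d[i])
            rank_desc = 1 + greater + equal / 2.0
            rank_asc = 1 + less + equal / 2.0
            rp_up[i] *= rank_desc ** (1.0 / n_pairs)
            rp_down[i] *= rank_asc ** (1.0 / n_pairs)
    return np.minimum(rp_up, rp_down)


def dense_pca_residual(values, k):
    """Reconstruction-subtraction via a full eigendecomposition of the
    feature covariance (independent of the SVD route)."""
    mu = values.mean(axis=1, keepdims=True)
    c = values - mu
    cov = c @ c.T
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    u = v[:, order[:k]]
    return c - u @ (u.T @ c) + mu
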
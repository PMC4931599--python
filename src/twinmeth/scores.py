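"""Filter scores for feature (CpG probe) selection.

Six scores, each computed on training samples only by the resampling
harness: absolute Welch t, absolute mean difference, Welch p-value,
absolute Pearson correlation with the 0/1 label, moderated-t p-value
(empirical-Bayes shrunk residual variance, the defining computation of
the limma single-covariate fit), and the paired rank product (geometric
mean over twin pairs of the feature's within-pair difference rank,
two-sided via the min of the up and down directions).

Selection is top-n by each score's better direction
(:func:`select_top`), never threshold-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .datasets import LabeledDataset, ValidationError

HIGHER = "higher_is_better"
LOWER = "lower_is_better"

#: sentinel replacing an infinite t on zero-variance features; sorts first
ZERO_VARIANCE_SENTINEL = 1e300

METHOD_NAMES = (
    "welch_t",
    "mean_diff",
    "welch_p",
    "correlation",
    "moderated_p",
    "rank_product",
)


@dataclass(frozen=True)
class FeatureScore:
    feature_id: str
    score: float
    direction: str
    flagged: bool = False


def _groups(values: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    aff = values[:, labels == 1]
    unaff = values[:, labels == 0]
    return aff, unaff


def _welch_core(values: np.ndarray, labels: np.ndarray):
    aff, unaff = _groups(values, labels)
    n1, n0 = aff.shape[1], unaff.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValidationError("Welch statistics need >= 2 samples per class")
    m1, m0 = aff.mean(axis=1), unaff.mean(axis=1)
    v1 = aff.var(axis=1, ddof=1)
    v0 = unaff.var(axis=1, ddof=1)
    se2 = v1 / n1 + v0 / n0
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
    zero_var = se2 == 0.0
    t = np.where(zero_var, np.where(diff == 0.0, 0.0, np.inf), t)
    return t, df, zero_var


def _welch_t_arrays(values, labels, pair_codes=None):
    t, _, zero_var = _welch_core(values, labels)
    out = np.abs(t)
    out[~np.isfinite(out)] = ZERO_VARIANCE_SENTINEL
    return out, HIGHER, zero_var


def _mean_diff_arrays(values, labels, pair_codes=None):
    aff, unaff = _groups(values, labels)
    if aff.shape[1] == 0 or unaff.shape[1] == 0:
        raise ValidationError("mean difference needs both classes present")
    out = np.abs(aff.mean(axis=1) - unaff.mean(axis=1))
    return out, HIGHER, np.zeros(values.shape[0], dtype=bool)


def _welch_p_arrays(values, labels, pair_codes=None):
    t, df, zero_var = _welch_core(values, labels)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-variance, nonzero difference: infinitely strong evidence
    p = np.where(zero_var, np.where(t == 0.0, 1.0, 0.0), p)
    return p, LOWER, zero_var


def _correlation_arrays(values, labels, pair_codes=None):
    labels = np.asarray(labels, dtype=float)
    if values.shape[1] < 3 or len(np.unique(labels)) < 2:
        raise ValidationError("correlation needs >= 3 samples and both classes")
    xc = values - values.mean(axis=1, keepdims=True)
    yc = labels - labels.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    flagged = denom == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / denom
    r = np.where(flagged, 0.0, r)
    return np.abs(r), HIGHER, flagged


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def moderated_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df d0, prior_var s0^2) from the
    log residual variances, matching the scaled-F marginal of the
    conjugate inverse-chi-square prior."""
    ok = s2 > 0.0
    if ok.sum() < 2:
        raise ValidationError("need >= 2 positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0.0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(
            np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s02 = float(np.exp(e.mean()))
    return d0, s02


def _moderated_p_arrays(
    values, labels, pair_codes=None, prior_df=None, prior_var=None
):
    aff, unaff = _groups(values, labels)
    n1, n0 = aff.shape[1], unaff.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValidationError("moderated t needs >= 2 samples per class")
    n = n1 + n0
    df = n - 2
    if df < 1:
        raise ValidationError("insufficient residual degrees of freedom")
    diff = aff.mean(axis=1) - unaff.mean(axis=1)
    sse = ((aff - aff.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (unaff - unaff.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = sse / df
    if prior_df is None:
        d0, s02 = moderated_variance_prior(s2, df)
    else:
        d0 = prior_df
        s02 = prior_var if prior_var is not None else 0.0
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    flagged = s2_tilde <= 0.0
    s2_tilde = np.where(flagged, _floor(s2), s2_tilde)
    t = diff / np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n0))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return p, LOWER, flagged


def _floor(s2: np.ndarray) -> float:
    pos = s2[s2 > 0]
    return float(pos.min()) * 1e-6 if pos.size else 1e-12


def _pair_differences(values, labels, pair_codes):
    """G x P matrix of affected-minus-unaffected differences per pair."""
    if pair_codes is None:
        raise ValidationError("rank product needs pair structure")
    labels = np.asarray(labels)
    pair_codes = np.asarray(pair_codes)
    diffs = []
    for p in np.unique(pair_codes):
        idx = np.flatnonzero(pair_codes == p)
        if idx.size != 2 or labels[idx].sum() != 1:
            raise ValidationError(
                "rank product needs complete discordant pairs"
            )
        a = idx[labels[idx] == 1][0]
        u = idx[labels[idx] == 0][0]
        diffs.append(values[:, a] - values[:, u])
    return np.column_stack(diffs)


def _rank_product_arrays(values, labels, pair_codes=None):
    d = _pair_differences(values, labels, pair_codes)
    g = d.shape[0]
    # ascending rank: 1 = most negative; descending: 1 = most positive
    asc = np.apply_along_axis(stats.rankdata, 0, d)
    desc = g + 1.0 - asc
    rp_down = np.exp(np.log(asc).mean(axis=1))
    rp_up = np.exp(np.log(desc).mean(axis=1))
    out = np.minimum(rp_up, rp_down)
    return out, LOWER, np.zeros(g, dtype=bool)


_ARRAY_FUNCS = {
    "welch_t": _welch_t_arrays,
    "mean_diff": _mean_diff_arrays,
    "welch_p": _welch_p_arrays,
    "correlation": _correlation_arrays,
    "moderated_p": _moderated_p_arrays,
    "rank_product": _rank_product_arrays,
}


def score_arrays(
    values: np.ndarray,
    labels: np.ndarray,
    method: str,
    pair_codes: np.ndarray | None = None,
) -> tuple[np.ndarray, str]:
    """Fast path: score a raw matrix, returning (scores, direction)."""
    if method not in _ARRAY_FUNCS:
        raise ValidationError(
            f"unknown score {method!r}; expected one of {METHOD_NAMES}"
        )
    s, direction, _ = _ARRAY_FUNCS[method](values, labels, pair_codes)
    return s, direction


def compute_scores(data: LabeledDataset, method: str, **kwargs) -> list[FeatureScore]:
    if method not in _ARRAY_FUNCS:
        raise ValidationError(
            f"unknown score {method!r}; expected one of {METHOD_NAMES}"
        )
    pair_codes = np.array(data.pair_ids())
    s, direction, flagged = _ARRAY_FUNCS[method](
        data.values, data.labels(), pair_codes, **kwargs
    )
    return [
        FeatureScore(f, float(s[i]), direction, bool(flagged[i]))
        for i, f in enumerate(data.feature_ids)
    ]


def score_welch_t(data: LabeledDataset) -> list[FeatureScore]:
    """Absolute Welch two-sample t statistic, higher is better."""
    return compute_scores(data, "welch_t")


def score_mean_diff(data: LabeledDataset) -> list[FeatureScore]:
    """Absolute difference of class means, higher is better."""
    return compute_scores(data, "mean_diff")


def score_welch_p(data: LabeledDataset) -> list[FeatureScore]:
    """Two-sided Welch p-value (Welch-Satterthwaite df), lower is better."""
    return compute_scores(data, "welch_p")


def score_correlation(data: LabeledDataset) -> list[FeatureScore]:
    """Absolute Pearson correlation with the 0/1 label, higher is better."""
    return compute_scores(data, "correlation")


def score_moderated_p(
    data: LabeledDataset,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> list[FeatureScore]:
    """Moderated-t p-value with empirical-Bayes variance shrinkage.

    ``prior_df``/``prior_var`` override the method-of-moments
    hyperparameters; ``prior_df=0`` recovers the ordinary
    pooled-variance t-test.
    """
    return compute_scores(
        data, "moderated_p", prior_df=prior_df, prior_var=prior_var
    )


def score_rank_product(data: LabeledDataset) -> list[FeatureScore]:
    """Two-sided paired rank product, lower is better."""
    return compute_scores(data, "rank_product")


def select_top(scores: list[FeatureScore], n: int) -> list[str]:
    """Top-n feature ids by the score's direction.

    Ties are broken by ascending position in the input list, so the
    selection is deterministic and stable.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if n > len(scores):
        raise ValidationError(f"n={n} exceeds the {len(scores)} scored features")
    directions = {s.direction for s in scores}
    if len(directions) != 1:
        raise ValidationError("scores mix directions")
    arr = np.array([s.score for s in scores])
    idx = select_top_indices(arr, directions.pop(), n)
    return [scores[i].feature_id for i in idx]


def select_top_indices(scores: np.ndarray, direction: str, n: int) -> np.ndarray:
    key = -scores if direction == HIGHER else scores
    order = np.argsort(key, kind="stable")
    return order[:n]
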
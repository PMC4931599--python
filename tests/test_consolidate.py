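"""PCA subtraction, normalization baselines and the empirical-Bayes
batch adjustment, checked against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy import stats

import twinmeth as tm
from twinmeth.consolidate import (
    ConsolidationSpec,
    combat,
    combat_adjust,
    combat_estimate_batch_params,
    combat_estimate_batch_params_parametric,
    combat_standardize,
    norm_mean,
    norm_scale,
    pca_adjust,
)
from twinmeth.datasets import ValidationError
from twinmeth.simulate import SyntheticConfig

from helpers import dense_pca_residual, make_dataset


def _single_region(rng, g, n_pairs, batch="R1"):
    pair_ids, statuses = [], []
    for p in range(n_pairs):
        pair_ids += [f"{batch}p{p}", f"{batch}p{p}"]
        statuses += ["affected", "unaffected"]
    return make_dataset(
        rng.normal(0, 1, (g, 2 * n_pairs)),
        pair_ids,
        statuses,
        [batch] * (2 * n_pairs),
        sample_ids=[f"{batch}s{j}" for j in range(2 * n_pairs)],
    )


# ---------------------------------------------------------------------------
# PCA subtraction
# ---------------------------------------------------------------------------

class TestPcaAdjust:
    def test_k0_is_identity(self, rng):
        data = _single_region(rng, 20, 5)
        out, diag = pca_adjust(data, 0)
        np.testing.assert_array_equal(out.values, data.values)
        assert diag.removed_variance_fraction == 0.0

    def test_rank1_centered_matrix_is_annihilated(self):
        u = np.arange(1.0, 6.0)[:, None]
        v = np.array([[1.0, -1.0, 2.0, -2.0]])
        values = u @ v + 7.0  # rank-1 after centering? centering keeps rank 1
        data = make_dataset(
            values,
            ["P1", "P1", "P2", "P2"],
            ["affected", "unaffected", "affected", "unaffected"],
            ["R"] * 4,
        )
        out, _ = pca_adjust(data, 1)
        mu = out.values.mean(axis=1, keepdims=True)
        assert np.max(np.abs(out.values - mu)) < 1e-10

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        data = _single_region(rng, 50, 10)
        out, diag = pca_adjust(data, 3)
        oracle = dense_pca_residual(data.values, 3)
        assert np.max(np.abs(out.values - oracle)) < 1e-8
        # zero projection onto removed axes
        c = data.values - data.values.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(c, full_matrices=False)
        proj = u[:, :3].T @ (out.values - out.values.mean(axis=1, keepdims=True))
        assert np.max(np.abs(proj)) < 1e-8
        expected_frac = np.sum(s[:3] ** 2) / np.sum(s**2)
        assert diag.removed_variance_fraction == pytest.approx(expected_frac)

    def test_feature_means_are_preserved(self, rng):
        data = _single_region(rng, 30, 8)
        out, _ = pca_adjust(data, 4)
        np.testing.assert_allclose(
            out.values.mean(axis=1), data.values.mean(axis=1), atol=1e-10
        )

    def test_k_beyond_rank_is_rejected(self, rng):
        data = _single_region(rng, 10, 3)  # centered rank <= 5
        with pytest.raises(ValidationError, match="variance"):
            pca_adjust(data, 6)
        with pytest.raises(ValidationError, match="single-region"):
            pca_adjust(
                tm.merge_regions(
                    [data, _single_region(rng, 10, 3, batch="R2")]
                ),
                1,
            )


# ---------------------------------------------------------------------------
# normalization baselines
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_norm_mean_examples_and_permutation_commutes(self, rng):
        data = _single_region(rng, 12, 4)
        data.dataset.values[0] = [1.0, 3.0] * 4
        out = norm_mean(data)
        assert np.max(np.abs(out.values.mean(axis=1))) < 1e-12
        np.testing.assert_allclose(out.values[0], [-1.0, 1.0] * 4)
        np.testing.assert_allclose(
            out.values.var(axis=1), data.values.var(axis=1)
        )
        # permuting pairs of columns commutes with normalization
        perm = np.array([2, 3, 0, 1, 6, 7, 4, 5])
        np.testing.assert_allclose(
            norm_mean(data.subset_samples(perm)).values,
            out.subset_samples(perm).values,
        )

    def test_norm_scale_unit_sd_and_degenerate_row(self, rng):
        data = _single_region(rng, 10, 5)
        data.dataset.values[3] = 5.0  # constant row
        with pytest.warns(UserWarning, match="zero-variance"):
            out = norm_scale(data)
        sd = out.values.std(axis=1, ddof=1)
        keep = np.arange(10) != 3
        assert np.max(np.abs(sd[keep] - 1.0)) < 1e-10
        np.testing.assert_array_equal(out.values[3], 0.0)
        # two-point row under the N-1 convention
        row = np.tile([1.0, 3.0], 5)
        expected = (row - 2.0) / np.std(row, ddof=1)
        data.dataset.values[0] = row
        with pytest.warns(UserWarning):
            np.testing.assert_allclose(norm_scale(data).values[0], expected)


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

def _planted_batches(rng, g=40, pairs=(5, 6, 7), gamma_sd=1.0, noise=0.0):
    """Data = alpha_g + gamma_ig + optional noise, discordant pairs."""
    alpha = rng.normal(0, 1, g)
    gammas = [rng.normal(0, gamma_sd, g) for _ in pairs]
    regions = []
    for i, n_pairs in enumerate(pairs):
        n = 2 * n_pairs
        vals = alpha[:, None] + gammas[i][:, None] + rng.normal(0, noise, (g, n))
        pair_ids, statuses = [], []
        for p in range(n_pairs):
            pair_ids += [f"B{i}p{p}", f"B{i}p{p}"]
            statuses += ["affected", "unaffected"]
        regions.append(
            make_dataset(
                vals, pair_ids, statuses, [f"B{i}"] * n,
                sample_ids=[f"B{i}s{j}" for j in range(n)],
            )
        )
    merged = regions[0] if len(regions) == 1 else tm.merge_regions(regions)
    return merged, alpha, np.vstack(gammas)


class TestCombat:
    def test_standardize_zero_noise_closed_form(self, rng):
        """Exact batch-plus-baseline data: Z has no within-batch variance
        and its batch means recover the constrained planted gamma."""
        merged, alpha, gamma = _planted_batches(rng, noise=0.0)
        with pytest.warns(UserWarning, match="zero residual variance"):
            z, model = combat_standardize(merged, include_status=False)
        n_per = model.n_per_batch
        w = n_per / n_per.sum()
        gamma_hat = gamma - w @ gamma  # weighted-constraint estimates
        np.testing.assert_allclose(model.alpha_hat, alpha + w @ gamma, atol=1e-8)
        batch_arr = np.array(merged.batch_ids())
        sigma = np.sqrt(model.sigma2_hat)
        for i, lab in enumerate(model.batch_labels):
            zb = z[:, batch_arr == lab]
            assert np.max(zb.std(axis=1) * sigma) < 1e-8
            np.testing.assert_allclose(
                zb.mean(axis=1) * sigma, gamma_hat[i], atol=1e-8
            )

    def test_standardize_matches_per_feature_least_squares(self, rng):
        """Noisy data: fitted parameters match an explicit per-feature
        weighted-constraint least-squares oracle."""
        merged, _, _ = _planted_batches(rng, g=15, noise=0.7)
        z, model = combat_standardize(merged, include_status=False)
        y = merged.values
        batch_arr = np.array(merged.batch_ids())
        labs = merged.batches()
        n_per = np.array([(batch_arr == b).sum() for b in labs])
        w = n_per / n_per.sum()
        for g in range(y.shape[0]):
            batch_means = np.array(
                [y[g, batch_arr == b].mean() for b in labs]
            )
            alpha_g = float(w @ batch_means)
            resid = np.concatenate(
                [y[g, batch_arr == b] - batch_means[i] for i, b in enumerate(labs)]
            )
            sigma2_g = float(np.mean(resid**2))
            assert model.alpha_hat[g] == pytest.approx(alpha_g, abs=1e-9)
            assert model.sigma2_hat[g] == pytest.approx(sigma2_g, abs=1e-9)
            np.testing.assert_allclose(
                z[g], (y[g] - alpha_g) / np.sqrt(sigma2_g), atol=1e-9
            )

    def test_standardize_constraint_and_confounding_error(self, rng):
        merged, _, _ = _planted_batches(rng, noise=0.5)
        z, model = combat_standardize(merged, include_status=True)
        model = combat_estimate_batch_params(z, merged, model)
        weighted = (model.n_per_batch[:, None] * model.gamma_hat).sum(axis=0)
        assert np.max(np.abs(weighted)) < 1e-8
        # a single batch cannot be standardized
        half, _, _ = _planted_batches(rng, pairs=(6,), gamma_sd=0.0, noise=1.0)
        with pytest.raises(ValidationError, match="2 batches"):
            combat_standardize(half, include_status=False)

    def test_two_feature_leave_one_out_swaps_estimates(self, rng):
        merged, _, _ = _planted_batches(rng, g=2, noise=0.7)
        z, model = combat_standardize(merged, include_status=False)
        model = combat_estimate_batch_params(z, merged, model)
        # with exactly two features each posterior is the other's raw estimate
        np.testing.assert_allclose(model.gamma_star[:, 0], model.gamma_hat[:, 1])
        np.testing.assert_allclose(model.gamma_star[:, 1], model.gamma_hat[:, 0])
        np.testing.assert_allclose(model.delta2_star[:, 0], model.delta2_hat[:, 1])

    def test_posterior_shrinks_toward_cross_feature_mean(self, rng):
        # iid features sharing one true (gamma, delta2)
        merged, _, _ = _planted_batches(rng, g=120, gamma_sd=0.0, noise=1.0)
        z, model = combat_standardize(merged, include_status=False)
        model = combat_estimate_batch_params(z, merged, model)
        for i in range(len(model.batch_labels)):
            assert model.gamma_star[i].var() < model.gamma_hat[i].var()
            assert model.delta2_star[i].var() < model.delta2_hat[i].var()

    def test_large_batch_posterior_recovers_planted_gamma(self):
        rng = np.random.default_rng(7)
        merged, _, gamma = _planted_batches(
            rng, g=200, pairs=(250, 250), gamma_sd=1.0, noise=1.0
        )
        z, model = combat_standardize(merged, include_status=False)
        model = combat_estimate_batch_params(z, merged, model)
        n_per = model.n_per_batch
        w = n_per / n_per.sum()
        gamma_centered = gamma - w @ gamma
        sigma = np.sqrt(model.sigma2_hat)
        rms = np.sqrt(np.mean((model.gamma_star * sigma - gamma_centered) ** 2))
        assert rms < 0.05

    def test_identity_adjustment_round_trips(self, rng):
        merged, _, _ = _planted_batches(rng, noise=0.8)
        z, model = combat_standardize(merged, include_status=True)
        model = combat_estimate_batch_params(z, merged, model)
        model.gamma_star = np.zeros_like(model.gamma_star)
        model.delta2_star = np.ones_like(model.delta2_star)
        out = combat_adjust(merged, model)
        assert np.max(np.abs(out.values - merged.values)) < 1e-10

    def test_adjustment_removes_planted_additive_effects(self, rng):
        merged, _, _ = _planted_batches(rng, g=300, gamma_sd=1.0, noise=1.0)
        batch_arr = np.array(merged.batch_ids())
        groups = lambda v: [v[:, batch_arr == b] for b in merged.batches()]
        f_pre, _ = stats.f_oneway(*groups(merged.values), axis=1)
        adjusted, _ = combat(merged, include_status=True)
        f_post, _ = stats.f_oneway(*groups(adjusted.values), axis=1)
        assert np.mean(f_post < f_pre) >= 0.95

    def test_zero_noise_batch_means_agree_after_adjustment(self, rng):
        """Vanishing-noise additive-only data: the conjugate-posterior
        adjustment equalizes per-batch feature means exactly (the
        leave-one-out nonparametric posterior substitutes donor features'
        estimates and is only asymptotically exact)."""
        merged, _, _ = _planted_batches(rng, g=60, gamma_sd=1.0, noise=1e-6)
        adjusted, _ = combat(merged, include_status=False, parametric=True)
        batch_arr = np.array(merged.batch_ids())
        means = np.stack(
            [
                adjusted.values[:, batch_arr == b].mean(axis=1)
                for b in merged.batches()
            ]
        )
        assert np.max(means.max(axis=0) - means.min(axis=0)) < 1e-5

    def test_pipeline_idempotent_in_additive_limit(self, rng):
        merged, _, _ = _planted_batches(rng, g=80, gamma_sd=1.0, noise=1e-6)
        once, _ = combat(merged, include_status=False, parametric=True)
        twice, _ = combat(once, include_status=False, parametric=True)
        assert np.max(np.abs(twice.values - once.values)) < 1e-6

    def test_parametric_variant_agrees_on_conjugate_simulation(self):
        cfg = SyntheticConfig(
            pairs_per_batch=(25, 25, 25), n_features=500, n_signal_features=0,
            batch_additive_sd=1.0, batch_multiplicative_shape=6.0,
            n_strat_components=0, strat_sd=0.0, pair_sd=0.0, seed=21,
        )
        data, _ = tm.simulate_cohort(cfg)
        nonpar, _ = combat(data, include_status=True, parametric=False)
        par, _ = combat(data, include_status=True, parametric=True)
        corr = [
            np.corrcoef(nonpar.values[i], par.values[i])[0, 1]
            for i in range(data.n_features)
        ]
        assert np.mean(corr) > 0.99


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

class TestConsolidate:
    def test_raw_single_region_is_identity(self, rng):
        data = _single_region(rng, 15, 4)
        out = tm.consolidate([data], ConsolidationSpec("RAW"))
        np.testing.assert_array_equal(out.values, data.values)

    def test_pca_combat_equals_manual_composition(self, small_regions):
        spec = ConsolidationSpec("PCA_ComBat", 3)
        auto = tm.consolidate(small_regions, spec)
        manual = tm.merge_regions([pca_adjust(d, 3)[0] for d in small_regions])
        manual, _ = combat(manual, include_status=True)
        np.testing.assert_allclose(auto.values, manual.values)
        assert auto.metadata == manual.metadata

    def test_norm_mean_zeroes_per_region_grand_means(self, small_regions):
        out = tm.consolidate(small_regions, ConsolidationSpec("NormMean"))
        batch_arr = np.array(out.batch_ids())
        for b in out.batches():
            means = out.values[:, batch_arr == b].mean(axis=1)
            assert np.max(np.abs(means)) < 1e-12

    def test_metadata_and_ids_untouched_for_all_specs(self, small_regions):
        specs = [
            ConsolidationSpec("RAW"),
            ConsolidationSpec("NormScale"),
            ConsolidationSpec("PCA", 2),
            ConsolidationSpec("ComBat"),
            ConsolidationSpec("PCA_ComBat", 2),
        ]
        reference = tm.merge_regions(small_regions)
        for spec in specs:
            out = tm.consolidate(small_regions, spec)
            assert out.sample_ids == reference.sample_ids
            assert out.feature_ids == reference.feature_ids
            assert out.metadata == reference.metadata

    def test_spec_validation(self):
        with pytest.raises(ValidationError, match="k >= 1"):
            ConsolidationSpec("PCA", 0)
        with pytest.raises(ValidationError, match="unknown"):
            ConsolidationSpec("Quantile")
        assert ConsolidationSpec("PCA_ComBat", 4).label == "PCA.4+ComBat"
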
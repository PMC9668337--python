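"""Permutation GLM, effect sizes, FDR, PCA reduction and the CCA pipeline."""

import numpy as np
import pytest

from shapeasym.group_stats import (
    ExchangeabilityBlocks,
    canonical_correlations,
    cca_pipeline,
    cohens_d,
    fdr_bh,
    glm_permutation,
    pca_reduce,
)


class TestCohensD:
    def test_unit_effect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, size=5000)
        b = rng.normal(0.0, 1.0, size=5000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.06)

    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    def test_swapping_groups_flips_sign(self):
        a, b = np.array([1.0, 2.0]), np.array([3.0, 5.0])
        assert cohens_d(a, b) == -cohens_d(b, a)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(np.ones(3), np.ones(4))


class TestFDR:
    def test_step_up_by_hand(self):
        # 0.01 <= 0.05*1/3 and 0.02 <= 0.05*2/3; 0.5 > 0.05
        reject, _ = fdr_bh([0.01, 0.02, 0.5], q=0.05)
        assert list(reject) == [True, True, False]

    def test_all_ones_no_rejections(self):
        reject, _ = fdr_bh(np.ones(10))
        assert not reject.any()

    def test_single_small_p_rejected(self):
        reject, adj = fdr_bh([0.04])
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_empty_input(self):
        reject, adj = fdr_bh([])
        assert reject.size == 0 and adj.size == 0


class TestBlocks:
    def test_permutation_never_splits_a_family(self):
        labels = np.repeat(np.arange(10), 2)
        blocks = ExchangeabilityBlocks(labels)
        rng = np.random.default_rng(1)
        for _ in range(50):
            perm = blocks.permutation(rng)
            # members of one family must land on one family's slots
            assert all(labels[perm[2 * i]] == labels[perm[2 * i + 1]]
                       for i in range(10))

    def test_singleton_blocks_reach_all_orderings(self):
        blocks = ExchangeabilityBlocks.singletons(5)
        rng = np.random.default_rng(2)
        perms = {tuple(blocks.permutation(rng)) for _ in range(300)}
        assert len(perms) > 100  # far beyond block-restricted counts

    def test_bootstrap_resamples_whole_blocks(self):
        labels = np.array(["a", "a", "b", "b", "c"])
        blocks = ExchangeabilityBlocks(labels)
        idx = blocks.bootstrap(np.random.default_rng(3))
        drawn = labels[idx]
        # each drawn family appears with all of its members contiguously
        i = 0
        while i < len(drawn):
            fam = drawn[i]
            size = (labels == fam).sum()
            assert set(drawn[i:i + size]) == {fam}
            i += size


class TestGLMPermutation:
    def test_null_predictor_large_p(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=80)
        x = rng.normal(size=80)
        beta, p, _ = glm_permutation(y, x, n_perm=500, seed=0)
        assert p > 0.01

    def test_injected_effect_detected(self):
        rng = np.random.default_rng(5)
        x = np.repeat([0.0, 1.0], 100)
        y = x + rng.normal(size=200)
        beta, p, _ = glm_permutation(y, x, n_perm=999, seed=0)
        # SE of the group-difference estimate is ~0.14 here
        assert beta == pytest.approx(1.0, abs=0.4)
        assert p < 0.005

    def test_covariates_absorb_confound(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=150)
        x = z + 0.3 * rng.normal(size=150)
        y = 2.0 * z + rng.normal(size=150)  # y relates to x only through z
        _, p_raw, _ = glm_permutation(y, x, n_perm=499, seed=1)
        _, p_adj, _ = glm_permutation(y, x, covariates=z[:, None],
                                      n_perm=499, seed=1)
        assert p_raw < 0.01 < p_adj

    def test_rank_deficient_design_rejected(self):
        y = np.arange(10.0)
        x = np.ones(10)  # collinear with the intercept
        with pytest.raises(ValueError, match="rank"):
            glm_permutation(y, x, n_perm=10)

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha = 0.05 over null simulations falls in the
        binomial 95% interval."""
        rng = np.random.default_rng(7)
        n, n_sim = 40, 400
        labels = np.repeat(np.arange(20), 2)
        blocks = ExchangeabilityBlocks(labels)
        rejections = 0
        for sim in range(n_sim):
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            _, p, _ = glm_permutation(y, x, blocks=blocks, n_perm=199, seed=sim)
            rejections += p <= 0.05
        rate = rejections / n_sim
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < ci + 1e-9


class TestPCAReduce:
    def test_four_planted_factors_recovered(self):
        rng = np.random.default_rng(8)
        factors = rng.normal(size=(300, 4))
        # 13 measures in 4 disjoint blocks, one factor each: after
        # standardization the variance shares are ~(4,3,3,3)/13, so three
        # components explain ~77% and the fourth is needed to reach 80%
        mixing = np.zeros((4, 13))
        for fac, cols in enumerate([(0, 1, 2, 3), (4, 5, 6), (7, 8, 9),
                                    (10, 11, 12)]):
            mixing[fac, list(cols)] = 1.0
        data = factors @ mixing + 0.05 * rng.normal(size=(300, 13))
        scores, loadings, ratio = pca_reduce(data, 0.80)
        assert scores.shape[1] == 4

    def test_full_variance_keeps_all_components(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(50, 6))
        scores, *_ = pca_reduce(data, 1.0)
        assert scores.shape[1] == 6

    def test_missing_values_rejected(self):
        data = np.ones((10, 3))
        data[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca_reduce(data)


class TestCCA:
    def test_duplicated_block_gives_unit_correlation(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 4))
        r, _, _ = canonical_correlations(X, X.copy())
        assert r[0] == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(80, 5))
        Y = rng.normal(size=(80, 3))
        r0, _, _ = canonical_correlations(X, Y)
        A = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        r1, _, _ = canonical_correlations(X @ A + 7.0, Y * 2.5 - 1.0)
        np.testing.assert_allclose(r0, r1, atol=1e-10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            canonical_correlations(np.zeros((5, 4)), np.zeros((5, 3)))

    def test_planted_mode_detected_and_loaded(self):
        """A single linear relation between one X column and one Y factor is
        found as a significant first mode with that column's loading
        surviving FDR."""
        rng = np.random.default_rng(12)
        n = 300
        latent = rng.normal(size=n)
        X = rng.normal(size=(n, 11))
        X[:, 4] += 1.2 * latent
        Y = rng.normal(size=(n, 4))
        Y[:, 0] += 1.2 * latent
        res = cca_pipeline(X, Y, n_perm=199, n_boot=199, seed=0)
        assert res.p_fwer[0] < 0.05
        assert res.x_loading_p_fdr[4] < 0.05
        assert abs(res.x_loadings[4]) == max(abs(res.x_loadings))

    def test_null_mode_calibration(self):
        """First-mode FWER rejection rate under independence stays near the
        nominal level."""
        rng = np.random.default_rng(13)
        n, n_sim = 80, 300
        rejections = 0
        for sim in range(n_sim):
            X = rng.normal(size=(n, 5))
            Y = rng.normal(size=(n, 3))
            res_r, _, _ = canonical_correlations(X, Y)
            # direct max-statistic permutation, small n_perm for speed
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            Qx, _ = np.linalg.qr(Xc)
            Qy, _ = np.linalg.qr(Yc)
            null = np.empty(99)
            for b in range(99):
                perm = rng.permutation(n)
                null[b] = np.linalg.svd(Qx.T @ Qy[perm], compute_uv=False)[0]
            p = (np.sum(null >= res_r[0]) + 1) / 100
            rejections += p <= 0.05
        rate = rejections / n_sim
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < ci + 1e-9

    def test_permutation_p_invariant_to_joint_reordering(self):
        """Jointly reordering subjects changes neither the canonical
        correlations nor a floor p-value from a planted strong mode."""
        rng = np.random.default_rng(14)
        n = 120
        latent = rng.normal(size=n)
        X = rng.normal(size=(n, 4)) + 2.0 * latent[:, None]
        Y = rng.normal(size=(n, 3)) + 2.0 * latent[:, None]
        res_a = cca_pipeline(X, Y, n_perm=199, n_boot=10, seed=5)
        perm = rng.permutation(n)
        res_b = cca_pipeline(X[perm], Y[perm], n_perm=199, n_boot=10, seed=5)
        np.testing.assert_allclose(res_a.correlations, res_b.correlations,
                                   atol=1e-12)
        assert res_a.p_fwer[0] == res_b.p_fwer[0] == pytest.approx(1 / 200)
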
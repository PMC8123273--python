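import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fatiguehrv import featstats
from fatiguehrv.pipeline import PipelineConfig, build_feature_table


class TestKSNormality:
    def test_normal_data_rarely_rejected(self):
        rejects = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=5000)
            rejects += featstats.ks_normality(x).reject
        assert rejects <= 5  # >= 95% acceptance under H0

    def test_uniform_data_rejected(self):
        x = np.random.default_rng(0).uniform(size=5000)
        assert featstats.ks_normality(x).reject

    def test_constant_column_degenerate(self):
        with pytest.raises(featstats.DegenerateInputError):
            featstats.ks_normality(np.full(100, 3.0))


class TestFriedman:
    def test_full_ties_give_zero(self):
        blocks = np.tile([5.0, 5.0, 5.0], (10, 1))
        res = featstats.friedman_test(blocks)
        assert res.statistic == 0.0

    def test_hand_computed_example(self):
        """Two blocks both ranked (1,2,3): rank sums (2,4,6) and
        X2 = 12/(2*3*4) * (4+16+36) - 3*2*4 = 4."""
        blocks = np.array([[1.0, 2.0, 3.0], [1.5, 2.5, 3.5]])
        res = featstats.friedman_test(blocks)
        np.testing.assert_allclose(res.rank_sums, [2.0, 4.0, 6.0])
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 2

    def test_matches_brute_force_and_scipy(self):
        """Tie-corrected statistic equals scipy's on random 20x3 tables;
        uncorrected equals the direct rank-sum arithmetic."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            blocks = rng.normal(size=(20, 3))
            res = featstats.friedman_test(blocks)
            sp = stats.friedmanchisquare(*blocks.T)
            assert res.statistic == pytest.approx(sp.statistic)
            assert res.p_value == pytest.approx(sp.pvalue)
            # brute force: explicit ranking + the plain formula (no ties here)
            ranks = np.vstack([stats.rankdata(row) for row in blocks])
            rj = ranks.sum(axis=0)
            n, m = blocks.shape
            x2 = 12.0 / (n * m * (m + 1)) * np.sum(rj ** 2) - 3 * n * (m + 1)
            un = featstats.friedman_test(blocks, tie_correction=False)
            assert un.statistic == pytest.approx(x2)

    def test_rank_sum_invariant(self):
        rng = np.random.default_rng(4)
        blocks = rng.normal(size=(15, 3))
        res = featstats.friedman_test(blocks)
        n, m = blocks.shape
        assert res.rank_sums.sum() == pytest.approx(n * m * (m + 1) / 2)

    def test_exact_permutation_vs_monte_carlo(self):
        """The exact (m!)^n enumeration agrees with a sampled permutation
        oracle within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        blocks = rng.normal(size=(4, 3)) + np.array([0.0, 0.4, 0.8])
        p_exact = featstats.friedman_exact_permutation_pvalue(blocks)
        obs, _ = featstats.friedman_statistic(blocks)
        n_mc = 4000
        count = 0
        perms = [np.array(p) for p in
                 __import__("itertools").permutations(range(3))]
        for _ in range(n_mc):
            permuted = np.vstack([row[perms[rng.integers(6)]] for row in blocks])
            stat, _ = featstats.friedman_statistic(permuted)
            count += stat >= obs - 1e-12
        p_mc = count / n_mc
        se = np.sqrt(p_exact * (1 - p_exact) / n_mc)
        assert abs(p_exact - p_mc) <= 4 * se + 1e-9

    def test_incomplete_blocks_rejected(self):
        blocks = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            featstats.friedman_test(blocks)


@pytest.fixture(scope="module")
def small_cohort_table():
    cfg = PipelineConfig(signal_level="rr", n_participants=12,
                         session_duration=900.0, n_test_participants=2,
                         seed=42)
    return build_feature_table(cfg)


@pytest.fixture(scope="module")
def correlated_table():
    rng = np.random.default_rng(10)
    latent = rng.normal(size=(300, 3))
    mix = rng.normal(size=(3, 8))
    x = latent @ mix + 0.1 * rng.normal(size=(300, 8))
    return pd.DataFrame(x, columns=[f"f{i}" for i in range(8)])


class TestSelection:
    def test_state_responsive_indexes_selected(self, small_cohort_table):
        """The ten indexes known to separate the three fatigue states are
        all retained by the Friedman screen."""
        sel = featstats.select_features(small_cohort_table)
        expected = {"T1_AVNN", "T2_AVHR", "T5_RMSSD", "T7_PNN50",
                    "F3_LFnorm", "F6_HFnorm", "F8_LF_HF",
                    "N1_SD1", "N4_Aplus", "N5_Bminus"}
        assert expected.issubset(set(sel.selected))

    def test_report_layout(self, small_cohort_table):
        sel = featstats.select_features(small_cohort_table)
        assert {"feature", "state", "mean", "sd", "mean_rank", "chi_square",
                "p_value"}.issubset(sel.report.columns)
        # three rows (states) per tested feature
        counts = sel.report.groupby("feature").size()
        assert (counts == 3).all()

    def test_null_feature_type_one_error_rate(self):
        """A pure-noise feature is selected at ~alpha over repeated tables."""
        rng = np.random.default_rng(9)
        alpha = 0.05
        hits = 0
        n_tables = 200
        for i in range(n_tables):
            blocks = rng.normal(size=(20, 3))
            hits += featstats.friedman_test(blocks, alpha=alpha).significant
        rate = hits / n_tables
        assert abs(rate - alpha) < 0.04

    def test_constant_feature_excluded_with_warning(self, small_cohort_table):
        tab = small_cohort_table.copy()
        tab["constant"] = 1.0
        with pytest.warns(UserWarning):
            sel = featstats.select_features(tab)
        assert "constant" in sel.excluded_constant
        assert "constant" not in sel.selected

    def test_unmatched_blocks_raise(self, small_cohort_table):
        broken = small_cohort_table[~((small_cohort_table.participant == 0)
                                      & (small_cohort_table.state == 1)
                                      & (small_cohort_table.window_index == 0))]
        with pytest.raises(ValueError, match="missing a state"):
            featstats.select_features(broken, features=["T1_AVNN"])


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(11)
        u = rng.normal(size=200)
        tab = pd.DataFrame({"a": u, "b": 2 * u, "c": -0.5 * u})
        model = featstats.fit_pca(tab)
        assert model.retained == 1
        assert model.contribution[0] == pytest.approx(1.0)

    def test_isotropic_noise_contributions(self):
        rng = np.random.default_rng(12)
        tab = pd.DataFrame(rng.normal(size=(4000, 10)),
                           columns=[f"f{i}" for i in range(10)])
        model = featstats.fit_pca(tab)
        assert np.all(np.abs(model.contribution - 0.1) < 0.03)

    def test_loading_identity_per_feature(self, correlated_table):
        """For correlation PCA the squared loadings of each feature sum
        to its (unit) standardized variance."""
        model = featstats.fit_pca(correlated_table)
        sums = (model.loadings ** 2).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)

    def test_reconstruction_with_all_components(self, correlated_table):
        model = featstats.fit_pca(correlated_table)
        k = len(model.feature_names)
        scores = featstats.transform_pca(model, correlated_table,
                                         n_components=k, keep_meta=False)
        z = (correlated_table.to_numpy() - model.means) / model.scales
        rec = featstats.inverse_transform_pca(model, scores.to_numpy())
        assert np.abs(rec - z).max() < 1e-8

    def test_scores_uncorrelated_and_variance_equals_eigenvalue(self, correlated_table):
        model = featstats.fit_pca(correlated_table)
        k = len(model.feature_names)
        s = featstats.transform_pca(model, correlated_table,
                                    n_components=k, keep_meta=False).to_numpy()
        n = s.shape[0]
        cov = s.T @ s / (n - 1)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8
        np.testing.assert_allclose(np.diag(cov), model.eigenvalues, atol=1e-10)

    def test_mean_row_maps_to_zero_scores(self, correlated_table):
        model = featstats.fit_pca(correlated_table)
        row = pd.DataFrame([model.means], columns=model.feature_names)
        s = featstats.transform_pca(model, row, keep_meta=False)
        assert np.abs(s.to_numpy()).max() < 1e-12

    def test_matches_sklearn(self, correlated_table):
        from sklearn.decomposition import PCA as SKPCA
        model = featstats.fit_pca(correlated_table)
        z = (correlated_table.to_numpy() - model.means) / model.scales
        sk = SKPCA().fit(z)
        # eigenvalues of the correlation matrix == explained variances
        np.testing.assert_allclose(np.sort(model.eigenvalues),
                                   np.sort(sk.explained_variance_), atol=1e-8)

    def test_zero_variance_feature_named_in_error(self, correlated_table):
        tab = correlated_table.copy()
        tab["flat"] = 0.0
        with pytest.raises(featstats.DegenerateInputError, match="flat"):
            featstats.fit_pca(tab)

    def test_feature_mismatch_rejected(self, correlated_table):
        model = featstats.fit_pca(correlated_table)
        with pytest.raises(ValueError, match="mismatch"):
            featstats.transform_pca(model, correlated_table.drop(columns=["f0"]))

    def test_json_roundtrip(self, correlated_table, tmp_path):
        model = featstats.fit_pca(correlated_table)
        path = tmp_path / "pca.json"
        model.to_json(path)
        back = featstats.PCAModel.from_json(path)
        np.testing.assert_allclose(back.eigenvectors, model.eigenvectors)
        assert back.retained == model.retained
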
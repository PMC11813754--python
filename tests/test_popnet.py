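"""Copula margins, StARS graphical lasso, and network summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isnkit.containers import CountMatrix
from isnkit.popnet import (FamilyConnectivity, PopulationNetwork,
                           exclude_sparse_overlap_samples, family_connectivity,
                           fit_copula_margins, gmpr_size_factors,
                           network_summary_metrics, stars_glasso)
from isnkit.simulate import SimulationConfig, default_taxonomy, generate_cohort
from isnkit.zinb import fit_zinb_regression
from tests.conftest import planted_config


def _net_from_weights(W, taxa=None):
    taxa = taxa or [f"t{k}" for k in range(W.shape[0])]
    w = pd.DataFrame(W, index=taxa, columns=taxa)
    return PopulationNetwork(w, w != 0, 0.1,
                             pd.DataFrame({"rho": [0.1], "instability": [0.0],
                                           "monotone_instability": [0.0]}),
                             [])


class TestSampleExclusion:
    def _cm(self, counts):
        counts = pd.DataFrame(counts,
                              index=[f"s{k}" for k in range(counts.shape[0])],
                              columns=[f"t{k}" for k in range(counts.shape[1])])
        tax = default_taxonomy(counts.shape[1]).set_index(counts.columns)
        meta = pd.DataFrame(index=counts.index)
        meta["outcome"] = "remission"
        return CountMatrix(counts, tax, meta)

    def test_all_zero_sample_removed_and_identity_otherwise(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(14, 12))
        counts[3, :] = 0
        cm = self._cm(counts)
        out = exclude_sparse_overlap_samples(cm)
        assert "s3" not in out.samples and len(out.samples) == 13
        again = exclude_sparse_overlap_samples(out)
        assert list(again.samples) == list(out.samples)

    def test_sample_with_nine_shared_taxa_removed(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=(13, 12))
        counts[5, :] = 0
        counts[5, :9] = 7  # shares exactly 9 taxa with the rest
        out = exclude_sparse_overlap_samples(self._cm(counts))
        assert "s5" not in out.samples

    def test_too_few_survivors_rejected(self):
        counts = np.zeros((12, 12), dtype=int)
        counts[:, 0] = 1
        with pytest.raises(ValueError, match="too few"):
            exclude_sparse_overlap_samples(self._cm(counts))


class TestZinbMargins:
    def test_nb_data_fits_near_zero_inflation(self):
        rng = np.random.default_rng(2)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + 30.0), size=500)
        fit = fit_zinb_regression(y)
        assert fit.pi < 0.05
        assert fit.mu == pytest.approx(30.0, rel=0.15)

    def test_covariate_coefficient_recovery(self):
        """True log-mean effect 0.5 recovered within +/-0.15 at n=500."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        mu = 20.0 * np.exp(0.5 * x)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        y[rng.random(500) < 0.15] = 0
        fit = fit_zinb_regression(y, x.reshape(-1, 1))
        assert fit.beta[1] == pytest.approx(0.5, abs=0.15)

    def test_statsmodels_oracle_agreement(self):
        """Our ZINB MLE matches statsmodels' ZeroInflatedNegativeBinomialP."""
        import statsmodels.api as sm
        from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

        rng = np.random.default_rng(4)
        mu, theta, pi = 25.0, 2.0, 0.2
        y = rng.negative_binomial(theta, theta / (theta + mu), size=800)
        y[rng.random(800) < pi] = 0
        ours = fit_zinb_regression(y)
        smf = ZeroInflatedNegativeBinomialP(y, np.ones((800, 1)), p=2).fit(disp=0)
        mu_sm = float(np.exp(smf.params[1]))
        pi_sm = float(1 / (1 + np.exp(-smf.params[0])))
        assert ours.mu == pytest.approx(mu_sm, rel=0.02)
        assert ours.pi == pytest.approx(pi_sm, abs=0.02)

    def test_scores_pass_normality_sanity(self, small_cohort):
        cm, _ = small_cohort
        _, Z = fit_copula_margins(cm)
        skew = np.abs(stats.skew(Z.values, axis=0))
        assert np.median(skew) < 0.5

    def test_copula_rank_invariance_under_count_rescaling(self, small_cohort):
        """Doubling all counts (a strictly increasing transform) leaves the
        rank structure of the scores essentially unchanged."""
        cm, _ = small_cohort
        _, Z1 = fit_copula_margins(cm)
        doubled = CountMatrix(cm.counts * 2, cm.taxonomy, cm.metadata)
        _, Z2 = fit_copula_margins(doubled)
        rhos = [stats.spearmanr(Z1.values[:, t], Z2.values[:, t]).statistic
                for t in range(Z1.shape[1])]
        assert np.median(rhos) > 0.99

    def test_gmpr_recovers_true_depth_ratios(self):
        rng = np.random.default_rng(5)
        base = rng.integers(20, 200, size=(1, 40))
        factors = np.array([1.0, 2.0, 0.5, 4.0])
        counts = (base * factors[:, None]).astype(int)
        sf = gmpr_size_factors(counts)
        np.testing.assert_allclose(sf / sf[0], factors / factors[0], rtol=0.05)


class TestStars:
    def test_large_rho_gives_empty_support(self, rng):
        Z = rng.normal(size=(60, 8))
        net = stars_glasso(Z, rho_grid=np.array([2.0, 1.5]), seed=0)
        assert net.support.values.sum() == 0
        assert net.rho_path["instability"].iloc[0] == 0.0

    def test_independent_data_selects_empty_support(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(400, 15))
        net = stars_glasso(Z, seed=1)
        assert net.support.values.sum() == 0

    def test_weights_are_signed_partial_correlations(self):
        rng = np.random.default_rng(7)
        cov = np.eye(3)
        cov[0, 1] = cov[1, 0] = 0.6
        Z = rng.multivariate_normal(np.zeros(3), cov, size=600)
        net = stars_glasso(Z, seed=2)
        assert net.weights.values[0, 1] > 0.3  # positive partial correlation
        np.testing.assert_allclose(net.weights.values, net.weights.values.T)
        assert (np.diag(net.weights.values) == 0).all()

    def test_instability_vanishes_at_max_penalty(self, rng):
        Z = rng.normal(size=(80, 10))
        net = stars_glasso(Z, seed=3)
        assert net.rho_path["instability"].iloc[0] <= 0.01

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match=">= 20"):
            stars_glasso(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="decreasing"):
            stars_glasso(rng.normal(size=(50, 4)), rho_grid=np.array([0.1, 0.2]))


class TestFamilyConnectivity:
    def test_between_and_within_family_arithmetic(self):
        W = np.zeros((3, 3))
        W[0, 2] = W[2, 0] = 0.2     # a1-b1
        W[1, 2] = W[2, 1] = -0.1    # a2-b1
        net = _net_from_weights(W, ["a1", "a2", "b1"])
        tax = pd.DataFrame({"family": ["A", "A", "B"], "genus": ["g"] * 3},
                           index=["a1", "a2", "b1"])
        fc = family_connectivity(net, tax)
        assert fc.connectivity.loc["A", "B"] == pytest.approx(0.05)
        assert fc.connectivity.loc["B", "A"] == pytest.approx(0.05)

    def test_within_family_single_pair(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = -0.4
        net = _net_from_weights(W, ["a1", "a2"])
        tax = pd.DataFrame({"family": ["A", "A"], "genus": ["g"] * 2},
                           index=["a1", "a2"])
        fc = family_connectivity(net, tax)
        assert fc.connectivity.loc["A", "A"] == pytest.approx(-0.4)

    def test_empty_network_gives_zero_connectivity(self):
        net = _net_from_weights(np.zeros((2, 2)), ["a1", "b1"])
        tax = pd.DataFrame({"family": ["A", "B"], "genus": ["g"] * 2},
                           index=["a1", "b1"])
        fc = family_connectivity(net, tax)
        assert (fc.connectivity.values == 0).all()


class TestNetworkSummaries:
    def test_single_edge_strengths(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = -0.3
        m = network_summary_metrics(_net_from_weights(W))
        assert m["average_node_strength"] == pytest.approx(0.3)

    def test_star_graph_average_strength(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        m = network_summary_metrics(_net_from_weights(W))
        assert m["average_node_strength"] == pytest.approx((4 + 1 + 1 + 1 + 1) / 5)
        assert m["eigenvector_centrality"].iloc[0] == pytest.approx(1.0)

    def test_complete_graph_equal_centrality(self):
        W = np.ones((4, 4)) - np.eye(4)
        m = network_summary_metrics(_net_from_weights(W))
        np.testing.assert_allclose(m["eigenvector_centrality"].values, 1.0)

    def test_empty_network_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            m = network_summary_metrics(_net_from_weights(np.zeros((3, 3))))
        assert m["average_eigenvector_centrality"] == 0.0


def test_oracle_support_agreement_on_gaussian_data():
    """With pi = 0 and no covariates the pipeline's support at rho* matches
    graphical lasso run directly on the latent correlation (Jaccard >= 0.9)."""
    cfg = planted_config(n_taxa=15, n_per_group=250, seed=11,
                         groups=("g",))
    cfg.planted_edges = []
    cfg.precision_base = np.eye(15)
    for i, j in [(0, 1), (2, 3), (4, 5)]:
        cfg.precision_base[i, j] = cfg.precision_base[j, i] = -0.45
    cfg.pi = np.zeros(15)
    cfg.check()
    cm, gt = generate_cohort(cfg)
    _, Z = fit_copula_margins(cm)
    net = stars_glasso(Z, seed=4)

    from isnkit.popnet import _glasso_precision, _support
    lat_corr = np.corrcoef(gt.latent.values, rowvar=False)
    oracle = _support(_glasso_precision(lat_corr, net.rho_star))
    ours = net.support.values
    iu = np.triu_indices(15, k=1)
    inter = np.sum(oracle[iu] & ours[iu])
    union = np.sum(oracle[iu] | ours[iu])
    assert union == 0 or inter / union >= 0.9
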
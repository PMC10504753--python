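"""Correlation input, graphical lasso, EBIC selection, covariate adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symptomnet._glasso import gaussian_loglik, glasso, kkt_violation
from symptomnet.cohort import (
    NETWORK_NODES,
    STRONG_EDGES,
    SyntheticSpec,
    default_spec,
    default_true_partial,
    generate_cohort,
    node_to_column,
    partial_to_latent_correlation,
)
from symptomnet.ggm import (
    EstimatorConfig,
    GGMNetwork,
    adjust_for_covariates,
    compare_networks,
    correlation_matrix,
    default_communities,
    ebic,
    estimate_network,
    polychoric_correlation,
    precision_to_partial,
    select_network,
)
from tests.conftest import draw_ordinal_pair

ITEM_COLS = [node_to_column(nd) for nd in NETWORK_NODES]


class TestCorrelationMatrix:
    def test_duplicated_column_has_unit_correlation(self):
        x = np.random.default_rng(0).integers(0, 4, size=200)
        R = correlation_matrix(np.column_stack([x, x, x % 2]), method="spearman")
        assert R[0, 1] == pytest.approx(1.0)

    def test_anti_monotone_recode_flips_spearman_sign(self, planted_items_2000):
        X = planted_items_2000[ITEM_COLS].to_numpy()
        R = correlation_matrix(X, method="spearman")
        Y = X.copy()
        Y[:, 0] = 3 - Y[:, 0]
        R2 = correlation_matrix(Y, method="spearman")
        assert np.allclose(R2[0, 1:], -R[0, 1:], atol=1e-12)

    def test_constant_column_error_names_item(self):
        df = pd.DataFrame({"A": [1, 2, 3], "B": [2, 2, 2]})
        with pytest.raises(ValueError, match="B"):
            correlation_matrix(df)

    def test_fast_ordinal_ranks_match_scipy(self, planted_items_2000):
        X = planted_items_2000[ITEM_COLS].to_numpy()
        ours = correlation_matrix(X, method="spearman")
        ref = stats.spearmanr(X).statistic
        assert np.allclose(ours, ref, atol=1e-12)

    def test_polychoric_recovers_latent_correlation(self):
        XY = draw_ordinal_pair(0.5, [-0.5, 0.5, 1.3], n=50_000, seed=6)
        est = polychoric_correlation(XY[:, 0], XY[:, 1])
        assert est == pytest.approx(0.5, abs=0.02)
        # Spearman on the same data is attenuated below the latent value
        r_sp = stats.spearmanr(XY[:, 0], XY[:, 1]).statistic
        assert r_sp < est


class TestGlasso:
    def test_identity_input_gives_identity_precision(self):
        Theta, *_ = glasso(np.eye(6), 0.1)
        assert np.allclose(Theta, np.eye(6))

    def test_penalty_above_max_correlation_empties_network(self):
        S = np.array([[1, 0.5, 0.3], [0.5, 1, 0.2], [0.3, 0.2, 1.0]])
        Theta, *_ = glasso(S, 0.51)
        off = Theta[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.0)

    def test_unpenalized_matches_matrix_inverse_oracle(self):
        S = np.array([[1, 0.5, 0.3], [0.5, 1, 0.2], [0.3, 0.2, 1.0]])
        Theta, *_ = glasso(S, 0.0, tol=1e-9, max_iter=5000)
        assert np.allclose(Theta, np.linalg.inv(S), atol=1e-6)

    def test_matches_sklearn_at_positive_penalty(self):
        from sklearn.covariance import graphical_lasso as sk_glasso

        rng = np.random.default_rng(8)
        X = rng.standard_normal((500, 8))
        X[:, 1] += 0.6 * X[:, 0]
        X[:, 4] += 0.5 * X[:, 2]
        S = np.corrcoef(X, rowvar=False)
        Theta, *_ = glasso(S, 0.08, tol=1e-7)
        _, prec = sk_glasso(S, alpha=0.08, tol=1e-8, max_iter=500)
        assert np.abs(Theta - prec).max() < 1e-4

    def test_kkt_conditions_hold_along_path(self, planted_items_2000):
        S = correlation_matrix(planted_items_2000[ITEM_COLS])
        for lam in (0.3, 0.1, 0.03):
            Theta, *_ = glasso(S, lam, tol=1e-7)
            assert kkt_violation(S, Theta, lam) < 1e-5

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso(np.eye(3), -0.1)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-50.0, 7, 200, 16, 0.0) == pytest.approx(100 + 7 * np.log(200))

    def test_arithmetic_example(self):
        expected = 200 + 5 * np.log(100) + 10 * np.log(16)
        assert ebic(-100.0, 5, 100, 16, 0.5) == pytest.approx(expected)

    def test_no_edges_is_twice_negative_loglik(self):
        assert ebic(-33.0, 0, 50, 4, 0.5) == pytest.approx(66.0)


class TestPrecisionToPartial:
    def test_diagonal_precision_gives_no_edges(self):
        assert np.allclose(precision_to_partial(np.diag([1.0, 2.0, 3.0])), 0.0)

    def test_bivariate_identity(self):
        r = 0.37
        Theta = np.linalg.inv(np.array([[1, r], [r, 1]]))
        W = precision_to_partial(Theta)
        assert W[0, 1] == pytest.approx(r, rel=1e-12)

    def test_matches_residualization_oracle(self):
        # partial corr of (i, j) = corr of residuals after regressing both
        # on the remaining variables; computed via Schur complement
        rng = np.random.default_rng(10)
        A = rng.standard_normal((4, 4))
        Sigma = A @ A.T + 4 * np.eye(4)
        Theta = np.linalg.inv(Sigma)
        W = precision_to_partial(Theta)
        for i, j in [(0, 1), (0, 3), (2, 3)]:
            rest = [k for k in range(4) if k not in (i, j)]
            Sij = Sigma[np.ix_([i, j], [i, j])]
            Sir = Sigma[np.ix_([i, j], rest)]
            Srr = Sigma[np.ix_(rest, rest)]
            C = Sij - Sir @ np.linalg.solve(Srr, Sir.T)
            oracle = C[0, 1] / np.sqrt(C[0, 0] * C[1, 1])
            assert W[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            precision_to_partial(np.array([[1.0, 0.0], [0.0, -2.0]]))


class TestSelectNetwork:
    def test_single_lambda_grid_selects_it(self, planted_items_2000, fast_config):
        S = correlation_matrix(planted_items_2000[ITEM_COLS])
        net = select_network(S, 2000, config=fast_config, lambda_grid=np.array([0.123]))
        assert net.lambda_selected == pytest.approx(0.123)

    def test_edge_count_monotone_along_path(self, planted_items_2000, fast_config):
        S = correlation_matrix(planted_items_2000[ITEM_COLS])
        net = select_network(S, 2000, config=fast_config)
        counts = net.metadata["path_edge_counts"]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_empty_network_rarely_gains_spurious_edges(self, fast_config):
        hits = 0
        for seed in range(50):
            spec = SyntheticSpec(
                n_participants=2000,
                true_partial=np.zeros((16, 16)),
                include_ctq=False,
                female_latent_shift=0.0,
                seed=seed,
            )
            net = estimate_network(generate_cohort(spec), fast_config)
            if net.edge_count() <= 1:
                hits += 1
        assert hits >= 45

    def test_planted_strong_edges_recovered(self, planted_items_2000, fast_config):
        net = estimate_network(planted_items_2000, fast_config)
        for a, b in STRONG_EDGES:
            i, j = NETWORK_NODES.index(a), NETWORK_NODES.index(b)
            assert net.weights[i, j] > 0

    def test_oracle_equivalence_small_graph_unpenalized(self):
        # p=4, lambda=0: selection pipeline must equal direct inversion
        R = partial_to_latent_correlation(
            np.array(
                [
                    [0, 0.3, 0, 0],
                    [0.3, 0, 0.2, 0],
                    [0, 0.2, 0, 0.25],
                    [0, 0, 0.25, 0],
                ]
            )
        )
        net = select_network(R, 1000, lambda_grid=np.array([0.0]))
        Theta = np.linalg.inv(R)
        s = 1 / np.sqrt(np.diag(Theta))
        expect = -Theta * np.outer(s, s)
        np.fill_diagonal(expect, 0.0)
        assert np.abs(net.weights - expect).max() < 1e-6


class TestAdjustment:
    def test_orthogonal_covariates_leave_network_unchanged(self):
        # Pearson input: residualizing on noise covariates perturbs each
        # item only at O(k/n).  (Spearman would not be invariant here: the
        # regression breaks the ordinal ties, which re-scales rank
        # correlations regardless of the covariates' relevance.)
        cfg = EstimatorConfig(method="pearson", n_lambda=20)
        spec = default_spec(5000, seed=21, include_ctq=False, female_latent_shift=0.0)
        df = generate_cohort(spec)
        items = df[ITEM_COLS]
        covs = df[["family_type", "income_band"]]  # independent of symptoms
        net = estimate_network(items, cfg, nodes=NETWORK_NODES)
        adj = estimate_network(
            adjust_for_covariates(items, covs), cfg, nodes=NETWORK_NODES
        )
        assert np.abs(net.weights - adj.weights).max() < 0.02

    def test_item_equal_to_covariate_becomes_constant(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"x": rng.integers(0, 2, 100).astype(float)})
        items = pd.DataFrame({"A": cov["x"], "B": rng.normal(size=100)})
        resid = adjust_for_covariates(items, cov)
        assert np.abs(resid["A"]).max() < 1e-10
        with pytest.raises(ValueError, match="A"):
            correlation_matrix(resid)

    def test_aliased_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        cov = pd.DataFrame(
            {"x": rng.normal(size=50), "y": np.arange(50.0)}
        )
        cov["z"] = cov["x"] + cov["y"]  # aliased
        items = pd.DataFrame({"A": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="aliased"):
            adjust_for_covariates(items, cov)

    def test_sex_mean_shift_adjustment_improves_recovery(self, fast_config):
        # a mean-only sex difference inflates marginal associations;
        # residualizing on sex should recover the pooled structure better
        P = default_true_partial()
        iu = np.triu_indices(16, 1)
        wins = 0
        for seed in range(20):
            df = generate_cohort(
                default_spec(2000, seed=seed, include_ctq=False, female_latent_shift=0.6)
            )
            items = df[ITEM_COLS]
            raw = estimate_network(items, fast_config, nodes=NETWORK_NODES)
            adj = estimate_network(
                adjust_for_covariates(items, df[["sex"]]),
                fast_config,
                nodes=NETWORK_NODES,
            )
            r_raw = stats.spearmanr(P[iu], raw.weights[iu]).statistic
            r_adj = stats.spearmanr(P[iu], adj.weights[iu]).statistic
            wins += r_adj >= r_raw
        assert wins >= 14


class TestCompareNetworks:
    def _net(self, weights):
        return GGMNetwork(
            nodes=NETWORK_NODES,
            weights=weights,
            communities=default_communities(),
        )

    def test_self_comparison(self, planted_items_2000, fast_config):
        net = estimate_network(planted_items_2000, fast_config)
        cmp = compare_networks(net, net)
        assert cmp.spearman_r == pytest.approx(1.0)
        assert cmp.t == pytest.approx(0.0)

    def test_rank_reversal_gives_minus_one(self):
        iu = np.triu_indices(16, 1)
        w = np.linspace(0.01, 0.3, iu[0].size)
        A = np.zeros((16, 16))
        A[iu] = w
        B = np.zeros((16, 16))
        B[iu] = w[::-1].copy()
        cmp = compare_networks(self._net(A + A.T), self._net(B + B.T))
        assert cmp.spearman_r == pytest.approx(-1.0)

    def test_noise_comparison_matches_direct_rank_oracle(self):
        rng = np.random.default_rng(3)
        iu = np.triu_indices(16, 1)
        w = rng.uniform(-0.2, 0.3, iu[0].size)
        v = w + rng.normal(0, 0.05, w.size)
        A = np.zeros((16, 16))
        A[iu] = w
        B = np.zeros((16, 16))
        B[iu] = v
        cmp = compare_networks(self._net(A + A.T), self._net(B + B.T))
        assert cmp.spearman_r == pytest.approx(
            stats.spearmanr(w, v).statistic, abs=1e-12
        )

    def test_mismatched_nodes_rejected(self):
        a = self._net(np.zeros((16, 16)))
        b = GGMNetwork(
            nodes=tuple(str(i) for i in range(16)),
            weights=np.zeros((16, 16)),
            communities={str(i): "all" for i in range(16)},
        )
        with pytest.raises(ValueError):
            compare_networks(a, b)


def test_network_json_round_trip(planted_items_2000, fast_config, tmp_path):
    net = estimate_network(planted_items_2000, fast_config)
    path = tmp_path / "net.json"
    net.to_json(path)
    back = GGMNetwork.from_json(path)
    assert back.nodes == net.nodes
    assert np.allclose(back.weights, net.weights)
    assert back.lambda_selected == net.lambda_selected
    assert back.communities == net.communities
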
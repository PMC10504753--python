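"""Holm adjustment, edge differences, permutation comparison test."""

import numpy as np
import pytest

from symptomnet.cohort import (
    NETWORK_NODES,
    default_spec,
    generate_cohort,
    node_to_column,
)
from symptomnet.ggm import EstimatorConfig, GGMNetwork, default_communities
from symptomnet.nct import (
    edge_difference_table,
    holm_adjust,
    network_comparison_test,
)

ITEM_COLS = [node_to_column(nd) for nd in NETWORK_NODES]


class TestHolm:
    def test_hand_executed_step_down(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones_unchanged(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_adjusted_never_below_raw_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= 0)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        ours = holm_adjust(p)
        theirs = sm.multipletests(p, method="holm")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


def _net(weights):
    return GGMNetwork(
        nodes=NETWORK_NODES, weights=weights, communities=default_communities()
    )


class TestEdgeDifferences:
    def test_identical_networks_all_zero(self):
        a = _net(np.zeros((16, 16)))
        table = edge_difference_table(a, a)
        assert (table["diff"] == 0).all()
        assert (table["stronger"] == "equal").all()

    def test_swap_flips_all_signs(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(-0.2, 0.2, (16, 16))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        a, b = _net(W), _net(np.zeros((16, 16)))
        fwd = edge_difference_table(a, b)["diff"].to_numpy()
        rev = edge_difference_table(b, a)["diff"].to_numpy()
        assert np.allclose(fwd, -rev)

    def test_single_differing_edge(self):
        from symptomnet.cohort import set_edge

        W = set_edge(np.zeros((16, 16)), NETWORK_NODES, "PHQ6", "PHQ9", 0.1)
        table = edge_difference_table(_net(W), _net(np.zeros((16, 16))))
        nz = table[table["diff"] != 0]
        assert len(nz) == 1
        assert nz.iloc[0]["diff"] == pytest.approx(0.1)
        assert {nz.iloc[0]["node_i"], nz.iloc[0]["node_j"]} == {"PHQ6", "PHQ9"}


CFG = EstimatorConfig(n_lambda=10)


class TestNetworkComparisonTest:
    def test_identical_groups_give_null_result(self, planted_items_2000):
        items = planted_items_2000[ITEM_COLS].iloc[:400]
        res = network_comparison_test(items, items.copy(), permutations=40, seed=1, config=CFG)
        assert res.strength_diff_observed == pytest.approx(0.0)
        assert res.M_observed == pytest.approx(0.0)
        assert res.strength_p == pytest.approx(1.0)
        assert res.M_p == pytest.approx(1.0)
        assert np.all(res.edge_p_raw == 1.0)

    def test_fixed_seed_is_deterministic(self, planted_items_2000):
        items = planted_items_2000[ITEM_COLS]
        g1, g2 = items.iloc[:300], items.iloc[300:600]
        a = network_comparison_test(g1, g2, permutations=50, seed=9, config=CFG)
        b = network_comparison_test(g1, g2, permutations=50, seed=9, config=CFG)
        assert a.strength_p == b.strength_p and a.M_p == b.M_p
        assert np.array_equal(a.edge_p_raw, b.edge_p_raw)

    def test_group_relabel_symmetry(self, planted_items_2000):
        items = planted_items_2000[ITEM_COLS]
        g1, g2 = items.iloc[:300], items.iloc[300:600]
        a = network_comparison_test(g1, g2, permutations=50, seed=9, config=CFG)
        b = network_comparison_test(g2, g1, permutations=50, seed=9, config=CFG)
        assert a.strength_p == b.strength_p
        assert a.M_p == b.M_p
        assert np.allclose(
            a.edge_diffs["diff"].to_numpy(), -b.edge_diffs["diff"].to_numpy()
        )

    def test_holm_p_dominates_raw(self, planted_items_2000):
        items = planted_items_2000[ITEM_COLS]
        res = network_comparison_test(
            items.iloc[:300], items.iloc[300:600], permutations=50, seed=3, config=CFG
        )
        assert np.all(res.edge_p_holm >= res.edge_p_raw)
        assert np.all((res.edge_p_raw > 0) & (res.edge_p_raw <= 1))

    def test_too_few_permutations_rejected(self, planted_items_2000):
        items = planted_items_2000[ITEM_COLS]
        with pytest.raises(ValueError, match="permutation"):
            network_comparison_test(
                items.iloc[:100], items.iloc[100:200], permutations=10, seed=0
            )

    def test_small_group_rejected(self, planted_items_2000):
        items = planted_items_2000[ITEM_COLS]
        with pytest.raises(ValueError, match="at least"):
            network_comparison_test(
                items.iloc[:30], items.iloc[100:200], permutations=50, seed=0
            )

    def test_planted_difference_detected(self):
        # one edge differs by 0.25 between strata; it should carry the
        # largest observed difference and a small Holm p
        from symptomnet.cohort import default_true_partial, set_edge

        male = default_true_partial()
        female = set_edge(male, NETWORK_NODES, "GAD2", "PHQ4", 0.25)
        hits = 0
        for seed in (17, 18, 19, 20, 21):
            spec = default_spec(
                2000,
                seed=seed,
                include_ctq=False,
                sex_effect=female,
                female_latent_shift=0.0,
            )
            df = generate_cohort(spec)
            g1 = df[df.sex == "male"][ITEM_COLS]
            g2 = df[df.sex == "female"][ITEM_COLS]
            res = network_comparison_test(g2, g1, permutations=100, seed=seed, config=CFG)
            diffs = res.edge_diffs
            k = diffs[(diffs.node_i == "GAD2") & (diffs.node_j == "PHQ4")].index[0]
            if (
                diffs.loc[k, "diff"] > 0
                and res.edge_p_raw[k] == res.edge_p_raw.min()
                and res.edge_p_holm[k] == res.edge_p_holm.min()
            ):
                hits += 1
        assert hits >= 4
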
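"""Synthetic cohort generator: latent-copula correctness and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtri

from symptomnet.cohort import (
    NETWORK_NODES,
    SyntheticSpec,
    default_spec,
    default_thresholds,
    default_true_partial,
    generate_cohort,
    inject_missing,
    node_to_column,
    partial_to_latent_correlation,
    set_edge,
    thresholds_from_mean,
)
from symptomnet.scales import ctq_sf


class TestPartialToLatent:
    def test_zero_partials_give_identity(self):
        assert np.allclose(partial_to_latent_correlation(np.zeros((4, 4))), np.eye(4))

    def test_isolated_edge_partial_equals_marginal(self):
        # with no other paths, the partial correlation is the marginal one
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = 0.3
        R = partial_to_latent_correlation(P)
        assert R[0, 1] == pytest.approx(0.3, abs=1e-12)
        assert R[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert R[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_chain_matches_precision_inversion_oracle(self):
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = 0.3
        P[1, 2] = P[2, 1] = 0.3
        R = partial_to_latent_correlation(P)
        # independent oracle: invert the standardized precision matrix
        K = np.array([[1, -0.3, 0], [-0.3, 1, -0.3], [0, -0.3, 1]], dtype=float)
        Sigma = np.linalg.inv(K)
        d = 1 / np.sqrt(np.diag(Sigma))
        assert np.allclose(R, Sigma * np.outer(d, d), atol=1e-12)
        assert np.all(np.linalg.eigvalsh(R) > 0)

    def test_round_trip_recovers_partials(self):
        P = default_true_partial()
        R = partial_to_latent_correlation(P)
        Theta = np.linalg.inv(R)
        s = 1 / np.sqrt(np.diag(Theta))
        back = -Theta * np.outer(s, s)
        np.fill_diagonal(back, 0.0)
        assert np.allclose(back, P, atol=1e-10)

    def test_non_positive_definite_rejected_with_eigenvalue(self):
        P = np.zeros((3, 3))
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            P[i, j] = P[j, i] = 0.9
        with pytest.raises(ValueError, match="eigenvalue"):
            partial_to_latent_correlation(P)

    @pytest.mark.parametrize(
        "bad",
        [np.full((3, 3), 0.2), np.eye(3) * 0.5, np.zeros((2, 3))],
        ids=["nonzero-diagonal", "diagonal-only", "not-square"],
    )
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            partial_to_latent_correlation(bad)


class TestThresholds:
    def test_thresholds_strictly_increasing_and_mean_correct(self):
        for m in (0.29, 0.86, 1.5, 2.5):
            t = thresholds_from_mean(m, 4)
            assert np.all(np.diff(t) > 0)
            probs = np.diff(np.concatenate(([0], stats.norm.cdf(t), [1])))
            assert (probs * np.arange(4)).sum() == pytest.approx(m, abs=1e-6)

    def test_out_of_range_mean_rejected(self):
        with pytest.raises(ValueError):
            thresholds_from_mean(3.5, 4)


class TestGenerateCohort:
    def test_same_seed_identical_tables(self):
        a = generate_cohort(default_spec(500, seed=42))
        b = generate_cohort(default_spec(500, seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_column_convention_and_ranges(self, small_cohort):
        for i in range(1, 29):
            assert f"CTQ{i:02d}" in small_cohort.columns
        for nd in NETWORK_NODES:
            col = node_to_column(nd)
            assert small_cohort[col].between(0, 3).all()
        ctq_cols = [c for c in small_cohort.columns if c.startswith("CTQ")]
        assert small_cohort[ctq_cols].stack().between(1, 5).all()
        assert not small_cohort.isna().any().any()

    def test_quartile_thresholds_give_quarter_proportions(self):
        thresholds = default_thresholds()
        thresholds["GAD1"] = ndtri([0.25, 0.5, 0.75])
        spec = SyntheticSpec(
            n_participants=50_000,
            thresholds=thresholds,
            include_ctq=False,
            female_latent_shift=0.0,
            seed=7,
        )
        counts = generate_cohort(spec)["GAD01"].value_counts(normalize=True)
        # normal-CDF oracle: quartile cut-points give equal mass
        for k in range(4):
            assert counts[k] == pytest.approx(0.25, abs=0.02)

    def test_independence_under_empty_network(self):
        spec = SyntheticSpec(
            n_participants=50_000,
            true_partial=np.zeros((16, 16)),
            include_ctq=False,
            female_latent_shift=0.0,
            seed=5,
        )
        items = generate_cohort(spec)[[node_to_column(nd) for nd in NETWORK_NODES]]
        rho = stats.spearmanr(items).statistic
        off = rho[~np.eye(16, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_discretization_attenuates_latent_correlation(self):
        # planted latent r=0.5 on an isolated pair; 4-category Spearman
        # must land strictly between 0 and 0.5
        P = set_edge(np.zeros((16, 16)), NETWORK_NODES, "GAD1", "GAD2", 0.5)
        spec = SyntheticSpec(
            n_participants=20_000,
            true_partial=P,
            include_ctq=False,
            female_latent_shift=0.0,
            seed=9,
        )
        df = generate_cohort(spec)
        r = stats.spearmanr(df["GAD01"], df["GAD02"]).statistic
        assert 0.0 < r < 0.5

    def test_sa_severity_monotonically_raises_flag_rate(self):
        sa_items = list(ctq_sf().subscales["sexual_abuse"])
        rates = []
        for target in (0.02, 0.036, 0.08):
            spec = default_spec(20_000, seed=13)
            spec.ctq_marginals = dict(spec.ctq_marginals, sexual_abuse=target)
            df = generate_cohort(spec)
            rates.append((df[sa_items].sum(axis=1) >= 8).mean())
        assert rates[0] < rates[1] < rates[2]
        assert rates[1] == pytest.approx(0.036, abs=0.01)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            default_spec(1)

    def test_inject_missing_only_on_request(self, small_cohort):
        out = inject_missing(small_cohort, rate=0.1, seed=1)
        item_cols = [c for c in out.columns if c[:3] in {"CTQ", "GAD", "PHQ"}]
        frac = out[item_cols].isna().to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.01)
        assert not small_cohort[item_cols].isna().any().any()
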
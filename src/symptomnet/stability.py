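"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two procedures, following the standard bootstrap methodology for
psychological networks:

* non-parametric edge bootstrap — resample rows with replacement,
  re-estimate, report percentile CIs per edge plus bootstrapped difference
  tests between edge pairs and between node centralities;
* case-dropping bootstrap — re-estimate on subsamples with an increasing
  proportion of cases dropped, correlate subsample centrality with the
  full-sample ranking, and summarize with the correlation-stability (CS)
  coefficient: the largest drop proportion at which at least 95% of
  subsample correlations stay >= 0.7.

CS below 0.25 is labelled unstable, 0.25-0.5 acceptable, above 0.5 good —
interpretive thresholds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import EstimatorConfig, GGMNetwork, correlation_matrix, select_network
from .nct import _as_matrix

__all__ = [
    "EdgeBootstrap",
    "StabilityReport",
    "bootstrap_edges",
    "case_drop_cs",
    "cs_label",
    "stability_report",
]

DEFAULT_DROP_GRID = np.round(np.arange(0.05, 0.76, 0.05), 2)


def cs_label(cs: float) -> str:
    if cs < 0.25:
        return "unstable"
    if cs < 0.5:
        return "acceptable"
    return "good"


def _fit_upper(X, config, iu):
    S = correlation_matrix(X, method=config.method)
    return select_network(S, len(X), config=config).weights[iu]


@dataclass
class EdgeBootstrap:
    """Percentile edge CIs and bootstrapped difference tests."""

    nodes: tuple[str, ...]
    edge_stats: pd.DataFrame  # node_i, node_j, observed, boot_mean, ci_low, ci_high
    edge_diff_significant: np.ndarray  # (n_edges, n_edges) bool
    centrality_diff_significant: np.ndarray  # (p, p) bool, expected influence
    replicates: int
    failures: int
    seed: int


def bootstrap_edges(
    items,
    B: int = 1000,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    nodes: tuple[str, ...] | None = None,
    level: float = 0.95,
    max_failure_rate: float = 0.05,
) -> EdgeBootstrap:
    """Non-parametric row bootstrap of the network estimator.

    An edge pair (or node pair, for expected influence) differs
    significantly when the percentile CI of its bootstrapped difference
    excludes zero.  Failed replicates (estimator errors) are dropped and
    counted; more than ``max_failure_rate`` of them is an error.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates for CIs")
    from .cohort import NETWORK_NODES, node_to_column

    if nodes is None and isinstance(items, pd.DataFrame) and all(
        node_to_column(nd) in items.columns for nd in NETWORK_NODES
    ):
        nodes = NETWORK_NODES
    X = _as_matrix(items, nodes or ())
    n, p = X.shape
    if nodes is None:
        nodes = tuple(str(j) for j in range(p))
    iu = np.triu_indices(p, k=1)
    observed = _fit_upper(X, config, iu)

    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            draws.append(_fit_upper(X[idx], config, iu))
        except (ValueError, RuntimeError):
            failures += 1
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed (> {max_failure_rate:.0%})"
        )
    Wb = np.asarray(draws)  # (B_ok, n_edges)
    alpha = 1.0 - level
    lo, hi = np.quantile(Wb, [alpha / 2, 1 - alpha / 2], axis=0)
    edge_stats = pd.DataFrame(
        {
            "node_i": [nodes[i] for i in iu[0]],
            "node_j": [nodes[j] for j in iu[1]],
            "observed": observed,
            "boot_mean": Wb.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
    # pairwise difference tests over edges
    dlo, dhi = np.quantile(
        Wb[:, :, None] - Wb[:, None, :], [alpha / 2, 1 - alpha / 2], axis=0
    )
    edge_diff_sig = (dlo > 0) | (dhi < 0)
    np.fill_diagonal(edge_diff_sig, False)
    # expected influence per replicate: fold the upper weights back
    ei = np.zeros((Wb.shape[0], p))
    for k, (i, j) in enumerate(zip(*iu)):
        ei[:, i] += Wb[:, k]
        ei[:, j] += Wb[:, k]
    clo, chi = np.quantile(
        ei[:, :, None] - ei[:, None, :], [alpha / 2, 1 - alpha / 2], axis=0
    )
    cent_diff_sig = (clo > 0) | (chi < 0)
    np.fill_diagonal(cent_diff_sig, False)
    return EdgeBootstrap(
        nodes=nodes,
        edge_stats=edge_stats,
        edge_diff_significant=edge_diff_sig,
        centrality_diff_significant=cent_diff_sig,
        replicates=Wb.shape[0],
        failures=failures,
        seed=seed,
    )


def _rank_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.allclose(a, b):
        return 1.0
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(stats.spearmanr(a, b).statistic)


def _index_values(weights_upper: np.ndarray, p: int, iu, cross_mask, index: str):
    vals = np.zeros(p)
    if index == "bridge_expected_influence":
        w = weights_upper * cross_mask
    elif index == "expected_influence":
        w = weights_upper
    else:
        raise ValueError(f"unknown centrality index {index!r}")
    for k, (i, j) in enumerate(zip(*iu)):
        vals[i] += w[k]
        vals[j] += w[k]
    return vals


def case_drop_cs(
    items,
    index: str = "expected_influence",
    drop_grid: np.ndarray = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    nodes: tuple[str, ...] | None = None,
    communities: dict[str, str] | None = None,
    threshold: float = 0.7,
    coverage: float = 0.95,
) -> tuple[pd.DataFrame, float]:
    """Case-dropping bootstrap and CS-coefficient for a centrality index.

    For each drop proportion q, ``B`` subsamples of (1-q)n rows are drawn
    without replacement and the Spearman correlation between full-sample
    and subsample centrality is recorded.  CS is the largest q whose
    correlations stay >= ``threshold`` with probability >= ``coverage``
    (0 if none).  Grid points whose subsample would be smaller than p + 2
    are skipped.

    Returns (curve, cs) where ``curve`` has one row per evaluated q with
    the fraction of correlations above the threshold and the mean
    correlation.
    """
    drop_grid = np.asarray(drop_grid, dtype=np.float64)
    if np.any((drop_grid <= 0) | (drop_grid >= 0.9)):
        raise ValueError("drop proportions must lie in (0, 0.9)")
    if B < 50:
        raise ValueError("need at least 50 subsamples per grid point")
    from .cohort import NETWORK_NODES, node_to_column
    from .ggm import default_communities

    if nodes is None and isinstance(items, pd.DataFrame) and all(
        node_to_column(nd) in items.columns for nd in NETWORK_NODES
    ):
        nodes = NETWORK_NODES
    X = _as_matrix(items, nodes or ())
    n, p = X.shape
    if nodes is None:
        nodes = tuple(str(j) for j in range(p))
    if communities is None:
        try:
            communities = default_communities(nodes)
        except ValueError:
            communities = {nd: "all" for nd in nodes}
    iu = np.triu_indices(p, k=1)
    comm = np.asarray([communities[nd] for nd in nodes])
    cross_mask = (comm[iu[0]] != comm[iu[1]]).astype(np.float64)

    w_full = _fit_upper(X, config, iu)
    base = _index_values(w_full, p, iu, cross_mask, index)

    rng = np.random.default_rng(seed)
    rows = []
    for q in np.sort(drop_grid):
        m = int(round((1.0 - q) * n))
        if m < p + 2:
            import warnings

            warnings.warn(f"drop proportion {q} leaves {m} < p + 2 rows; skipped")
            continue
        corrs = np.empty(B)
        for b in range(B):
            idx = rng.choice(n, size=m, replace=False)
            w_sub = _fit_upper(X[idx], config, iu)
            corrs[b] = _rank_corr(base, _index_values(w_sub, p, iu, cross_mask, index))
        rows.append(
            {
                "drop": float(q),
                "n_subsample": m,
                "frac_above": float((corrs >= threshold).mean()),
                "mean_corr": float(corrs.mean()),
            }
        )
    curve = pd.DataFrame(rows)
    ok = curve[curve["frac_above"] >= coverage]
    cs = float(ok["drop"].max()) if len(ok) else 0.0
    return curve, cs


@dataclass
class StabilityReport:
    """Combined bootstrap accuracy and case-dropping stability report."""

    edge_bootstrap: EdgeBootstrap
    cs_curves: dict[str, pd.DataFrame]
    cs_coefficients: dict[str, float]
    seed: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "replicates": self.edge_bootstrap.replicates,
            "failures": self.edge_bootstrap.failures,
            "cs_coefficients": {
                k: {"cs": v, "label": cs_label(v)}
                for k, v in self.cs_coefficients.items()
            },
            "seed": self.seed,
        }


def stability_report(
    items,
    B_edges: int = 1000,
    B_drop: int = 1000,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    drop_grid: np.ndarray = DEFAULT_DROP_GRID,
    indices: tuple[str, ...] = ("expected_influence", "bridge_expected_influence"),
) -> StabilityReport:
    """Run both stability procedures with sub-seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed).spawn(1 + len(indices))
    eb = bootstrap_edges(
        items, B=B_edges, seed=int(ss[0].generate_state(1)[0] % 2**31), config=config
    )
    curves: dict[str, pd.DataFrame] = {}
    cs: dict[str, float] = {}
    for child, index in zip(ss[1:], indices):
        curve, c = case_drop_cs(
            items,
            index=index,
            drop_grid=drop_grid,
            B=B_drop,
            seed=int(child.generate_state(1)[0] % 2**31),
            config=config,
        )
        curves[index] = curve
        cs[index] = c
    return StabilityReport(
        edge_bootstrap=eb,
        cs_curves=curves,
        cs_coefficients=cs,
        seed=seed,
        metadata={"B_edges": B_edges, "B_drop": B_drop},
    )
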
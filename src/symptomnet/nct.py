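"""Permutation comparison of two group networks (network comparison test).

Group networks (e.g. male vs female) are each estimated with the shared
EBIC-glasso estimator; the null distribution of every statistic comes from
re-estimating both networks after randomly permuting group labels across
the pooled rows.  Three families of hypotheses:

* global strength invariance — statistic |sum|w1|| - sum|w2||,
* network structure invariance — M = max_ij |w1_ij - w2_ij|,
* per-edge differences — |w1_ij - w2_ij| per node pair, Holm-corrected
  across all pairs.

p-values use the add-one estimator (1 + #{perm >= obs}) / (1 + P), so they
are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NETWORK_NODES, node_to_column
from .ggm import EstimatorConfig, GGMNetwork, correlation_matrix, select_network

__all__ = [
    "NCTResult",
    "edge_difference_table",
    "holm_adjust",
    "network_comparison_test",
]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Sort ascending; adjusted p_(i) = max_{j <= i} min(1, (m - j + 1) p_(j)),
    mapped back to the input order.  Monotone: the raw ordering is
    preserved.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


def edge_difference_table(net_a: GGMNetwork, net_b: GGMNetwork) -> pd.DataFrame:
    """Signed per-edge weight difference, group a minus group b.

    The sign classifies each edge as stronger in group a (positive, the
    'green' edges of a male-minus-female comparison) or in group b
    (negative, 'red').
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks are defined over different node sets")
    iu = np.triu_indices(len(net_a.nodes), k=1)
    diff = (net_a.weights - net_b.weights)[iu]
    stronger = np.where(diff > 0, "group1", np.where(diff < 0, "group2", "equal"))
    return pd.DataFrame(
        {
            "node_i": [net_a.nodes[i] for i in iu[0]],
            "node_j": [net_a.nodes[j] for j in iu[1]],
            "diff": diff,
            "stronger": stronger,
        }
    )


@dataclass
class NCTResult:
    """Observed statistics and permutation p-values of one comparison."""

    nodes: tuple[str, ...]
    net1: GGMNetwork
    net2: GGMNetwork
    global_strength: tuple[float, float]
    strength_diff_observed: float
    strength_p: float
    M_observed: float
    M_p: float
    edge_diffs: pd.DataFrame  # signed, group1 - group2
    edge_p_raw: np.ndarray
    edge_p_holm: np.ndarray
    permutations: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "global_strength_group1": self.global_strength[0],
            "global_strength_group2": self.global_strength[1],
            "strength_diff_observed": self.strength_diff_observed,
            "strength_p": self.strength_p,
            "M_observed": self.M_observed,
            "M_p": self.M_p,
            "n_edges_tested": int(self.edge_p_raw.size),
            "n_edges_significant_holm": int((self.edge_p_holm < 0.05).sum()),
            "permutations": self.permutations,
            "seed": self.seed,
        }


def _as_matrix(items, nodes) -> np.ndarray:
    if isinstance(items, pd.DataFrame):
        cols = [node_to_column(nd) for nd in nodes] if nodes else []
        if cols and all(c in items.columns for c in cols):
            return items[cols].to_numpy(dtype=np.float64)
        return items.to_numpy(dtype=np.float64)
    return np.asarray(items, dtype=np.float64)


def _fit_upper(X: np.ndarray, config: EstimatorConfig, iu) -> tuple[np.ndarray, float]:
    S = correlation_matrix(X, method=config.method)
    net = select_network(S, len(X), config=config)
    w = net.weights[iu]
    return w, float(np.abs(w).sum())


def network_comparison_test(
    items_g1,
    items_g2,
    permutations: int = 1000,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    nodes: tuple[str, ...] | None = None,
    communities: dict[str, str] | None = None,
    min_group: int = 50,
) -> NCTResult:
    """Permutation test comparing the networks of two participant groups.

    Both observed and permuted networks are re-estimated with the full
    shared estimator (correlation + EBIC-glasso path).  Per-edge p-values
    are Holm-adjusted over all node pairs.  Deterministic under a fixed
    seed.
    """
    if permutations < 20:
        raise ValueError("need at least 20 permutations for usable p resolution")
    if nodes is None:
        nodes = NETWORK_NODES if (
            isinstance(items_g1, pd.DataFrame)
            and all(node_to_column(nd) in items_g1.columns for nd in NETWORK_NODES)
        ) else None
    X1 = _as_matrix(items_g1, nodes or ())
    X2 = _as_matrix(items_g2, nodes or ())
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("groups have different item columns")
    if len(X1) < min_group or len(X2) < min_group:
        raise ValueError(f"each group needs at least {min_group} rows")
    p = X1.shape[1]
    if nodes is None:
        nodes = tuple(str(j) for j in range(p))
    iu = np.triu_indices(p, k=1)

    from .ggm import default_communities

    if communities is None:
        try:
            communities = default_communities(nodes)
        except ValueError:
            communities = {nd: "all" for nd in nodes}

    w1, gs1 = _fit_upper(X1, config, iu)
    w2, gs2 = _fit_upper(X2, config, iu)
    obs_strength = abs(gs1 - gs2)
    obs_edge = np.abs(w1 - w2)
    obs_M = float(obs_edge.max())

    pooled = np.vstack([X1, X2])
    # canonical row order: the null distribution (and hence the p-values of
    # the symmetric statistics) is invariant to relabeling the two groups
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n1 = len(X1)
    rng = np.random.default_rng(seed)
    ge_strength = 0
    ge_M = 0
    ge_edge = np.zeros(iu[0].size, dtype=np.int64)
    for _ in range(permutations):
        perm = rng.permutation(len(pooled))
        pw1, pgs1 = _fit_upper(pooled[perm[:n1]], config, iu)
        pw2, pgs2 = _fit_upper(pooled[perm[n1:]], config, iu)
        d = np.abs(pw1 - pw2)
        if abs(pgs1 - pgs2) >= obs_strength:
            ge_strength += 1
        if d.max() >= obs_M:
            ge_M += 1
        ge_edge += d >= obs_edge
    denom = 1.0 + permutations
    edge_p_raw = (1.0 + ge_edge) / denom

    def mk_net(w):
        W = np.zeros((p, p))
        W[iu] = w
        return GGMNetwork(nodes=nodes, weights=W + W.T, communities=communities)

    net1, net2 = mk_net(w1), mk_net(w2)
    return NCTResult(
        nodes=nodes,
        net1=net1,
        net2=net2,
        global_strength=(gs1, gs2),
        strength_diff_observed=obs_strength,
        strength_p=(1.0 + ge_strength) / denom,
        M_observed=obs_M,
        M_p=(1.0 + ge_M) / denom,
        edge_diffs=edge_difference_table(net1, net2),
        edge_p_raw=edge_p_raw,
        edge_p_holm=holm_adjust(edge_p_raw),
        permutations=permutations,
        seed=seed,
        metadata={"estimator": config.__dict__.copy()},
    )
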
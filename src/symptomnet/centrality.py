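"""Node centrality: expected influence, bridge expected influence,
predictability.

Expected influence EI(i) is the signed sum of node i's incident edge
weights (one-step); bridge expected influence bEI(i) restricts the sum to
edges crossing to the other symptom community, so EI decomposes exactly
into bEI plus the within-community incident sum.  Predictability is the
share of a node's variance explained by all remaining nodes (nodewise
linear R^2).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import node_to_column
from .ggm import GGMNetwork

__all__ = [
    "bridge_expected_influence",
    "centrality_table",
    "expected_influence",
    "predictability",
]


def expected_influence(net: GGMNetwork) -> pd.Series:
    """One-step expected influence: EI(i) = sum_j w_ij."""
    return pd.Series(net.weights.sum(axis=1), index=list(net.nodes), name="EI")


def bridge_expected_influence(net: GGMNetwork) -> pd.Series:
    """Signed sum of each node's edges into the other community."""
    missing = [nd for nd in net.nodes if nd not in net.communities]
    if missing:
        raise ValueError(f"nodes without a community: {missing}")
    comm = np.asarray([net.communities[nd] for nd in net.nodes])
    cross = comm[:, None] != comm[None, :]
    return pd.Series(
        (net.weights * cross).sum(axis=1), index=list(net.nodes), name="bEI"
    )


def predictability(items: pd.DataFrame | np.ndarray, net: GGMNetwork) -> pd.Series:
    """Nodewise R^2: each item regressed on all remaining items.

    Requires n >= p + 2 rows.  A singular design falls back to a small
    ridge penalty with a warning.
    """
    if isinstance(items, pd.DataFrame):
        cols = [
            node_to_column(nd) if node_to_column(nd) in items.columns else nd
            for nd in net.nodes
        ]
        X = items[cols].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(items, dtype=np.float64)
    n, p = X.shape
    if p != len(net.nodes):
        raise ValueError("item columns do not match network nodes")
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} rows, got {n}")
    Xc = X - X.mean(axis=0)
    out = np.empty(p)
    for j in range(p):
        y = Xc[:, j]
        D = np.delete(Xc, j, axis=1)
        tss = float(y @ y)
        if tss == 0.0:
            out[j] = 0.0
            continue
        G = D.T @ D
        try:
            beta = np.linalg.solve(G, D.T @ y)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular design for node {net.nodes[j]}; using ridge fallback",
                stacklevel=2,
            )
            beta = np.linalg.solve(G + 1e-8 * np.trace(G) / p * np.eye(p - 1), D.T @ y)
        rss = float(np.sum((y - D @ beta) ** 2))
        out[j] = max(0.0, min(1.0, 1.0 - rss / tss))
    return pd.Series(out, index=list(net.nodes), name="predictability")


def centrality_table(
    net: GGMNetwork, items: pd.DataFrame | np.ndarray | None = None
) -> pd.DataFrame:
    """EI, bEI (raw and z-standardized) and, when data are given,
    predictability, indexed by node."""
    ei = expected_influence(net)
    bei = bridge_expected_influence(net)

    def z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=0)
        return (s - s.mean()) / sd if sd > 0 else s * 0.0

    table = pd.DataFrame(
        {"EI": ei, "zEI": z(ei), "bEI": bei, "zbEI": z(bei)}
    )
    if items is not None:
        table["predictability"] = predictability(items, net)
    return table
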
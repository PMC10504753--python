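"""Regularized partial-correlation network estimation (EBIC graphical lasso).

The estimation pipeline for one group of ordinal symptom items:

1. a correlation matrix (Spearman by default — robust for 4-category Likert
   items; Pearson and two-step ML polychoric available),
2. a graphical-lasso path over a log-spaced penalty grid, warm-started,
3. model selection by the Extended Bayesian Information Criterion
   EBIC = -2 logL + E log n + 4 gamma E log p, with the log-likelihood
   recomputed from the unpenalized Gaussian MLE restricted to each fit's
   sparsity pattern (penalized likelihoods bias model-size comparison),
4. conversion of the selected precision matrix to partial correlations
   w_ij = -Theta_ij / sqrt(Theta_ii Theta_jj).

Ties on the EBIC break toward the larger penalty (sparser model).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import ndtri
from scipy.stats import multivariate_normal

from ._glasso import constrained_mle, gaussian_loglik, glasso
from .cohort import ANXIETY_NODES, DEPRESSION_NODES, NETWORK_NODES, node_to_column

__all__ = [
    "EstimatorConfig",
    "GGMNetwork",
    "NetworkComparison",
    "adjust_for_covariates",
    "compare_networks",
    "correlation_matrix",
    "default_communities",
    "ebic",
    "estimate_network",
    "polychoric_correlation",
    "precision_to_partial",
    "select_network",
]


def default_communities(nodes=NETWORK_NODES) -> dict[str, str]:
    """Instrument membership: GAD items -> anxiety, PHQ items -> depression."""
    out = {}
    for nd in nodes:
        if nd in ANXIETY_NODES:
            out[nd] = "anxiety"
        elif nd in DEPRESSION_NODES:
            out[nd] = "depression"
        else:
            raise ValueError(f"no default community for node {nd!r}")
    return out


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings for one network estimation.

    ``n_lambda`` log-spaced penalties from lambda_max (largest absolute
    off-diagonal correlation) down to ``lambda_min_ratio * lambda_max``.
    ``refit=True`` scores EBIC on the pattern-constrained unpenalized MLE.
    """

    method: str = "spearman"  # spearman | pearson | polychoric
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    refit: bool = True
    tol: float = 1e-4
    max_iter: int = 1000

    def lambda_grid(self, lambda_max: float) -> np.ndarray:
        return np.geomspace(lambda_max, self.lambda_min_ratio * lambda_max, self.n_lambda)


class NetworkComparison(NamedTuple):
    """Agreement between two networks over their upper-triangle weights."""

    spearman_r: float
    spearman_p: float
    t: float
    t_p: float


@dataclass
class GGMNetwork:
    """A fitted Gaussian graphical model over symptom nodes.

    ``weights`` is the symmetric zero-diagonal partial-correlation matrix;
    ``communities`` maps each node to its symptom cluster.
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    communities: dict[str, str]
    lambda_selected: float = float("nan")
    gamma: float = float("nan")
    n: int = 0
    input_correlation: np.ndarray | None = None
    method: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=np.float64)
        p = len(self.nodes)
        if W.shape != (p, p):
            raise ValueError("weights shape does not match nodes")
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(W)) > 1e-10):
            raise ValueError("weights must have a zero diagonal")
        if np.any(np.abs(W) >= 1.0):
            raise ValueError("partial correlations must lie in (-1, 1)")
        self.weights = W

    # -- views -------------------------------------------------------------
    def upper_weights(self) -> np.ndarray:
        """Weights of the p(p-1)/2 unordered node pairs (row-major order)."""
        iu = np.triu_indices(len(self.nodes), k=1)
        return self.weights[iu]

    def edge_list(self, nonzero_only: bool = False) -> pd.DataFrame:
        iu = np.triu_indices(len(self.nodes), k=1)
        df = pd.DataFrame(
            {
                "node_i": [self.nodes[i] for i in iu[0]],
                "node_j": [self.nodes[j] for j in iu[1]],
                "weight": self.weights[iu],
            }
        )
        if nonzero_only:
            df = df[df["weight"] != 0.0].reset_index(drop=True)
        return df

    def edge_count(self) -> int:
        return int((np.abs(self.upper_weights()) > 1e-10).sum())

    def global_strength(self) -> float:
        return float(np.abs(self.upper_weights()).sum())

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": list(self.nodes),
            "weights": self.weights.tolist(),
            "communities": dict(self.communities),
            "lambda_selected": self.lambda_selected,
            "gamma": self.gamma,
            "n": self.n,
            "method": self.method,
            "input_correlation": None
            if self.input_correlation is None
            else self.input_correlation.tolist(),
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GGMNetwork":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            nodes=tuple(d["nodes"]),
            weights=np.asarray(d["weights"]),
            communities=d["communities"],
            lambda_selected=d["lambda_selected"],
            gamma=d["gamma"],
            n=d["n"],
            input_correlation=None
            if d.get("input_correlation") is None
            else np.asarray(d["input_correlation"]),
            method=d.get("method", ""),
            metadata=d.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# correlation input
# ---------------------------------------------------------------------------


def _ordinal_ranks(X: np.ndarray) -> np.ndarray:
    """Column-wise average ranks for small-integer data (fast path)."""
    n, p = X.shape
    out = np.empty((n, p))
    for j in range(p):
        col = X[:, j]
        vals, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        cum = np.concatenate(([0], np.cumsum(counts)))
        avg = (cum[:-1] + cum[1:] + 1) / 2.0  # average rank per category
        out[:, j] = avg[inv]
    return out


def correlation_matrix(
    items: np.ndarray | pd.DataFrame, method: str = "spearman"
) -> np.ndarray:
    """Symmetric unit-diagonal correlation matrix of the item columns.

    ``spearman`` ranks each column (ties get average ranks) and takes the
    Pearson correlation of the ranks; ``polychoric`` uses the two-step
    maximum-likelihood estimator for ordered categories.  A constant column
    is an error naming the offending item.
    """
    if isinstance(items, pd.DataFrame):
        names = list(items.columns)
        X = items.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(items, dtype=np.float64)
        names = [str(j) for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 item columns")
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    const = np.nonzero(np.ptp(X, axis=0) <= 1e-10 * scale)[0]
    if const.size:
        raise ValueError(f"constant item column: {names[const[0]]}")
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        if np.all(X == np.round(X)) and np.ptp(X) < 50:
            ranks = _ordinal_ranks(X.astype(np.int64))
        else:
            ranks = stats.rankdata(X, axis=0)
        R = np.corrcoef(ranks, rowvar=False)
    elif method == "polychoric":
        R = _polychoric_matrix(X.astype(np.int64), names)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R


def polychoric_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two ordinal vectors.

    Step 1: thresholds from the marginal category proportions via the
    inverse normal CDF.  Step 2: maximize the bivariate-normal likelihood
    of the contingency-table counts over the latent correlation.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    if xv.size < 2 or yv.size < 2:
        raise ValueError("both variables need at least 2 observed categories")
    counts = np.zeros((xv.size, yv.size))
    np.add.at(counts, (xi, yi), 1.0)
    n = x.size
    ax = ndtri(np.cumsum(counts.sum(axis=1))[:-1] / n)
    ay = ndtri(np.cumsum(counts.sum(axis=0))[:-1] / n)
    big = 8.0
    ax = np.concatenate(([-big], ax, [big]))
    ay = np.concatenate(([-big], ay, [big]))

    def neg_ll(rho: float) -> float:
        bvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        F = bvn.cdf(
            np.array(
                [[xa, yb] for xa in ax for yb in ay]
            )
        ).reshape(ax.size, ay.size)
        cell = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
        cell = np.clip(cell, 1e-12, None)
        return -float((counts * np.log(cell)).sum())

    res = minimize_scalar(neg_ll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def _polychoric_matrix(X: np.ndarray, names: list[str]) -> np.ndarray:
    p = X.shape[1]
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            R[i, j] = R[j, i] = polychoric_correlation(X[:, i], X[:, j])
    return R


def _ensure_psd(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale to a correlation matrix."""
    vals, vecs = np.linalg.eigh(R)
    if vals[0] > 0:
        return R
    vals = np.clip(vals, floor, None)
    R2 = (vecs * vals) @ vecs.T
    d = 1.0 / np.sqrt(np.diag(R2))
    R2 = R2 * np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def ebic(logL: float, E: int, n: int, p: int, gamma: float) -> float:
    """EBIC = -2 logL + E log n + 4 gamma E log p."""
    if E < 0 or n < 2 or p < 2:
        raise ValueError("need E >= 0, n >= 2, p >= 2")
    return -2.0 * logL + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def precision_to_partial(Theta: np.ndarray) -> np.ndarray:
    """Partial correlations -Theta_ij / sqrt(Theta_ii Theta_jj), zero diag."""
    Theta = np.asarray(Theta, dtype=np.float64)
    d = np.diag(Theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix has a non-positive diagonal entry")
    s = 1.0 / np.sqrt(d)
    W = -Theta * np.outer(s, s)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def select_network(
    S: np.ndarray,
    n: int,
    config: EstimatorConfig = EstimatorConfig(),
    nodes: tuple[str, ...] | None = None,
    communities: dict[str, str] | None = None,
    lambda_grid: np.ndarray | None = None,
) -> GGMNetwork:
    """Fit the glasso path on correlation matrix ``S`` and pick by EBIC.

    The path is warm-started from large to small penalties; the pattern-
    restricted log-likelihood is cached by sparsity pattern.  Ties break
    toward the larger penalty.
    """
    S = _ensure_psd(np.asarray(S, dtype=np.float64))
    p = S.shape[0]
    if nodes is None:
        nodes = tuple(str(i) for i in range(p))
    if communities is None:
        communities = {nd: "all" for nd in nodes}
    off = np.abs(S - np.diag(np.diag(S)))
    lambda_max = float(off.max())
    if lambda_grid is None:
        if lambda_max <= 0:  # independence: any penalty gives the empty graph
            lambda_grid = np.array([0.1])
        else:
            lambda_grid = config.lambda_grid(lambda_max)
    lambda_grid = np.asarray(lambda_grid, dtype=np.float64)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(np.diff(lambda_grid) > 0):
        raise ValueError("lambda grid must be non-increasing")

    best = None
    W = B = None
    loglik_cache: dict[bytes, float] = {}
    path = []
    for lam in lambda_grid:
        Theta, W, B = glasso(
            S, float(lam), W_init=W, B_init=B, tol=config.tol, max_iter=config.max_iter
        )
        adj = Theta != 0.0
        np.fill_diagonal(adj, False)
        E = int(adj.sum() // 2)
        if config.refit:
            key = np.packbits(adj).tobytes()
            if key not in loglik_cache:
                Theta_ref = constrained_mle(S, adj, tol=1e-8)
                loglik_cache[key] = gaussian_loglik(S, Theta_ref, n)
            logL = loglik_cache[key]
        else:
            logL = gaussian_loglik(S, Theta, n)
        score = ebic(logL, E, n, p, config.gamma)
        path.append((float(lam), E, score))
        if best is None or score < best[0]:
            best = (score, float(lam), Theta)
    score, lam_sel, Theta_sel = best
    return GGMNetwork(
        nodes=nodes,
        weights=precision_to_partial(Theta_sel),
        communities=communities,
        lambda_selected=lam_sel,
        gamma=config.gamma,
        n=int(n),
        input_correlation=S,
        method=config.method,
        metadata={
            "ebic": score,
            "refit": config.refit,
            "lambda_grid": [lambda_grid[0], lambda_grid[-1], int(lambda_grid.size)],
            "path_edge_counts": [e for _, e, _ in path],
        },
    )


def _symptom_columns(table: pd.DataFrame) -> list[str]:
    cols = [node_to_column(nd) for nd in NETWORK_NODES]
    if all(c in table.columns for c in cols):
        return cols
    raise ValueError("table lacks the GAD01..GAD07 / PHQ01..PHQ09 item columns")


def estimate_network(
    items: pd.DataFrame | np.ndarray,
    config: EstimatorConfig = EstimatorConfig(),
    nodes: tuple[str, ...] | None = None,
    communities: dict[str, str] | None = None,
) -> GGMNetwork:
    """End-to-end estimation from an item table.

    Accepts either a cohort DataFrame containing the 16 symptom item
    columns (other columns are ignored) or a plain numeric matrix.
    """
    if isinstance(items, pd.DataFrame):
        if nodes is None and all(
            node_to_column(nd) in items.columns for nd in NETWORK_NODES
        ):
            nodes = NETWORK_NODES
            X = items[_symptom_columns(items)]
        else:
            X = items
            if nodes is None:
                nodes = tuple(items.columns)
    else:
        X = np.asarray(items)
        if nodes is None:
            nodes = tuple(str(j) for j in range(X.shape[1]))
    if communities is None:
        try:
            communities = default_communities(nodes)
        except ValueError:
            communities = {nd: "all" for nd in nodes}
    S = correlation_matrix(X, method=config.method)
    n = len(X)
    return select_network(S, n, config=config, nodes=nodes, communities=communities)


# ---------------------------------------------------------------------------
# covariate adjustment and network comparison
# ---------------------------------------------------------------------------


def adjust_for_covariates(
    items: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Residualize each item on an intercept plus covariate indicators.

    Categorical covariates are expanded to dummy indicators (first level
    dropped); aliased (collinear) design columns are removed with a
    warning.  Returns the residualized items with the original column
    names; downstream estimation is unchanged.
    """
    if len(items) != len(covariates):
        raise ValueError("items and covariates must have equal row counts")
    D = pd.get_dummies(covariates, drop_first=True, dtype=np.float64)
    X = np.column_stack([np.ones(len(D)), D.to_numpy()])
    # drop aliased columns by pivoted QR
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag[0] * 1e-10).sum())
    if rank < X.shape[1]:
        dropped = sorted(piv[rank:])
        names = ["intercept"] + list(D.columns)
        warnings.warn(
            f"dropping aliased covariate columns: {[names[i] for i in dropped]}",
            stacklevel=2,
        )
        X = X[:, sorted(piv[:rank])]
    Y = items.to_numpy(dtype=np.float64)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, columns=items.columns, index=items.index)


def compare_networks(a: GGMNetwork, b: GGMNetwork) -> NetworkComparison:
    """Spearman correlation and two-sample t over the edge-weight vectors.

    Both statistics are computed over the p(p-1)/2 upper-triangle weights;
    the t-test is the independent-sample pooled test (matching the
    descriptive comparisons).
    """
    if a.nodes != b.nodes:
        raise ValueError("networks are defined over different node sets")
    ua, ub = a.upper_weights(), b.upper_weights()
    if np.array_equal(ua, ub):
        r, rp = 1.0, 0.0
    else:
        r, rp = stats.spearmanr(ua, ub)
    from .descriptives import pooled_t_test

    try:
        t, _, tp = pooled_t_test(ua, ub)
    except ValueError:
        t, tp = 0.0, 1.0
    return NetworkComparison(float(r), float(rp), float(t), float(tp))
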
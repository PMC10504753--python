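"""Low-level graphical-lasso numerics.

Block coordinate-descent solver for the L1-penalized Gaussian log-likelihood

    max_Theta  log det Theta - tr(S Theta) - lam * sum_{i != j} |Theta_ij|

(the diagonal is not penalized), plus the pattern-constrained Gaussian MLE
used to score models on their unpenalized likelihood.  Both are jitted with
numba because the permutation and bootstrap stages re-estimate networks tens
of thousands of times; a single 16-node solve runs in ~0.1 ms warm.

The public entry points return the precision matrix Theta; exact zeros in
Theta (from the soft threshold) define the edge set.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso", "constrained_mle", "gaussian_loglik", "kkt_violation"]


@njit(cache=True)
def _glasso_cd(S, lam, W, B, tol, max_iter):
    """In-place block CD on the covariance estimate W with coefficient store B.

    B[j, k] holds the lasso coefficient of variable k in the regression for
    column j (B[j, j] unused).  Returns the number of outer sweeps used, or
    -1 on non-convergence.
    """
    p = S.shape[0]
    # scale for the convergence test: mean absolute off-diagonal of S
    s_off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_off += abs(S[i, j])
    s_off = s_off / (p * (p - 1)) + 1e-12

    w11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    beta = np.empty(p - 1)
    idx = np.empty(p - 1, dtype=np.int64)

    for sweep in range(max_iter):
        max_d = 0.0
        for j in range(p):
            m = 0
            for k in range(p):
                if k != j:
                    idx[m] = k
                    m += 1
            for a in range(p - 1):
                ia = idx[a]
                s12[a] = S[ia, j]
                beta[a] = B[j, ia]
                for b in range(p - 1):
                    w11[a, b] = W[ia, idx[b]]
            # lasso coordinate descent, warm-started from previous beta
            for it in range(200):
                d_in = 0.0
                for a in range(p - 1):
                    r = s12[a]
                    for b in range(p - 1):
                        if b != a:
                            r -= w11[a, b] * beta[b]
                    if r > lam:
                        bn = (r - lam) / w11[a, a]
                    elif r < -lam:
                        bn = (r + lam) / w11[a, a]
                    else:
                        bn = 0.0
                    d = abs(bn - beta[a])
                    if d > d_in:
                        d_in = d
                    beta[a] = bn
                if d_in < 0.1 * tol * s_off:
                    break
            # w12 = W11 beta
            for a in range(p - 1):
                w = 0.0
                for b in range(p - 1):
                    w += w11[a, b] * beta[b]
                ia = idx[a]
                d = abs(w - W[ia, j])
                if d > max_d:
                    max_d = d
                W[ia, j] = w
                W[j, ia] = w
                B[j, ia] = beta[a]
        if max_d < tol * s_off:
            return sweep + 1
    return -1


@njit(cache=True)
def _recover_precision(S, W, B, lam):
    """Theta from the converged (W, B); exact zeros where beta was zeroed."""
    p = S.shape[0]
    Theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for k in range(p):
            if k != j:
                dot += W[k, j] * B[j, k]
        tjj = 1.0 / (W[j, j] - dot)
        Theta[j, j] = tjj
        for k in range(p):
            if k != j and B[j, k] != 0.0:
                Theta[k, j] = -B[j, k] * tjj
    # symmetrize (the two block solutions agree only to tolerance)
    for i in range(p):
        for j in range(i + 1, p):
            if Theta[i, j] == 0.0 or Theta[j, i] == 0.0:
                Theta[i, j] = 0.0
                Theta[j, i] = 0.0
            else:
                v = 0.5 * (Theta[i, j] + Theta[j, i])
                Theta[i, j] = v
                Theta[j, i] = v
    return Theta


@njit(cache=True)
def _constrained_cd(S, adj, W, tol, max_iter):
    """Pattern-constrained Gaussian MLE (regression form of IPS).

    Iterates node-wise least squares restricted to each node's neighbors in
    ``adj`` until the implied covariance matches S on all allowed entries.
    """
    p = S.shape[0]
    s_off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_off += abs(S[i, j])
    s_off = s_off / (p * (p - 1)) + 1e-12

    B = np.zeros((p, p))
    for sweep in range(max_iter):
        max_d = 0.0
        for j in range(p):
            na = 0
            for k in range(p):
                if k != j and adj[k, j]:
                    na += 1
            if na == 0:
                for k in range(p):
                    if k != j:
                        if abs(W[k, j]) > max_d:
                            max_d = abs(W[k, j])
                        W[k, j] = 0.0
                        W[j, k] = 0.0
                        B[j, k] = 0.0
                continue
            act = np.empty(na, dtype=np.int64)
            m = 0
            for k in range(p):
                if k != j and adj[k, j]:
                    act[m] = k
                    m += 1
            Waa = np.empty((na, na))
            sa = np.empty(na)
            for a in range(na):
                sa[a] = S[act[a], j]
                for b in range(na):
                    Waa[a, b] = W[act[a], act[b]]
            beta_a = np.linalg.solve(Waa, sa)
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for a in range(na):
                    w += W[k, act[a]] * beta_a[a]
                d = abs(w - W[k, j])
                if d > max_d:
                    max_d = d
                W[k, j] = w
                W[j, k] = w
                B[j, k] = 0.0
            for a in range(na):
                B[j, act[a]] = beta_a[a]
        if max_d < tol * s_off:
            return _recover_precision(S, W, B, 0.0)
    return _recover_precision(S, W, B, 0.0)


def glasso(
    S: np.ndarray,
    lam: float,
    *,
    W_init: np.ndarray | None = None,
    B_init: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the graphical lasso at one penalty.

    Parameters
    ----------
    S
        Symmetric correlation (or covariance) matrix, positive semi-definite.
    lam
        Off-diagonal L1 penalty, >= 0.
    W_init, B_init
        Warm starts from a neighboring penalty on the path (copied, not
        mutated).

    Returns
    -------
    Theta, W, B
        Precision estimate (exact zeros off the support), its implied
        covariance, and the regression coefficients for warm-starting.

    Raises
    ------
    ValueError
        If lam < 0 or S is not square/symmetric.
    RuntimeError
        On non-convergence within ``max_iter`` outer sweeps.
    """
    S = np.asarray(S, dtype=np.float64)
    p = S.shape[0]
    if S.ndim != 2 or S.shape[1] != p:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    W = S.copy() if W_init is None else W_init.copy()
    np.fill_diagonal(W, np.diag(S))
    B = np.zeros((p, p)) if B_init is None else B_init.copy()
    n_iter = _glasso_cd(S, float(lam), W, B, float(tol), int(max_iter))
    if n_iter < 0:
        raise RuntimeError(
            f"graphical lasso did not converge at lambda={lam:.6g} "
            f"within {max_iter} sweeps"
        )
    Theta = _recover_precision(S, W, B, float(lam))
    return Theta, W, B


def constrained_mle(
    S: np.ndarray,
    adjacency: np.ndarray,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Gaussian MLE of the precision matrix under a fixed zero pattern.

    ``adjacency`` is a boolean symmetric matrix marking allowed off-diagonal
    entries.  Used to score EBIC on the unpenalized likelihood of the
    selected support.
    """
    S = np.asarray(S, dtype=np.float64)
    adj = np.asarray(adjacency, dtype=np.bool_)
    W = S.copy()
    return _constrained_cd(S, adj, W, float(tol), int(max_iter))


def gaussian_loglik(S: np.ndarray, Theta: np.ndarray, n: int) -> float:
    """Sample Gaussian log-likelihood (n/2)(log det Theta - tr(S Theta)).

    The additive -(np/2) log(2 pi) constant is omitted: it cancels in every
    model comparison the package performs.
    """
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        raise ValueError("Theta is not positive definite")
    return 0.5 * n * (logdet - float(np.sum(S * Theta)))


def kkt_violation(S: np.ndarray, Theta: np.ndarray, lam: float) -> float:
    """Maximum violation of the glasso stationarity conditions.

    For W = Theta^{-1}: |S_ij - W_ij| <= lam on zero entries and
    S_ij - W_ij = -lam * sign(Theta_ij) on active entries.
    """
    W = np.linalg.inv(Theta)
    G = S - W
    p = S.shape[0]
    viol = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            if Theta[i, j] == 0.0:
                viol = max(viol, abs(G[i, j]) - lam)
            else:
                viol = max(viol, abs(G[i, j] + lam * np.sign(Theta[i, j])))
    return viol
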
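"""One-dimensional latent components: PCA, PLS, and multi-block PLS.

Each fitter returns a unit-norm loading vector w and scores u = X_std w for
the current data block. The partial-correlation machinery controls for all
taxa except a pair (i, j) by zeroing the two loadings (a masking shortcut
that avoids refitting the component for each of the p(p-1)/2 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConvergenceError(RuntimeError):
    def __init__(self, msg, last_loadings=None, tol_achieved=None):
        super().__init__(msg)
        self.last_loadings = last_loadings
        self.tol_achieved = tol_achieved


@dataclass
class LatentFactor:
    """A one-dimensional component: scores u (n,) and unit loadings w (p,).

    For multi-block fits, ``block_loadings`` keeps the loadings of the past
    blocks; ``u`` and ``w`` always refer to the current (last) block.
    """

    u: np.ndarray
    w: np.ndarray
    method: str
    block_loadings: list[np.ndarray] = field(default_factory=list)
    time_index: int = 0
    X: np.ndarray | None = None  # the (possibly deflated) block the factor was fitted on

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.w = np.asarray(self.w, dtype=float)


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude loading is positive."""
    k = int(np.argmax(np.abs(w)))
    return -w if w[k] < 0 else w


def pca_first_component(X_std: np.ndarray) -> LatentFactor:
    """Leading principal component of a centred (standardized) matrix.

    w maximizes var(X_std w) subject to ||w|| = 1; computed from the SVD.
    """
    X = np.asarray(X_std, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 samples and p >= 2 taxa")
    if not X.any():
        raise ValueError("all-zero matrix has no principal component")
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    w = _fix_sign(vt[0])
    return LatentFactor(u=X @ w, w=w, method="pca", X=X)


def pls_first_components(
    X_prev_std: np.ndarray, X_curr_std: np.ndarray
) -> tuple[LatentFactor, LatentFactor]:
    """First PLS components of two row-matched blocks.

    The loadings are the leading left/right singular vectors of the
    cross-covariance X_prev' X_curr / (n - 1), maximizing
    Cov(X_prev w_prev, X_curr w_curr).
    """
    Xp = np.asarray(X_prev_std, dtype=float)
    Xc = np.asarray(X_curr_std, dtype=float)
    if Xp.shape[0] != Xc.shape[0]:
        raise ValueError("blocks must share samples (rows)")
    if Xp.shape[1] < 2 or Xc.shape[1] < 2:
        raise ValueError("each block needs at least 2 taxa")
    n = Xp.shape[0]
    C = Xp.T @ Xc / (n - 1)
    if not np.abs(C).max() > 0:
        raise ValueError("zero cross-covariance: no association to exploit")
    U, _, Vt = np.linalg.svd(C, full_matrices=False)
    w_prev = _fix_sign(U[:, 0])
    w_curr = _fix_sign(Vt[0])
    prev = LatentFactor(u=Xp @ w_prev, w=w_prev, method="pls", time_index=0, X=Xp)
    curr = LatentFactor(
        u=Xc @ w_curr, w=w_curr, method="pls", block_loadings=[w_prev], time_index=1, X=Xc
    )
    return prev, curr


def blockpls_first_components(
    blocks: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 500,
    return_history: bool = False,
):
    """First components of >= 2 row-matched blocks under a fully connected
    design, jointly maximizing the sum of pairwise score covariances.

    Iterative update w_q <- normalize(X_q' sum_{k != q} u_k), initialized from
    each block's own PCA loading, cycled until the largest loading change
    falls below ``tol``. The objective is non-decreasing across sweeps.
    """
    Xs = [np.asarray(b, dtype=float) for b in blocks]
    if len(Xs) < 2:
        raise ValueError("need at least 2 blocks")
    n = Xs[0].shape[0]
    for X in Xs:
        if X.shape[0] != n:
            raise ValueError("blocks must share samples (rows)")
        if X.shape[1] < 2:
            raise ValueError("each block needs at least 2 taxa")
    ws = [pca_first_component(X).w for X in Xs]
    us = [X @ w for X, w in zip(Xs, ws)]
    history = [_block_objective(us, n)]
    delta = np.inf
    for _ in range(max_iter):
        delta = 0.0
        for q, X in enumerate(Xs):
            other = sum(us[k] for k in range(len(Xs)) if k != q)
            w_new = X.T @ other
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                raise ValueError(f"block {q} decoupled: zero update direction")
            w_new /= nrm
            delta = max(delta, float(np.max(np.abs(w_new - ws[q]))))
            ws[q] = w_new
            us[q] = X @ w_new
        history.append(_block_objective(us, n))
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"blockPLS did not converge in {max_iter} iterations "
            f"(last max loading change {delta:.2e})",
            last_loadings=ws,
            tol_achieved=delta,
        )
    # the objective is invariant only under flipping ALL blocks jointly, so
    # the deterministic sign convention is applied globally via block 0
    k0 = int(np.argmax(np.abs(ws[0])))
    if ws[0][k0] < 0:
        ws = [-w for w in ws]
    factors = []
    for q, (X, w) in enumerate(zip(Xs, ws)):
        factors.append(
            LatentFactor(
                u=X @ w,
                w=w,
                method="blockpls",
                block_loadings=list(ws[:q]),
                time_index=q,
                X=X,
            )
        )
    if return_history:
        return factors, history
    return factors


def _block_objective(us: list[np.ndarray], n: int) -> float:
    """Sum over ordered pairs q != k of Cov(u_q, u_k)."""
    total = 0.0
    for q in range(len(us)):
        for k in range(len(us)):
            if q != k:
                total += float(us[q] @ us[k]) / (n - 1)
    return total


def fit_factor_once(
    X_blocks: list[np.ndarray],
    method: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LatentFactor:
    """Fit the latent factor on the full taxa set once, for later masking.

    Dispatch: one block -> PCA; two -> PLS; more -> blockPLS. The returned
    factor belongs to the last (current) block.
    """
    if method is None:
        method = {1: "pca", 2: "pls"}.get(len(X_blocks), "blockpls")
    if method == "pca":
        if len(X_blocks) != 1:
            raise ValueError("pca expects exactly one block")
        return pca_first_component(X_blocks[0])
    if method == "pls":
        if len(X_blocks) != 2:
            raise ValueError("pls expects exactly two blocks")
        return pls_first_components(X_blocks[0], X_blocks[1])[1]
    if method == "blockpls":
        return blockpls_first_components(X_blocks, tol=tol, max_iter=max_iter)[-1]
    raise ValueError(f"unknown method {method!r}")


def fit_factors(
    X_blocks: list[np.ndarray],
    method: str | None = None,
    n_components: int = 1,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[LatentFactor]:
    """Fit ``n_components`` successive factors for the current block.

    Components beyond the first are obtained by deflating every block on its
    own scores (X_q <- X_q - u_q u_q' X_q / u_q'u_q) and refitting, which for
    a single block reproduces successive principal components exactly.
    """
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1, 2 or 3")
    blocks = [np.asarray(b, dtype=float).copy() for b in X_blocks]
    factors = []
    for _ in range(n_components):
        if method is None:
            m = {1: "pca", 2: "pls"}.get(len(blocks), "blockpls")
        else:
            m = method
        if m == "pca":
            fitted = [pca_first_component(blocks[0])]
        elif m == "pls":
            fitted = list(pls_first_components(blocks[0], blocks[1]))
        else:
            fitted = blockpls_first_components(blocks, tol=tol, max_iter=max_iter)
        factors.append(fitted[-1])
        if len(factors) < n_components:
            for q, fac in enumerate(fitted):
                u = fac.u
                denom = float(u @ u)
                if denom > 0:
                    blocks[q] = blocks[q] - np.outer(u, u @ blocks[q]) / denom
    return factors


def masked_component(
    factor: LatentFactor,
    X_std: np.ndarray | None = None,
    i: int = 0,
    j: int = 1,
    renormalize: bool = False,
) -> np.ndarray:
    """Scores with the loadings of taxa i and j zeroed: u^{-(i,j)} = X w~.

    Exact identity given the fixed full-data loadings:
    u^{-(i,j)} = u - X[:, i] w_i - X[:, j] w_j. By default w~ is not
    renormalized — scaling w~ would only rescale the covariate, which an OLS
    slope absorbs anyway.
    """
    if i == j:
        raise ValueError("mask requires two distinct taxa")
    X = np.asarray(factor.X if X_std is None else X_std, dtype=float)
    u = factor.u - X[:, i] * factor.w[i] - X[:, j] * factor.w[j]
    if renormalize:
        w_norm = np.sqrt(max(1.0 - factor.w[i] ** 2 - factor.w[j] ** 2, 0.0))
        if w_norm > 0:
            u = u / w_norm
    return u
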
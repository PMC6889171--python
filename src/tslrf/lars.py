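"""Least Angle Regression over the whitened, standardized marker matrix.

This is the forward LARS procedure of Efron, Hastie, Johnstone & Tibshirani
(2004), without the lasso modification: at each step the variable most
correlated with the current residual joins the active set, and the fit moves
along the equiangular direction of the active set until an inactive variable
ties the active absolute correlation.  Because a LARS fit saturates after at
most n - 1 steps, the screen returns at most n - 1 candidate SNPs no matter
how many markers enter.

The implementation maintains a Cholesky factor of the active Gram matrix,
updated one column at a time, so a full 198-step path over 10,000 markers
costs two (p x n) mat-vecs per step plus O(s^2) for the factor update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = ["LarsPath", "lars_path", "cp_statistic", "select_variables"]

_CORR_TOL = 1e-10  # correlations below this are treated as a saturated fit


@dataclass
class LarsPath:
    """Ordered active set with per-step coefficients, RSS and Cp traces.

    ``coef_path[s]`` holds the coefficients after step s+1, aligned with
    ``active_order[: s + 1]``.
    """

    active_order: np.ndarray
    coef_path: list = field(repr=False, default_factory=list)
    rss_trace: np.ndarray = field(default=None)  # type: ignore[assignment]
    cp_trace: np.ndarray = field(default=None)  # type: ignore[assignment]
    s_max: int = 0
    n: int = 0
    p: int = 0
    sigma_bar2: float = 1.0

    def coefficients_full(self, step: int | None = None) -> np.ndarray:
        """Length-p coefficient vector after ``step`` steps (default: last)."""
        step = self.s_max if step is None else step
        beta = np.zeros(self.p)
        if step:
            beta[self.active_order[:step]] = self.coef_path[step - 1]
        return beta


def cp_statistic(rss_s: float, sigma_bar2: float, n: int, s: int) -> float:
    """Mallows-type risk estimate of an s-step LARS fit: RSS/sigma2 - n + 2s."""
    if sigma_bar2 <= 0:
        raise ValueError("sigma_bar2 must be positive")
    if not 0 <= s <= n - 1:
        raise ValueError(f"step s={s} outside [0, n-1]")
    return rss_s / sigma_bar2 - n + 2 * s


def _check_standardized(X: np.ndarray, tol: float = 1e-6) -> None:
    means = X.mean(axis=0)
    ss = np.sum(X**2, axis=0)
    if np.abs(means).max(initial=0.0) > tol or np.abs(ss - 1.0).max(initial=0.0) > tol:
        raise ValueError(
            "X columns must be centered with unit sum of squares before LARS"
        )


def lars_path(
    X: np.ndarray,
    Y: np.ndarray,
    max_steps: int,
    sigma_bar2: float | None = None,
) -> LarsPath:
    """Run the LARS screen and record the path.

    Parameters
    ----------
    X : (n, p) matrix with centered, unit-sum-of-squares columns.
    Y : length-n response (whitened phenotype, intercept projected out).
    max_steps : maximum number of variables to admit; capped at n - 1.
    sigma_bar2 : residual-variance scale for the Cp trace.  Defaults to the
        sample variance of Y (null-model estimate); with p >> n the ``full
        OLS model`` estimate of the classical Cp formula does not exist.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n, p = X.shape
    if Y.shape != (n,):
        raise ValueError("Y length does not match X rows")
    if max_steps > n - 1:
        raise ValueError(f"max_steps={max_steps} exceeds n-1={n - 1}")
    _check_standardized(X)
    if sigma_bar2 is None:
        sigma_bar2 = float(np.var(Y, ddof=1))
    if sigma_bar2 <= 0:
        raise ValueError("sigma_bar2 must be positive (is Y constant?)")

    mu = np.zeros(n)
    active: list[int] = []
    excluded = np.zeros(p, dtype=bool)
    L = np.zeros((max_steps, max_steps))
    XA = np.empty((n, max_steps))
    beta = np.zeros(max_steps)
    coef_path: list[np.ndarray] = []
    rss_trace: list[float] = []

    while len(active) < max_steps:
        c = X.T @ (Y - mu)
        cabs = np.abs(c)
        cabs[active] = -np.inf
        cabs[excluded] = -np.inf
        j = int(np.argmax(cabs))  # ties -> lowest column index
        Cmax = cabs[j]
        if Cmax < _CORR_TOL:
            break  # residual numerically orthogonal to every remaining column
        k = len(active)
        if not _chol_append_inplace(L, k, XA, X[:, j]):
            warnings.warn(
                f"marker column {j} is collinear with the active set; excluded"
            )
            excluded[j] = True
            continue
        XA[:, k] = X[:, j]
        active.append(j)
        k += 1

        sgn = np.sign(c[active])
        sgn[sgn == 0] = 1.0
        # equiangular direction: w = A * G_A^{-1} s,  u = X_A w,  ||u|| = 1
        tmp = solve_triangular(L[:k, :k], sgn, lower=True)
        ginv_s = solve_triangular(L[:k, :k].T, tmp, lower=False)
        A = 1.0 / np.sqrt(float(sgn @ ginv_s))
        w = A * ginv_s
        u = XA[:, :k] @ w
        C = float(np.mean(np.abs(c[active])))

        gamma = C / A  # step to the least-squares fit of the active set
        mask = ~excluded
        mask[active] = False
        if mask.any():
            a = X[:, mask].T @ u
            cm = c[mask]
            with np.errstate(divide="ignore", invalid="ignore"):
                g1 = (C - cm) / (A - a)
                g2 = (C + cm) / (A + a)
            cand = np.concatenate([g1, g2])
            cand = cand[np.isfinite(cand) & (cand > _CORR_TOL)]
            if cand.size:
                gamma = min(gamma, float(cand.min()))

        mu = mu + gamma * u
        beta[:k] += gamma * w
        coef_path.append(beta[:k].copy())
        rss_trace.append(float(np.sum((Y - mu) ** 2)))

    s_max = len(active)
    rss = np.asarray(rss_trace)
    cp = np.array(
        [cp_statistic(rss[s], sigma_bar2, n, s + 1) for s in range(s_max)]
    )
    return LarsPath(
        active_order=np.asarray(active, dtype=np.int64),
        coef_path=coef_path,
        rss_trace=rss,
        cp_trace=cp,
        s_max=s_max,
        n=n,
        p=p,
        sigma_bar2=sigma_bar2,
    )


def _chol_append_inplace(L, k, XA, xj) -> bool:
    """Grow the active-set Cholesky factor in place; False if collinear."""
    if k:
        g = XA[:, :k].T @ xj
        w = solve_triangular(L[:k, :k], g, lower=True)
        d2 = 1.0 - float(w @ w)
    else:
        w = np.empty(0)
        d2 = 1.0
    if d2 < 1e-12:
        return False
    L[k, :k] = w
    L[k, k] = np.sqrt(d2)
    return True


def select_variables(path: LarsPath, k: int | None = None) -> np.ndarray:
    """First k entries of the LARS active set (default: all of them)."""
    k = path.s_max if k is None else k
    if k > path.s_max:
        raise ValueError(f"k={k} exceeds the number of LARS steps {path.s_max}")
    return path.active_order[:k].copy()
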
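"""Polygenic-background control: kinship, REML variance components, whitening.

The phenotypic model is the standard GWAS mixed model

    y = W a + u + e,    u ~ N(0, sg2 * K),    e ~ N(0, s2 * I),

with W the fixed-effect design (intercept, optional structure covariates) and
K a marker-derived relatedness matrix.  The variance ratio lambda = sg2/s2 is
estimated once, on the null (no-QTN) model, by restricted maximum likelihood
profiled over lambda through the eigendecomposition of K (the EMMA device:
for each lambda the likelihood is available in closed form after rotating by
K's eigenvectors, so the 1-D profile can be gridded and then refined).

Whitening then premultiplies the model by C = (lambda*K + I)^(-1/2), after
which the combined polygenic + residual covariance is proportional to the
identity and the marker columns can be screened by ordinary least-squares
machinery.  Transformed marker columns are centered and scaled to unit sum of
squares (sum_i x_ij = 0, sum_i x_ij^2 = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .data_io import GenotypeMatrix, PhenotypeVector

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "WhitenedData",
    "compute_kinship",
    "read_kinship",
    "write_kinship",
    "estimate_variance_components",
    "whiten",
]

LAMBDA_BOUNDS = (1e-5, 1e5)
GRID_POINTS = 100


@dataclass
class KinshipMatrix:
    """Symmetric PSD n x n relatedness matrix aligned with a sample ordering."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.sample_ids) != n:
            raise ValueError("kinship matrix must be square and aligned with sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric (tolerance 1e-8)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, index: np.ndarray) -> "KinshipMatrix":
        index = np.asarray(index)
        return KinshipMatrix(
            values=self.values[np.ix_(index, index)],
            sample_ids=[self.sample_ids[i] for i in index],
        )


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma2: float
    lam: float
    reml_loglik: float

    def __post_init__(self) -> None:
        self.sigma_g2 = float(self.sigma_g2)
        self.sigma2 = float(self.sigma2)
        self.lam = float(self.lam)
        self.reml_loglik = float(self.reml_loglik)
        if self.sigma2 <= 0:
            raise ValueError("residual variance must be positive")
        if self.sigma_g2 < 0:
            raise ValueError("polygenic variance must be non-negative")
        if not np.isfinite(self.reml_loglik):
            raise ValueError("REML log-likelihood is not finite")
        if abs(self.lam - self.sigma_g2 / self.sigma2) > 1e-6 * max(1.0, self.lam):
            raise ValueError("lambda inconsistent with sigma_g2/sigma2")


@dataclass
class WhitenedData:
    """Transformed phenotype/markers of the whitened regression model.

    ``X`` columns are centered with unit sum of squares.  ``marker_index``
    maps X's columns back to columns of the genotype matrix (constant columns
    are dropped).  ``centers``/``scales`` record the affine map applied to the
    whitened raw columns, for transforming new samples consistently.
    """

    Y: np.ndarray
    X: np.ndarray
    C: np.ndarray
    fixed_design: np.ndarray
    marker_index: np.ndarray
    centers: np.ndarray
    scales: np.ndarray


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden-style standardized kinship K = M M^T / p.

    M is the column-centered, unit-variance-scaled marker matrix; monomorphic
    markers are excluded.  Requires an imputed (no-missing) genotype matrix.
    """
    if g.missing_mask.any():
        raise ValueError("compute_kinship requires imputed genotypes (no missing)")
    M = g.values - g.values.mean(axis=0)
    sd = g.values.std(axis=0, ddof=1)
    poly = sd > 0
    if not poly.any():
        raise ValueError("no polymorphic markers available for kinship")
    M = M[:, poly] / sd[poly]
    K = (M @ M.T) / poly.sum()
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, sample_ids=list(g.sample_ids))


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"{path}: kinship row/column sample ids differ")
    return KinshipMatrix(values=df.to_numpy(dtype=float), sample_ids=ids)


def write_kinship(k: KinshipMatrix, path) -> None:
    pd.DataFrame(k.values, index=k.sample_ids, columns=k.sample_ids).to_csv(path, sep="\t")


def _default_fixed_design(n: int, covariates: np.ndarray | None = None) -> np.ndarray:
    W = np.ones((n, 1))
    if covariates is not None:
        W = np.column_stack([W, np.asarray(covariates, dtype=float)])
    return W


def _reml_loglik(log_lam: float, s: np.ndarray, Wt: np.ndarray, yt: np.ndarray) -> float:
    """Restricted log-likelihood profiled over the variance scale, at lambda.

    Works in the eigenbasis of K: s are K's eigenvalues, Wt/yt the rotated
    fixed design and phenotype.
    """
    lam = 10.0 ** log_lam
    d = lam * s + 1.0
    n, c = Wt.shape
    Dinv = 1.0 / d
    WtD = Wt * Dinv[:, None]
    A = Wt.T @ WtD  # W' V^-1 W
    b = WtD.T @ yt
    alpha = np.linalg.solve(A, b)
    ypy = float(yt @ (Dinv * yt) - b @ alpha)
    nc = n - c
    if ypy <= 0:
        return -np.inf
    sigma2 = ypy / nc
    _, logdet_A = np.linalg.slogdet(A)
    _, logdet_WW = np.linalg.slogdet(Wt.T @ Wt)
    return -0.5 * (
        nc * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(d))
        + logdet_A
        - logdet_WW
    )


def estimate_variance_components(
    y: PhenotypeVector,
    k: KinshipMatrix,
    fixed_design: np.ndarray | None = None,
) -> VarianceComponents:
    """REML estimate of (sigma_g2, sigma2) for the null model y = W a + u + e.

    The profile likelihood in lambda = sigma_g2/sigma2 is evaluated on a
    100-point log grid over [1e-5, 1e5] and refined with a bounded scalar
    optimizer; sigma2 is recovered in closed form at the optimum.  When the
    profile is flat (e.g. K = I, where sg2*K + s2*I is unidentifiable) the
    estimate is returned at the lower boundary with a warning.
    """
    yv = np.asarray(y.values, dtype=float)
    if np.isnan(yv).any():
        raise ValueError("phenotype contains missing values; drop them first")
    n = yv.size
    if n < 10:
        raise ValueError("need at least 10 samples for variance-component REML")
    if np.var(yv) == 0:
        raise ValueError("phenotype has zero variance")
    if k.n != n:
        raise ValueError("kinship size does not match phenotype length")
    W = fixed_design if fixed_design is not None else _default_fixed_design(n)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("fixed design is rank deficient")

    s, U = eigh(k.values)
    if s.min() < -1e-8:
        raise ValueError(f"kinship is not PSD (min eigenvalue {s.min():.3g})")
    s = np.clip(s, 0.0, None)
    yt = U.T @ yv
    Wt = U.T @ W

    lo, hi = np.log10(LAMBDA_BOUNDS[0]), np.log10(LAMBDA_BOUNDS[1])
    grid = np.linspace(lo, hi, GRID_POINTS)
    ll = np.array([_reml_loglik(g, s, Wt, yt) for g in grid])
    best = int(np.argmax(ll))
    if ll.max() - ll.min() < 1e-6:
        warnings.warn(
            "REML profile is flat in lambda (variance components unidentifiable); "
            "returning the boundary estimate"
        )
        log_lam_hat, ll_hat = grid[0], ll[0]
    else:
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, GRID_POINTS - 1)]
        res = minimize_scalar(
            lambda t: -_reml_loglik(t, s, Wt, yt),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-6},
        )
        log_lam_hat, ll_hat = float(res.x), -float(res.fun)
        if ll[best] > ll_hat:  # refinement must not lose to the grid
            log_lam_hat, ll_hat = grid[best], ll[best]

    lam = 10.0 ** log_lam_hat
    d = lam * s + 1.0
    Dinv = 1.0 / d
    WtD = Wt * Dinv[:, None]
    A = Wt.T @ WtD
    b_vec = WtD.T @ yt
    ypy = float(yt @ (Dinv * yt) - b_vec @ np.linalg.solve(A, b_vec))
    sigma2 = ypy / (n - W.shape[1])
    return VarianceComponents(
        sigma_g2=lam * sigma2, sigma2=sigma2, lam=lam, reml_loglik=ll_hat
    )


def whitening_matrix(k: KinshipMatrix, lam: float) -> np.ndarray:
    """C = (lam*K + I)^(-1/2) via the eigendecomposition of K."""
    s, U = eigh(k.values)
    d = lam * np.clip(s, 0.0, None) + 1.0
    if d.min() < 1e-10:
        raise np.linalg.LinAlgError("lam*K + I has an eigenvalue below 1e-10")
    return (U * (d ** -0.5)) @ U.T


def whiten(
    y: PhenotypeVector,
    g: GenotypeMatrix,
    k: KinshipMatrix,
    vc: VarianceComponents,
    covariates: np.ndarray | None = None,
) -> WhitenedData:
    """Apply the model transformation that makes the residual covariance s2*I.

    Y = C y and each raw marker column z_j becomes C z_j, then is centered and
    scaled to unit sum of squares.  Columns that are constant after the
    transformation are dropped with a warning (their scaling is undefined).
    """
    if g.missing_mask.any():
        raise ValueError("whiten requires imputed genotypes")
    C = whitening_matrix(k, vc.lam)
    Y = C @ np.asarray(y.values, dtype=float)
    Xraw = C @ g.values
    centers = Xraw.mean(axis=0)
    Xc = Xraw - centers
    scales = np.sqrt(np.sum(Xc**2, axis=0))
    keep = scales > 1e-8
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} constant marker columns after whitening")
    X = Xc[:, keep] / scales[keep]
    W = _default_fixed_design(g.n_samples, covariates)
    return WhitenedData(
        Y=Y,
        X=X,
        C=C,
        fixed_design=C @ W,
        marker_index=np.flatnonzero(keep),
        centers=centers[keep],
        scales=scales[keep],
    )
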
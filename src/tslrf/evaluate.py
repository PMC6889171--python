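"""Prediction-accuracy metrics and the ten-fold cross-validation protocol.

MAE = (1/n) sum |y_i - yhat_i| and MAPE = (1/n) sum |(y_i - yhat_i)/y_i|
(fraction scale, no x100).  The correlation is the product-moment r computed
from standardized scores with n-1 denominators, normalized so |r| <= 1.

``ten_fold_cv`` re-runs the *entire* requested pipeline -- kinship, REML,
whitening and the LARS screen included -- on each training fold, so held-out
samples never influence marker selection ("no peeking").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeMatrix, PhenotypeVector
from .pipeline import (
    PipelineConfig,
    _align_samples,
    _rf_baseline_fit,
    predict_tslrf,
    run_tslrf,
)

__all__ = ["CVResult", "mae", "mape", "pearson_r", "ten_fold_cv"]


@dataclass
class CVResult:
    fold_assignment: np.ndarray  # 1-based fold label per sample
    predictions: np.ndarray  # out-of-fold prediction per sample
    mae: float
    mape: float
    pearson_r: float
    seed: int


def _check_pair(y, yhat, min_n: int = 1):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D vectors of equal length")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if np.isnan(y).any() or np.isnan(yhat).any():
        raise ValueError("missing values are not allowed in metric inputs")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def mape(y, yhat) -> float:
    """Mean absolute percentage error on the fraction scale; y_i = 0 is an error."""
    y, yhat = _check_pair(y, yhat)
    zeros = np.flatnonzero(y == 0)
    if zeros.size:
        raise ValueError(f"MAPE undefined: y is zero at index {zeros[0]}")
    return float(np.mean(np.abs((y - yhat) / y)))


def pearson_r(y, yhat) -> float:
    """Product-moment correlation of observed and predicted values."""
    y, yhat = _check_pair(y, yhat, min_n=2)
    sy = np.std(y, ddof=1)
    syh = np.std(yhat, ddof=1)
    if sy == 0 or syh == 0:
        raise ValueError("pearson_r undefined for constant input")
    n = y.size
    r = float(np.sum((y - y.mean()) / sy * (yhat - yhat.mean()) / syh) / (n - 1))
    assert abs(r) <= 1 + 1e-9
    return r


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition into folds whose sizes differ by at most one."""
    labels = np.empty(n, dtype=np.int64)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, n_folds), start=1):
        if chunk.size < 2:
            raise ValueError("a fold has fewer than 2 samples; reduce n_folds")
        labels[chunk] = f
    return labels


def ten_fold_cv(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    cfg: PipelineConfig | None = None,
    method: str = "tslrf",
    seed: int | None = None,
    n_folds: int = 10,
) -> CVResult:
    """Out-of-fold phenotype prediction with per-fold pipeline refits.

    ``method`` is one of ``tslrf``, ``rf`` (single-stage forest) or ``tsrf``.
    Metrics are computed on the pooled out-of-fold predictions.
    """
    if method not in {"tslrf", "rf", "tsrf"}:
        raise ValueError(f"unknown method {method!r}")
    cfg = cfg if cfg is not None else PipelineConfig()
    g2, y2 = _align_samples(g, y)
    n = g2.n_samples
    if n < 20:
        raise ValueError("need at least 20 samples for cross-validation")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0xCF]))
    folds = _fold_assignment(n, n_folds, rng)
    fold_seeds = {
        f: int(s.generate_state(1)[0]) % 2**31
        for f, s in enumerate(np.random.SeedSequence(seed).spawn(n_folds), start=1)
    }

    preds = np.full(n, np.nan)
    for f in range(1, n_folds + 1):
        train = np.flatnonzero(folds != f)
        test = np.flatnonzero(folds == f)
        g_tr, g_te = g2.subset_samples(train), g2.subset_samples(test)
        y_tr = PhenotypeVector(
            sample_ids=list(g_tr.sample_ids), values=y2.values[train]
        )
        fold_cfg = PipelineConfig(
            **{**cfg.__dict__, "seed": fold_seeds[f], "compute_importance": False}
        )
        if method == "tslrf":
            fit = run_tslrf(g_tr, y_tr, fold_cfg)
            preds[test] = predict_tslrf(fit, g_te)
        elif method == "rf":
            _, model, g_fit, fill = _rf_baseline_fit(g_tr, y_tr, fold_cfg)
            preds[test] = _predict_raw(model, g_fit, fill, g_te)
        else:  # tsrf: eliminate on the training fold, predict with final forest
            preds[test] = _tsrf_fold_predict(g_tr, y_tr, fold_cfg, g_te)

    return CVResult(
        fold_assignment=folds,
        predictions=preds,
        mae=mae(y2.values, preds),
        mape=mape(y2.values, preds),
        pearson_r=pearson_r(y2.values, preds),
        seed=int(seed),
    )


def _predict_raw(model, g_fit: GenotypeMatrix, fill, g_new: GenotypeMatrix) -> np.ndarray:
    """Predict new samples from a forest fitted on raw (filtered) marker codes."""
    pos = {m: i for i, m in enumerate(g_new.marker_ids)}
    cols = [pos[m] for m in g_fit.marker_ids]
    Z = g_new.values[:, cols].astype(float)
    mask = g_new.missing_mask[:, cols]
    if mask.any():
        f = fill if fill is not None else g_fit.values.mean(axis=0)
        Z = np.where(mask, np.asarray(f)[None, :], Z)
    return model.predict(Z)


def _tsrf_fold_predict(g_tr, y_tr, cfg: PipelineConfig, g_te) -> np.ndarray:
    from .pipeline import _prepare, run_tsrf_comparator
    from .forest import fit_forest

    table = run_tsrf_comparator(g_tr, y_tr, cfg)
    g2, y2, fill = _prepare(g_tr, y_tr, cfg)
    surv_ids = list(table.marker_id)
    pos = {m: i for i, m in enumerate(g2.marker_ids)}
    cols = np.array([pos[m] for m in surv_ids])
    model = fit_forest(
        g2.values[:, cols],
        y2.values,
        ntree=cfg.ntree,
        mtry=max(1, cols.size // 3),
        seed=cfg.seed,
        min_samples_leaf=cfg.min_samples_leaf,
    )
    g_fit = g2.subset_markers(cols)
    return _predict_raw(model, g_fit, None if fill is None else fill[cols], g_te)
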
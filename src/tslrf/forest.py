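"""Stage-2 random-forest regression and %IncMSE permutation importance.

The ensemble itself is scikit-learn's :class:`RandomForestRegressor`
(bootstrap resampling + per-node random subspaces of size ``mtry``, minimum
node size 5 -- the classical regression-forest configuration).  What this
module adds is the out-of-bag bookkeeping and the permutation importance in
the classical %IncMSE convention: for every tree, the increase in mean
squared error on that tree's out-of-bag samples after permuting one variable;
the per-variable score is the mean increase over trees divided by its
standard error (``scaled=True``, the convention whose scores behave like
t-statistics), or the raw mean increase (``scaled=False``).

Permuting a variable that a tree never splits on cannot change that tree's
predictions, so per tree only the variables appearing in its split nodes are
permuted explicitly; the remaining increases are exactly zero.  This makes
the importance pass cheap even for forests over many thousands of markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ForestModel",
    "ImportanceResult",
    "fit_forest",
    "tune_mtry",
    "permutation_importance",
    "default_mtry_grid",
]


@dataclass
class ForestModel:
    """A fitted bagged-tree ensemble with out-of-bag predictions."""

    model: RandomForestRegressor = field(repr=False)
    ntree: int
    mtry: int
    seed: int
    oob_predictions: np.ndarray
    oob_mse: float
    oob_counts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    inbag: list = field(repr=False, default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=np.float64))


@dataclass
class ImportanceResult:
    scores: np.ndarray
    permutations: int
    seed: int


def default_mtry_grid(k: int) -> list[int]:
    """Candidate per-node subspace sizes: k/3, sqrt(k), k/2 and k (deduplicated)."""
    if k < 1:
        raise ValueError("need at least one variable")
    return sorted({max(1, k // 3), max(1, int(np.sqrt(k))), max(1, k // 2), k})


def fit_forest(
    X_sel: np.ndarray,
    Y: np.ndarray,
    ntree: int = 500,
    mtry: int | None = None,
    seed: int = 0,
    min_samples_leaf: int = 5,
) -> ForestModel:
    """Grow a regression forest on the selected variables.

    ``mtry`` defaults to max(1, k/3), the classical regression-forest choice.
    Refitting with the same seed reproduces the ensemble (and its OOB error)
    exactly.
    """
    X_sel = np.asarray(X_sel, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n, k = X_sel.shape
    if k < 1 or ntree < 1:
        raise ValueError("need at least one variable and one tree")
    if mtry is None:
        mtry = max(1, k // 3)
    if not 1 <= mtry <= k:
        raise ValueError(f"mtry={mtry} outside [1, {k}]")
    rf = RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        min_samples_leaf=min_samples_leaf,
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    rf.fit(X_sel, Y)

    inbag = [np.asarray(s) for s in rf.estimators_samples_]
    pred_sum = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for tree, bag in zip(rf.estimators_, inbag):
        oob = np.ones(n, dtype=bool)
        oob[bag] = False
        if oob.any():
            pred_sum[oob] += tree.predict(X_sel[oob])
            counts[oob] += 1
    covered = counts > 0
    if not covered.all():
        warnings.warn(
            f"{np.sum(~covered)} samples were never out-of-bag; "
            "OOB error computed on the covered samples only"
        )
    oob_pred = np.full(n, np.nan)
    oob_pred[covered] = pred_sum[covered] / counts[covered]
    oob_mse = float(np.mean((Y[covered] - oob_pred[covered]) ** 2)) if covered.any() else np.nan
    return ForestModel(
        model=rf,
        ntree=ntree,
        mtry=mtry,
        seed=int(seed),
        oob_predictions=oob_pred,
        oob_mse=oob_mse,
        oob_counts=counts,
        inbag=inbag,
    )


def tune_mtry(
    X_sel: np.ndarray,
    Y: np.ndarray,
    grid: list[int] | None = None,
    ntree: int = 500,
    seed: int = 0,
) -> int:
    """Return the grid value with the smallest OOB MSE (ties -> smallest mtry)."""
    k = np.asarray(X_sel).shape[1]
    if grid is None:
        grid = default_mtry_grid(k)
    if not grid:
        raise ValueError("empty mtry grid")
    for m in grid:
        if not 1 <= m <= k:
            raise ValueError(f"grid value {m} outside [1, {k}]")
    best_m, best_mse = None, np.inf
    for m in sorted(grid):
        mse = fit_forest(X_sel, Y, ntree=ntree, mtry=m, seed=seed).oob_mse
        if mse < best_mse:
            best_m, best_mse = m, mse
    return int(best_m)


def permutation_importance(
    model: ForestModel,
    X_sel: np.ndarray,
    Y: np.ndarray,
    permutations: int = 1,
    seed: int = 0,
    scaled: bool = True,
) -> ImportanceResult:
    """Classical per-tree OOB permutation importance (%IncMSE).

    For each tree t with out-of-bag index set O_t and each variable j,

        d_tj = MSE_t(permute column j on O_t) - MSE_t(O_t),

    averaged over ``permutations`` independent permutation draws.  The score
    of variable j is mean_t(d_tj) / (sd_t(d_tj) / sqrt(ntree)) when
    ``scaled``, else mean_t(d_tj).  Variables a tree never splits on have
    d_tj = 0 identically and enter the mean and SD as zeros.
    """
    X_sel = np.asarray(X_sel, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n, k = X_sel.shape
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0x9E37]))

    deltas = np.zeros((model.ntree, k))
    n_oob_trees = 0
    for t, (tree, bag) in enumerate(zip(model.model.estimators_, model.inbag)):
        oob = np.ones(n, dtype=bool)
        oob[bag] = False
        m = int(oob.sum())
        if m == 0:
            continue
        n_oob_trees += 1
        Xo = X_sel[oob]
        yo = Y[oob]
        base_err = float(np.mean((yo - tree.predict(Xo)) ** 2))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size == 0:
            continue
        acc = np.zeros(used.size)
        for _ in range(permutations):
            Xrep = np.tile(Xo, (used.size, 1))
            for i, j in enumerate(used):
                Xrep[i * m : (i + 1) * m, j] = Xo[rng.permutation(m), j]
            preds = tree.predict(Xrep).reshape(used.size, m)
            acc += np.mean((yo[None, :] - preds) ** 2, axis=1) - base_err
        deltas[t, used] = acc / permutations

    if n_oob_trees == 0:
        warnings.warn("no tree had out-of-bag samples; importance undefined")
        return ImportanceResult(
            scores=np.full(k, np.nan), permutations=permutations, seed=int(seed)
        )

    mean = deltas.mean(axis=0)
    if scaled:
        se = deltas.std(axis=0, ddof=0) / np.sqrt(model.ntree)
        scores = np.where(se > 0, mean / np.where(se > 0, se, 1.0), mean)
    else:
        scores = mean
    return ImportanceResult(scores=scores, permutations=permutations, seed=int(seed))
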
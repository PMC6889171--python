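"""End-to-end orchestration of the two-stage screen and its comparators.

``run_tslrf`` chains: sample alignment -> MAF filter -> imputation -> kinship
-> REML variance components -> whitening -> LARS screen (at most n - 1 SNPs)
-> mtry-tuned random forest -> %IncMSE permutation importance -> ranking.
``run_rf_baseline`` is the single-stage forest over all filtered SNPs and
``run_tsrf_comparator`` a group-wise backward-elimination forest; both exist
to quantify what the whitening + LARS stages buy.

All randomness is derived from ``PipelineConfig.seed`` through a
SeedSequence, so a rerun with the same config and inputs is bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    GenotypeMatrix,
    ImportanceTable,
    PhenotypeVector,
    filter_maf,
    impute_missing,
)
from .forest import (
    ForestModel,
    default_mtry_grid,
    fit_forest,
    permutation_importance,
    tune_mtry,
)
from .kinship_background import (
    KinshipMatrix,
    VarianceComponents,
    WhitenedData,
    compute_kinship,
    estimate_variance_components,
    whiten,
)
from .lars import LarsPath, lars_path, select_variables

__all__ = [
    "PipelineConfig",
    "TslrfResult",
    "run_tslrf",
    "predict_tslrf",
    "run_rf_baseline",
    "run_tsrf_comparator",
]

log = logging.getLogger("tslrf")


@dataclass
class PipelineConfig:
    """Tunable knobs of the two-stage pipeline (defaults follow the study design)."""

    maf_threshold: float = 0.10
    lars_max_steps: int | None = None  # None -> n - 1
    ntree: int = 500
    mtry_grid: list | None = None  # None -> {k/3, sqrt(k), k/2, k}
    tune_mtry: bool = True  # False -> fixed mtry = k/3, no tuning fits
    top_m: int = 20
    seed: int = 0
    covariates: np.ndarray | None = None
    kinship: KinshipMatrix | None = None
    min_samples_leaf: int = 5
    permutations: int = 1
    scaled_importance: bool = True
    baseline_mtry: int | None = None  # None -> p/3 for the single-stage forest
    tsrf_group_size: int = 1000
    compute_importance: bool = True  # False: fit/predict only (used inside CV)

    def __post_init__(self) -> None:
        if self.ntree < 1 or self.top_m < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")


@dataclass
class TslrfResult:
    """Everything the two-stage run produced, plus what a rerun needs."""

    importance: ImportanceTable | None
    lars_path: LarsPath
    variance_components: VarianceComponents
    forest: ForestModel = field(repr=False)
    whitened: WhitenedData = field(repr=False)
    selected: np.ndarray  # column indices into the filtered genotype matrix
    fitted_values: np.ndarray = field(repr=False)
    config: PipelineConfig = field(repr=False, default=None)  # type: ignore[assignment]
    predict_state: dict = field(repr=False, default_factory=dict)

    def top(self, m: int | None = None):
        return self.importance.top(m if m is not None else self.config.top_m)


def _align_samples(
    g: GenotypeMatrix, y: PhenotypeVector
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Intersect and reorder samples by id (genotype order), dropping missing y."""
    y_by_id = dict(zip(y.sample_ids, y.values))
    keep = [
        i
        for i, sid in enumerate(g.sample_ids)
        if sid in y_by_id and np.isfinite(y_by_id[sid])
    ]
    if not keep:
        raise ValueError("no samples shared between genotypes and phenotypes")
    g2 = g.subset_samples(np.asarray(keep))
    return g2, PhenotypeVector(
        sample_ids=list(g2.sample_ids),
        values=np.array([y_by_id[s] for s in g2.sample_ids]),
    )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) % 2**31 for s in np.random.SeedSequence(seed).spawn(n)]


def _prepare(g: GenotypeMatrix, y: PhenotypeVector, cfg: PipelineConfig):
    g2, y2 = _align_samples(g, y)
    if g2.n_samples < 20:
        raise ValueError(f"need at least 20 aligned samples, have {g2.n_samples}")
    log.info("stage=filter markers_in=%d maf>=%.3g", g2.n_markers, cfg.maf_threshold)
    g2 = filter_maf(g2, cfg.maf_threshold)
    if g2.n_markers < 2:
        raise ValueError("fewer than 2 polymorphic markers after MAF filtering")
    fill = None
    if g2.missing_mask.any():
        obs = np.where(g2.missing_mask, np.nan, g2.values)
        fill = np.nanmean(obs, axis=0)
    g2 = impute_missing(g2, "column_mean")
    return g2, y2, fill


def run_tslrf(g: GenotypeMatrix, y: PhenotypeVector, cfg: PipelineConfig | None = None) -> TslrfResult:
    """Run the full two-stage screen and return scored, ranked candidate SNPs.

    At most n - 1 SNPs (the LARS saturation bound) receive importance scores;
    all other SNPs are unselected and carry no score.
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    g2, y2, fill = _prepare(g, y, cfg)
    n = g2.n_samples

    k_matrix = cfg.kinship.subset(
        [cfg.kinship.sample_ids.index(s) for s in g2.sample_ids]
    ) if cfg.kinship is not None else compute_kinship(g2)
    log.info("stage=kinship n=%d", n)
    vc = estimate_variance_components(y2, k_matrix, _fixed_design(n, cfg.covariates))
    log.info("stage=reml lambda=%.4g sigma2=%.4g", vc.lam, vc.sigma2)
    wd = whiten(y2, g2, k_matrix, vc, covariates=cfg.covariates)
    log.info("stage=whiten markers=%d", wd.X.shape[1])

    Yc = wd.Y - wd.Y.mean()  # intercept projected out of the screen
    max_steps = min(cfg.lars_max_steps or n - 1, n - 1, wd.X.shape[1])
    path = lars_path(wd.X, Yc, max_steps=max_steps)
    sel = select_variables(path)
    log.info("stage=lars k=%d", sel.size)

    X_sel = wd.X[:, sel]
    forest_seed, imp_seed, tune_seed = _spawn_seeds(cfg.seed, 3)
    k = sel.size
    if cfg.tune_mtry:
        grid = cfg.mtry_grid if cfg.mtry_grid is not None else default_mtry_grid(k)
        mtry = tune_mtry(X_sel, wd.Y, grid=grid, ntree=cfg.ntree, seed=tune_seed) if len(grid) > 1 else int(grid[0])
    else:
        mtry = max(1, k // 3)
    model = fit_forest(
        X_sel,
        wd.Y,
        ntree=cfg.ntree,
        mtry=mtry,
        seed=forest_seed,
        min_samples_leaf=cfg.min_samples_leaf,
    )
    log.info("stage=forest ntree=%d mtry=%d oob_mse=%.4g", cfg.ntree, mtry, model.oob_mse)
    orig = wd.marker_index[sel]  # columns of the filtered genotype matrix
    table = None
    if cfg.compute_importance:
        imp = permutation_importance(
            model,
            X_sel,
            wd.Y,
            permutations=cfg.permutations,
            seed=imp_seed,
            scaled=cfg.scaled_importance,
        )
        log.info("stage=importance k=%d", k)
        table = ImportanceTable.from_scores(
            marker_id=g2.marker_ids[orig],
            chromosome=g2.chromosomes[orig],
            position=g2.positions[orig],
            score=imp.scores,
        )
    # Map forest outputs (whitened-phenotype scale) back to the raw phenotype
    # scale through the average whitening shrinkage c_bar = tr(C)/n: exact for
    # C = I and for the near-scalar C that a weakly informative kinship gives.
    c_bar = float(np.trace(wd.C) / n)
    y_mean = float(np.mean(y2.values))
    Y_mean = float(np.mean(wd.Y))
    fitted = y_mean + (model.predict(X_sel) - Y_mean) / c_bar
    # Raw-scale training column stats for mapping new samples into the feature
    # space the forest was trained on: for C = c*I the whitened standardized
    # column equals the raw standardized column (the scalar cancels), so new
    # samples are standardized with the raw centers and norms.
    Zsel = g2.values[:, orig]
    raw_centers = Zsel.mean(axis=0)
    raw_scales = np.sqrt(np.sum((Zsel - raw_centers) ** 2, axis=0))
    predict_state = {
        "marker_ids": list(g2.marker_ids[orig]),
        "fill": None if fill is None else fill[wd.marker_index[sel]],
        "centers": raw_centers,
        "scales": raw_scales,
        "c_bar": c_bar,
        "y_mean": y_mean,
        "Y_mean": Y_mean,
    }
    return TslrfResult(
        importance=table,
        lars_path=path,
        variance_components=vc,
        forest=model,
        whitened=wd,
        selected=orig,
        fitted_values=fitted,
        config=cfg,
        predict_state=predict_state,
    )


def _fixed_design(n: int, covariates) -> np.ndarray:
    W = np.ones((n, 1))
    if covariates is not None:
        W = np.column_stack([W, np.asarray(covariates, dtype=float)])
    return W


def predict_tslrf(result: TslrfResult, g_new: GenotypeMatrix) -> np.ndarray:
    """Predict phenotypes for unseen samples from a fitted two-stage model.

    New samples cannot participate in the training-fold whitening rotation, so
    their selected marker columns are mapped through the training centering and
    scaling only, and the forest output (whitened scale) is mapped back to the
    phenotype scale via the average whitening shrinkage; this is exact when the
    estimated variance ratio is ~0 and an approximation otherwise.
    """
    st = result.predict_state
    pos = {m: i for i, m in enumerate(g_new.marker_ids)}
    try:
        cols = [pos[m] for m in st["marker_ids"]]
    except KeyError as exc:
        raise ValueError(f"marker {exc} absent from the new genotype matrix") from None
    Z = g_new.values[:, cols].astype(float)
    mask = g_new.missing_mask[:, cols]
    if mask.any():
        fill = st["fill"] if st["fill"] is not None else st["centers"]
        Z = np.where(mask, np.asarray(fill)[None, :], Z)
    X = (Z - st["centers"][None, :]) / st["scales"][None, :]
    return st["y_mean"] + (result.forest.predict(X) - st["Y_mean"]) / st["c_bar"]


# ---------------------------------------------------------------------------
# comparators


def run_rf_baseline(
    g: GenotypeMatrix, y: PhenotypeVector, cfg: PipelineConfig | None = None
) -> ImportanceTable:
    """Single-stage forest over all MAF-filtered SNPs (no whitening, no LARS)."""
    table, _, _, _ = _rf_baseline_fit(g, y, cfg if cfg is not None else PipelineConfig())
    return table


def _rf_baseline_fit(g: GenotypeMatrix, y: PhenotypeVector, cfg: PipelineConfig):
    g2, y2, fill = _prepare(g, y, cfg)
    p = g2.n_markers
    mtry = cfg.baseline_mtry if cfg.baseline_mtry is not None else max(1, p // 3)
    forest_seed, imp_seed = _spawn_seeds(cfg.seed, 2)
    model = fit_forest(
        g2.values,
        y2.values,
        ntree=cfg.ntree,
        mtry=mtry,
        seed=forest_seed,
        min_samples_leaf=cfg.min_samples_leaf,
    )
    table = None
    if cfg.compute_importance:
        imp = permutation_importance(
            model,
            g2.values,
            y2.values,
            permutations=cfg.permutations,
            seed=imp_seed,
            scaled=cfg.scaled_importance,
        )
        table = ImportanceTable.from_scores(
            marker_id=g2.marker_ids,
            chromosome=g2.chromosomes,
            position=g2.positions,
            score=imp.scores,
        )
    return table, model, g2, fill


def run_tsrf_comparator(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    cfg: PipelineConfig | None = None,
    group_size: int | None = None,
) -> ImportanceTable:
    """Group-wise backward-elimination forest (approximate TSRF reconstruction).

    Repeatedly fits a forest on the surviving SNPs and discards the
    ``group_size`` lowest-scoring ones until at most ``group_size`` survive;
    the final forest supplies the survivors' scores.  This follows a textual
    description of the original procedure and is best-effort, not exact.
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    group_size = group_size if group_size is not None else cfg.tsrf_group_size
    g2, y2, _ = _prepare(g, y, cfg)
    p = g2.n_markers
    if group_size >= p:
        warnings.warn("group_size >= marker count; degenerating to the plain forest")
        return run_rf_baseline(g, y, cfg)
    seeds = iter(_spawn_seeds(cfg.seed, 2 * (p // group_size + 2)))
    surviving = np.arange(p)
    while surviving.size > group_size:
        X = g2.values[:, surviving]
        model = fit_forest(
            X,
            y2.values,
            ntree=cfg.ntree,
            mtry=max(1, surviving.size // 3),
            seed=next(seeds),
            min_samples_leaf=cfg.min_samples_leaf,
        )
        imp = permutation_importance(
            model, X, y2.values, permutations=cfg.permutations,
            seed=next(seeds), scaled=cfg.scaled_importance,
        )
        drop = min(group_size, surviving.size - group_size)
        order = np.argsort(imp.scores, kind="stable")  # lowest scores first
        surviving = np.delete(surviving, order[:drop])
    X = g2.values[:, surviving]
    model = fit_forest(
        X,
        y2.values,
        ntree=cfg.ntree,
        mtry=max(1, surviving.size // 3),
        seed=next(seeds),
        min_samples_leaf=cfg.min_samples_leaf,
    )
    imp = permutation_importance(
        model, X, y2.values, permutations=cfg.permutations,
        seed=next(seeds), scaled=cfg.scaled_importance,
    )
    return ImportanceTable.from_scores(
        marker_id=g2.marker_ids[surviving],
        chromosome=g2.chromosomes[surviving],
        position=g2.positions[surviving],
        score=imp.scores,
    )
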
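"""ROC/AUC scoring, cross-validation, and model selection.

AUC is computed in its Mann-Whitney form: the probability that a randomly
chosen positive sample outscores a randomly chosen negative one, with ties
counted one half.  Cross-validation uses stratified k-fold splits (or
leave-one-out, where held-out scores are pooled into a single AUC), always
standardizing with training-fold statistics.  In nested mode a feature
selector runs inside each training fold so that selection optimism cannot
leak into the validation AUC.

Model selection evaluates a grid of (model family, latent-variable count
M, retention size p) cells by cross-validated AUC, sharing one FFS score
table per retention pass, and picks the argmax (ties resolved toward the
smaller M, then the smaller p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import feature_reduction as fr
from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .kernels import KernelSpec
from .kpls import KPLSModel, predict_kpls, train_kpls
from .pls import PLSModel, predict_pls, train_pls


@dataclass
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int


def auc(scores, labels) -> ROCResult:
    """Mann-Whitney AUC of ``scores`` against +-1 ``labels``."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks give ties a half credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return ROCResult(auc=float(u / (n_pos * n_neg)), n_pos=n_pos, n_neg=n_neg)


@dataclass(frozen=True)
class ModelConfig:
    """A classifier family plus its hyperparameters."""

    family: str = "lpls"  # "lpls" or "kpls"
    M: int = 3
    kernel: KernelSpec | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lpls", "kpls"):
            raise ValidationError(f"unknown model family {self.family!r}")
        if self.M < 1:
            raise ValidationError("M must be >= 1")

    @property
    def label(self) -> str:
        if self.family == "lpls":
            return "lpls"
        kernel = self.kernel if self.kernel is not None else KernelSpec()
        return f"kpls-{kernel.label}"


def fit_model(config: ModelConfig, X, y) -> PLSModel | KPLSModel:
    if config.family == "lpls":
        return train_pls(X, y, config.M)
    kernel = config.kernel if config.kernel is not None else KernelSpec()
    return train_kpls(X, y, kernel, config.M)


def predict_model(model: PLSModel | KPLSModel, X) -> np.ndarray:
    if isinstance(model, PLSModel):
        return predict_pls(model, X)
    return predict_kpls(model, X)


def stratified_fold_labels(y, k: int, rng) -> np.ndarray:
    """Assign each sample to one of k folds, stratified by class."""
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    for cls in (1, -1):
        idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float
    oof_scores: np.ndarray  # out-of-fold score per sample (NaN if skipped)
    fold_labels: np.ndarray
    scheme: str


def cross_validate(
    X,
    y,
    config: ModelConfig,
    k: int = 5,
    scheme: str = "kfold",
    seed: int = 0,
    selector=None,
) -> CVResult:
    """Cross-validated AUC of ``config`` with no training/validation leakage.

    ``selector``, if given, is called as ``selector(X_train, y_train)``
    inside every training fold and must return feature indices; this is
    the nested mode that keeps feature selection honest.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if values.shape[0] != n:
        raise ValidationError("X and y sample counts differ")
    if scheme == "loo":
        folds = np.arange(n)
        k = n
    elif scheme == "kfold":
        if k < 2:
            raise ValidationError("k must be >= 2")
        folds = stratified_fold_labels(y, k, np.random.default_rng(seed))
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")

    oof = np.full(n, np.nan)
    fold_aucs: list[float] = []
    for f in range(k):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {f}: single-class training fold skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        X_tr, X_te = values[train], values[test]
        if selector is not None:
            cols = np.asarray(selector(X_tr, y[train]))
            X_tr, X_te = X_tr[:, cols], X_te[:, cols]
        model = fit_model(config, X_tr, y[train])
        oof[test] = predict_model(model, X_te)
        if scheme == "kfold":
            if len(np.unique(y[test])) < 2:
                warnings.warn(f"fold {f}: single-class validation fold skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            fold_aucs.append(auc(oof[test], y[test]).auc)
    if scheme == "loo":
        scored = ~np.isnan(oof)
        fold_aucs = [auc(oof[scored], y[scored]).auc]
    if not fold_aucs:
        raise ValidationError("no fold produced a valid AUC")
    return CVResult(
        fold_aucs=fold_aucs, mean_auc=float(np.mean(fold_aucs)),
        oof_scores=oof, fold_labels=folds, scheme=scheme,
    )


@dataclass
class ModelSelectionReport:
    """Grid of mean validation AUCs and the chosen configuration."""

    grid: pd.DataFrame  # columns: family, M, p, mean_auc
    best_config: ModelConfig
    best_p: int | None
    best_auc: float
    feature_sets: dict = field(default_factory=dict)  # p -> retained ids
    ffs_scores: pd.DataFrame | None = None  # aggregate score per feature

    @property
    def best_features(self):
        return self.feature_sets.get(self.best_p)


def select_model(
    X,
    y,
    families: list[ModelConfig],
    M_range=range(1, 6),
    p_grid=None,
    ffs_runs: int = 1000,
    ffs_split: float = 2 / 3,
    ffs_settings: tuple[int, ...] = fr.DEFAULT_SETTINGS,
    k: int = 5,
    scheme: str = "kfold",
    seed: int = 0,
) -> ModelSelectionReport:
    """Evaluate every (family, M, p) cell by cross-validated AUC.

    ``p_grid=None`` evaluates the families on the full feature set (no FFS
    pass); otherwise one FFS score table is computed and each p retains its
    top features before cross-validation.  The chosen cell is the AUC
    argmax; ties prefer the smaller M, then the smaller p, then the family
    listed first.
    """
    if not families or not len(M_range):
        raise ValidationError("families and M_range must be non-empty")
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    ids = (X.feature_ids if isinstance(X, ExpressionMatrix)
           else [str(j) for j in range(values.shape[1])])
    seeds = np.random.SeedSequence(seed).spawn(2)
    ffs_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    cv_seed = int(seeds[1].generate_state(1)[0] % (2**31))

    feature_sets: dict = {}
    ffs_scores = None
    if p_grid is None:
        subsets = {None: np.arange(values.shape[1])}
        feature_sets[None] = list(ids)
    else:
        table_ids, totals = fr.ffs_score_table(
            values, y, ffs_runs, split_fraction=ffs_split, seed=ffs_seed,
            settings=ffs_settings,
        )
        id_pos = {f: j for j, f in enumerate(ids)}
        subsets = {}
        for p in p_grid:
            tab = fr.retain_from_scores(ids, totals, p, ffs_runs, ffs_settings)
            subsets[p] = np.array([id_pos[f] for f in tab.union])
            feature_sets[p] = tab.union
        ffs_scores = pd.DataFrame(
            {"feature_id": table_ids}
            | {f"score_{l}": totals[l] for l in ffs_settings}
        )

    rows = []
    for p, cols in subsets.items():
        Xp = values[:, cols]
        for config in families:
            for M in M_range:
                cfg = replace(config, M=M)
                cv = cross_validate(Xp, y, cfg, k=k, scheme=scheme, seed=cv_seed)
                rows.append({
                    "family": cfg.label, "M": M,
                    "p": -1 if p is None else p,
                    "mean_auc": cv.mean_auc, "config": cfg,
                })
    grid = pd.DataFrame(rows)
    # argmax AUC; ties -> smaller M, then smaller p, then family order
    order = grid.sort_values(
        by=["mean_auc", "M", "p"], ascending=[False, True, True],
        kind="stable",
    )
    best = order.iloc[0]
    best_p = None if best["p"] == -1 else int(best["p"])
    return ModelSelectionReport(
        grid=grid.drop(columns="config"),
        best_config=best["config"],
        best_p=best_p,
        best_auc=float(best["mean_auc"]),
        feature_sets=feature_sets,
        ffs_scores=ffs_scores,
    )
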
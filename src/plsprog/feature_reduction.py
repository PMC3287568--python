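"""Coarse feature reduction and fine feature selection.

Coarse Feature Reduction (CFR) is a two-stage univariate filter applied
before any model building: stage 1 keeps features whose two-sample t-test
between the two risk classes has p below a hard cutoff (0.05 by default);
stage 2 keeps, of those, features whose coefficient of variation
(sd / |mean| over all samples) is at least a cutoff (0.632 by default),
i.e. variance pruning of low-variability probes.

Fine Feature Selection (FFS) ranks the survivors by repeatedly fitting a
one-latent-variable linear PLS on random training folds and reading the
first weight vector.  In each run, for each sensitivity setting
l in {20, 30, 150}, the feature with the r-th largest |w_1| component
(r <= l) receives a positional score of l - r + 1, so the top feature in
the l = 30 setting scores 30, the runner-up 29, and everything past rank l
scores nothing.  Scores accumulate over R runs; per setting the top-p
features by aggregate score are retained and the final set is the union

    S_FFS^p = S_20^p  U  S_30^p  U  S_150^p

whose size lies between p and 3p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io_formats import ExpressionMatrix
from .pls import Standardizer

DEFAULT_SETTINGS = (20, 30, 150)


def _unpack(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ExpressionMatrix):
        return X.values, list(X.feature_ids)
    X = np.asarray(X, dtype=float)
    return X, [str(j) for j in range(X.shape[1])]


def coefficient_of_variation(values: np.ndarray) -> np.ndarray:
    """Per-feature sd / |mean|; +inf where the mean is exactly zero."""
    sd = values.std(axis=0, ddof=1)
    mean = values.mean(axis=0)
    zero = mean == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} feature(s) with zero mean; CV set to +inf",
            RuntimeWarning, stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        cv = np.where(zero, np.inf, sd / np.abs(np.where(zero, 1.0, mean)))
    return cv


def cfr_filter(
    X,
    y,
    p_cutoff: float = 0.05,
    cv_cutoff: float = 0.632,
    direction: str = "above",
    equal_var: bool = True,
) -> list[str]:
    """Two-sample t-test filter followed by coefficient-of-variation pruning.

    Parameters
    ----------
    X : ExpressionMatrix or array (n x p)
    y : +-1 class labels
    p_cutoff : hard t-test p-value cutoff (stage 1 keeps p < p_cutoff)
    cv_cutoff : coefficient-of-variation cutoff (stage 2)
    direction : "above" keeps CV >= cutoff (prune low-variability features);
        "below" keeps CV <= cutoff
    equal_var : pooled-variance Student t (default) or Welch when false

    Returns the retained feature identifiers in their original order.
    """
    values, ids = _unpack(X)
    y = np.asarray(y)
    if not 0 < p_cutoff < 1:
        raise ValidationError("p_cutoff must lie in (0, 1)")
    if direction not in ("above", "below"):
        raise ValidationError("direction must be 'above' or 'below'")
    pos, neg = values[y == 1], values[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("each class needs at least 2 samples for the t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, pvals = sps.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    stage1 = pvals < p_cutoff  # NaN p (zero-variance feature) is dropped
    cv = coefficient_of_variation(values)
    stage2 = cv >= cv_cutoff if direction == "above" else cv <= cv_cutoff
    keep = stage1 & stage2
    return [f for f, k in zip(ids, keep) if k]


def positional_scores(order: np.ndarray, setting: int, n_features: int) -> np.ndarray:
    """Scores for one run and one setting l given a ranking.

    ``order[r]`` is the feature index with the (r+1)-th largest |weight|;
    the rank-r feature (r <= l) scores l - r + 1, all others 0.
    """
    scores = np.zeros(n_features)
    top = order[: min(setting, n_features)]
    scores[top] = setting - np.arange(len(top))
    return scores


def ffs_run_scores(
    X_train_std: np.ndarray,
    y_train: np.ndarray,
    settings: tuple[int, ...] = DEFAULT_SETTINGS,
) -> dict[int, np.ndarray]:
    """Positional scores for one standardized training fold.

    The importance ranking is by decreasing magnitude of the first PLS
    weight vector w_1 = X'y (the sign carries no importance information).
    """
    X = np.asarray(X_train_std, dtype=float)
    y = np.asarray(y_train, dtype=float)
    w1 = X.T @ y  # first PLS weight vector on standardized data
    if not np.any(w1):
        raise ValidationError("degenerate fold: first weight vector is zero")
    order = np.argsort(-np.abs(w1), kind="stable")
    return {l: positional_scores(order, l, X.shape[1]) for l in settings}


@dataclass
class FeatureScoreTable:
    """Aggregate FFS scores with per-setting retained sets and their union."""

    feature_ids: list[str]
    scores: dict[int, np.ndarray]  # setting l -> aggregate score per feature
    retained: dict[int, list[str]]  # S_l^p, in original feature order
    union: list[str]  # S_FFS^p, in original feature order
    p: int
    runs: int
    settings: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        cols = {"feature_id": self.feature_ids}
        for l in self.settings:
            cols[f"score_{l}"] = self.scores[l]
        return pd.DataFrame(cols)


def retain_from_scores(
    feature_ids: list[str],
    scores: dict[int, np.ndarray],
    p: int,
    runs: int,
    settings: tuple[int, ...],
) -> FeatureScoreTable:
    """Top-p retention per setting and the union set, from aggregate scores.

    Ties are broken by original feature order (stable sort), making the
    retained sets deterministic.
    """
    n_features = len(feature_ids)
    if not 1 <= p <= n_features:
        raise ValidationError(f"p={p} outside [1, {n_features}]")
    retained: dict[int, list[str]] = {}
    union_mask = np.zeros(n_features, dtype=bool)
    for l in settings:
        order = np.argsort(-scores[l], kind="stable")
        top = np.sort(order[:p])
        retained[l] = [feature_ids[j] for j in top]
        union_mask[top] = True
    union = [f for f, m in zip(feature_ids, union_mask) if m]
    return FeatureScoreTable(
        feature_ids=list(feature_ids), scores=scores, retained=retained,
        union=union, p=p, runs=runs, settings=settings,
    )


def ffs_score_table(
    X,
    y,
    runs: int,
    split_fraction: float = 2 / 3,
    seed: int = 0,
    settings: tuple[int, ...] = DEFAULT_SETTINGS,
) -> tuple[list[str], dict[int, np.ndarray]]:
    """Aggregate positional scores over ``runs`` random stratified splits.

    Each run draws a stratified training fold of ``split_fraction`` of the
    samples, standardizes it with its own statistics, and accumulates the
    positional scores of the first PLS weight vector.
    """
    values, ids = _unpack(X)
    y = np.asarray(y, dtype=float)
    if runs < 1:
        raise ValidationError("runs must be >= 1")
    if not 0 < split_fraction < 1:
        raise ValidationError("split_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_features = values.shape[1]
    totals = {l: np.zeros(n_features) for l in settings}
    pos_idx = np.nonzero(y == 1)[0]
    neg_idx = np.nonzero(y == -1)[0]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValidationError("both classes must be present")
    for _ in range(runs):
        train = np.concatenate([
            rng.permutation(pos_idx)[: max(1, int(round(split_fraction * len(pos_idx))))],
            rng.permutation(neg_idx)[: max(1, int(round(split_fraction * len(neg_idx))))],
        ])
        stats = Standardizer.fit(values[train], y[train], warn_constant=False)
        Xs = stats.transform_x(values[train])
        ys = stats.transform_y(y[train])
        for l, s in ffs_run_scores(Xs, ys, settings).items():
            totals[l] += s
    return ids, totals


def ffs_select(
    X,
    y,
    runs: int,
    p: int,
    split_fraction: float = 2 / 3,
    seed: int = 0,
    settings: tuple[int, ...] = DEFAULT_SETTINGS,
) -> FeatureScoreTable:
    """Full fine feature selection: score over R runs, retain, and unite."""
    ids, totals = ffs_score_table(
        X, y, runs, split_fraction=split_fraction, seed=seed, settings=settings
    )
    return retain_from_scores(ids, totals, p, runs, settings)
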
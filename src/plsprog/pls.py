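"""Linear partial least squares by deflation.

The model represents predictors and response through orthonormal latent
score vectors:

    X = t_1 p_1 + t_2 p_2 + ... + t_M p_M + eps
    y = t_1 q_1 + t_2 q_2 + ... + t_M q_M + zeta

Each latent variable is extracted from the current deflated data: the
weight w_m = X_m' y_m points along the direction of maximum covariance
with the response, the score t_m = X_m w_m is normalized to unit length,
and both X and y are deflated by the rank-one component just explained
(the response is renormalized after deflation, which only rescales the
next weight).  The regression vector is the closed form

    beta = W (T' X W)^{-1} T' y

evaluated with the *original* centered X and y, which makes beta invariant
to rescaling any column of W.  Fitted values equal the orthogonal
projection of y onto the span of the scores, so at M = rank(X) the fit
coincides with ordinary least squares.

All fitting happens on standardized data; :class:`Standardizer` holds the
training statistics so that prediction accepts matrices in original units
and returns scores on the original response scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import NumericalError, RankError, ValidationError

#: A score norm below RANK_TOL * ||X||_F means deflation is exhausted.
RANK_TOL = 1e-10


@dataclass
class Standardizer:
    """Column-standardization statistics learned from a training fold.

    Training columns are transformed to mean 0 and unit standard deviation;
    constant columns get scale 1 so they map to exactly zero.  Other folds
    must be transformed with these same statistics (no leakage).
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float = 0.0
    y_scale: float = 1.0
    constant_columns: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @classmethod
    def fit(cls, X, y=None, warn_constant: bool = True) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0, ddof=0)
        constant = x_scale == 0.0
        if constant.any() and warn_constant:
            warnings.warn(
                f"{int(constant.sum())} constant column(s); scale set to 1",
                RuntimeWarning, stacklevel=2,
            )
        x_scale = np.where(constant, 1.0, x_scale)
        y_mean, y_scale = 0.0, 1.0
        if y is not None:
            y = np.asarray(y, dtype=float)
            y_mean = float(y.mean())
            sd = float(y.std(ddof=0))
            y_scale = sd if sd > 0 else 1.0
        return cls(x_mean, x_scale, y_mean, y_scale, constant)

    def transform_x(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.x_mean.shape[0]:
            raise ValidationError(
                f"expected {self.x_mean.shape[0]} features, got {X.shape[1]}"
            )
        return (X - self.x_mean) / self.x_scale

    def transform_y(self, y) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_scale

    def inverse_y(self, scores) -> np.ndarray:
        return np.asarray(scores, dtype=float) * self.y_scale + self.y_mean

    @classmethod
    def identity(cls, p: int) -> "Standardizer":
        return cls(np.zeros(p), np.ones(p))


def normalize(X_train, y_train=None, *X_other, warn_constant: bool = True):
    """Standardize a training fold and transform companions with its stats.

    Returns ``(X_std, y_std, stats)`` followed by one standardized copy of
    each extra matrix, all computed with the training statistics only.
    """
    stats = Standardizer.fit(X_train, y_train, warn_constant=warn_constant)
    out = [stats.transform_x(X_train),
           stats.transform_y(y_train) if y_train is not None else None,
           stats]
    out.extend(stats.transform_x(Xo) for Xo in X_other)
    return tuple(out)


@dataclass
class PLSModel:
    """Fitted linear PLS model.

    W (p x M) holds the weight vectors, T (n x M) the orthonormal training
    scores, P (M x p) and q (M,) the loadings (diagnostics only; beta does
    not use them), beta the regression vector on the standardized scale.
    x_residual / y_residual are the unexplained remainders after M
    deflations.
    """

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    beta: np.ndarray
    M: int
    stats: Standardizer
    fitted: np.ndarray
    y_residual: np.ndarray
    x_residual: np.ndarray

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    def to_dict(self) -> dict:
        return {
            "format": "plsprog-pls-model-v1",
            "M": self.M,
            "beta": self.beta.tolist(),
            "W": self.W.tolist(),
            "x_mean": self.stats.x_mean.tolist(),
            "x_scale": self.stats.x_scale.tolist(),
            "y_mean": self.stats.y_mean,
            "y_scale": self.stats.y_scale,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def fit_pls(X, y, M: int, stats: Standardizer | None = None) -> PLSModel:
    """Fit PLS on pre-standardized data (see :func:`normalize`).

    ``X`` must be column-centered/scaled and ``y`` centered; ``stats`` are
    attached to the model so :func:`predict_pls` can accept original units
    (identity statistics are assumed when omitted).
    """
    X = np.array(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel().copy()
    n, p = X.shape
    if len(y) != n:
        raise ValidationError("X and y sample counts differ")
    if not 1 <= M <= min(n - 1, p):
        raise ValidationError(f"M={M} outside [1, min(n-1, p)={min(n - 1, p)}]")
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        raise RankError("X is identically zero")

    W = np.empty((p, M))
    T = np.empty((n, M))
    P = np.empty((M, p))
    q = np.empty(M)
    Xm, ym = X.copy(), y.copy()
    for m in range(M):
        w = Xm.T @ ym
        t = Xm @ w
        t_norm = np.linalg.norm(t)
        if t_norm < RANK_TOL * norm_x:
            raise RankError(
                f"deflation exhausted at latent variable {m + 1}: "
                f"score norm {t_norm:.3e}"
            )
        t /= t_norm
        p_row = t @ Xm
        q_m = float(t @ ym)
        Xm -= np.outer(t, p_row)
        ym = ym - t * q_m
        y_norm = np.linalg.norm(ym)
        if y_norm > 0:
            ym = ym / y_norm
        W[:, m], T[:, m], P[m], q[m] = w, t, p_row, q_m

    A = T.T @ (X @ W)
    try:
        beta = W @ linalg.solve(A, T.T @ y)
    except linalg.LinAlgError as exc:
        raise NumericalError(f"singular T'XW system: {exc}") from exc
    if not np.all(np.isfinite(beta)):
        raise NumericalError("non-finite regression coefficients")
    fitted = X @ beta
    return PLSModel(
        W=W, T=T, P=P, q=q, beta=beta, M=M,
        stats=stats if stats is not None else Standardizer.identity(p),
        fitted=fitted, y_residual=y - fitted, x_residual=Xm,
    )


def predict_pls(model: PLSModel, X_new) -> np.ndarray:
    """Score new samples given in original units; higher = higher risk."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValidationError(
            f"expected {model.n_features} features, got {X_new.shape[1]}"
        )
    return model.stats.inverse_y(model.stats.transform_x(X_new) @ model.beta)


def train_pls(X, y, M: int, warn_constant: bool = False) -> PLSModel:
    """Standardize ``X``/``y`` and fit; the one-call training entry point."""
    Xs, ys, stats = normalize(X, y, warn_constant=warn_constant)
    return fit_pls(Xs, ys, M, stats=stats)
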
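"""Kernelized partial least squares in the dual.

The training algorithm mirrors linear PLS but operates on the centered
Gram matrix K1 and a response standardized to mean 0, sd 1: at each step
the score is t_m = K_m y_m (normalized), the kernel is deflated on both
sides, K_{m+1} = (I - t_m t_m') K_m (I - t_m t_m'), and the response is
deflated and renormalized.  Collecting the pre-deflation responses as the
columns of U, the dual coefficients are

    a = U (T' K1 U)^{-1} T' y

so that predictions are kernel sums over the training samples,

    f(x) = sum_i K1(x_i, x) a_i,

with the test kernel row centered by the training statistics.  With the
plain dot-product kernel this reproduces linear PLS exactly (the degree-1
polynomial/linear equivalence), which pins down the coefficient formula
and is enforced in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import NumericalError, RankError, ValidationError
from .kernels import GramCenterer, KernelSpec, center_cross, center_gram, gram_matrix
from .pls import Standardizer, normalize


@dataclass
class KPLSFit:
    """Dual-side quantities from the core fit (standardized scale)."""

    a: np.ndarray  # n-vector of dual coefficients
    T: np.ndarray  # n x M orthonormal scores
    U: np.ndarray  # n x M pre-deflation response columns
    fitted: np.ndarray


def fit_kpls(K1, y, M: int) -> KPLSFit:
    """Core dual fit on a centered train kernel and standardized response."""
    K1 = np.asarray(K1, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = K1.shape[0]
    if K1.shape != (n, n):
        raise ValidationError("K1 must be square")
    if len(y) != n:
        raise ValidationError("response length does not match kernel size")
    if not 1 <= M <= n - 1:
        raise ValidationError(f"M={M} outside [1, n-1={n - 1}]")
    norm_k = np.linalg.norm(K1)
    if norm_k == 0:
        raise RankError("centered kernel is identically zero")

    T = np.empty((n, M))
    U = np.empty((n, M))
    Km, ym = K1.copy(), y.copy()
    for m in range(M):
        U[:, m] = ym
        t = Km @ ym
        t_norm = np.linalg.norm(t)
        if t_norm < 1e-10 * norm_k:
            raise RankError(
                f"deflation exhausted at latent variable {m + 1}: "
                f"score norm {t_norm:.3e}"
            )
        t /= t_norm
        # K_{m+1} = (I - t t') K_m (I - t t')
        Km = Km - np.outer(t, t @ Km)
        Km = Km - np.outer(Km @ t, t)
        ym = ym - t * float(t @ ym)
        y_norm = np.linalg.norm(ym)
        if y_norm > 0:
            ym = ym / y_norm
        T[:, m] = t

    A = T.T @ (K1 @ U)
    try:
        a = U @ linalg.solve(A, T.T @ y)
    except linalg.LinAlgError as exc:
        raise NumericalError(f"singular T'K1U system: {exc}") from exc
    if not np.all(np.isfinite(a)):
        raise NumericalError("non-finite dual coefficients")
    return KPLSFit(a=a, T=T, U=U, fitted=K1 @ a)


@dataclass
class KPLSModel:
    """Fitted kernel PLS model, carrying everything prediction needs:
    the kernel spec, dual coefficients, stored (standardized) training
    rows, kernel-centering statistics, and the response normalization."""

    spec: KernelSpec
    M: int
    a: np.ndarray
    T: np.ndarray
    U: np.ndarray
    stats: Standardizer
    centerer: GramCenterer
    X_train_std: np.ndarray
    fitted_std: np.ndarray

    @property
    def n_features(self) -> int:
        return self.X_train_std.shape[1]

    def to_dict(self) -> dict:
        return {
            "format": "plsprog-kpls-model-v1",
            "kernel": {
                "family": self.spec.family,
                "degree": int(self.spec.degree),
                "sigma": self.spec.sigma,
            },
            "M": self.M,
            "a": self.a.tolist(),
            "X_train_std": self.X_train_std.tolist(),
            "kernel_col_means": self.centerer.col_means.tolist(),
            "kernel_grand_mean": self.centerer.grand_mean,
            "x_mean": self.stats.x_mean.tolist(),
            "x_scale": self.stats.x_scale.tolist(),
            "y_mean": self.stats.y_mean,
            "y_scale": self.stats.y_scale,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def train_kpls(
    X, y, spec: KernelSpec, M: int, warn_constant: bool = False
) -> KPLSModel:
    """Standardize, build and center the Gram matrix, and fit the dual."""
    Xs, ys, stats = normalize(X, y, warn_constant=warn_constant)
    K0 = gram_matrix(spec, Xs)
    K1, centerer = center_gram(K0)
    core = fit_kpls(K1, ys, M)
    return KPLSModel(
        spec=spec, M=M, a=core.a, T=core.T, U=core.U, stats=stats,
        centerer=centerer, X_train_std=Xs, fitted_std=core.fitted,
    )


def predict_kpls(model: KPLSModel, X_new) -> np.ndarray:
    """Score new samples in original units via the centered test kernel."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValidationError(
            f"expected {model.n_features} features, got {X_new.shape[1]}"
        )
    Xs = model.stats.transform_x(X_new)
    K_cross = gram_matrix(model.spec, Xs, model.X_train_std)
    K1_cross = center_cross(K_cross, model.centerer)
    return model.stats.inverse_y(K1_cross @ model.a)
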
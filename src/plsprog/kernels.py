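"""Kernel functions, Gram matrices, and empirical feature-space centering.

Four kernel families are supported, all expressing similarity either
through the angle between inputs or their Euclidean distance:

* ``dot``              K(u, v) = u . v
* ``polynomial``       K(u, v) = (u . v + 1)^d   on unit-normalized inputs,
                       so outputs lie in [0, 2^d]
* ``gaussian_rbf``     K(u, v) = exp(-||u - v||^2 / (2 sigma^2))
* ``exponential_rbf``  K(u, v) = exp(-||u - v|| / (2 sigma^2))

The exponential RBF divides the *unsquared* distance by 2 sigma^2; this is
an unusual scaling but it is the form this package standardizes on, so
sigma is not interchangeable with the common exp(-d / sigma)
parameterization.

Centering maps the Gram matrix to the one induced by mean-centered feature
maps: K1 = H K0 H with H = I - 11'/n.  A test-vs-train block is centered
with the *training* row means and grand mean, which is the exact analogue
of transforming validation data with training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError

FAMILIES = ("dot", "polynomial", "gaussian_rbf", "exponential_rbf")

#: Tolerance for the unit-norm requirement of the polynomial kernel.
UNIT_NORM_TOL = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its parameter (degree d or width sigma).

    ``normalize`` controls the polynomial family's unit-norm requirement:
    inputs are rescaled to unit length when true (the default), or rejected
    when false and not already unit length.
    """

    family: str = "gaussian_rbf"
    degree: int = 3
    sigma: float = 1.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown kernel family {self.family!r}")
        if self.family == "polynomial" and (
            self.degree < 1 or int(self.degree) != self.degree
        ):
            raise ValidationError("polynomial degree must be a positive integer")
        if self.family.endswith("_rbf") and self.sigma <= 0:
            raise ValidationError("sigma must be positive")

    @property
    def label(self) -> str:
        if self.family == "polynomial":
            return f"polynomial(d={int(self.degree)})"
        if self.family.endswith("_rbf"):
            return f"{self.family}(sigma={self.sigma:g})"
        return self.family


def _unit_rows(X: np.ndarray, strict: bool) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    if strict:
        if np.any(np.abs(norms - 1.0) > UNIT_NORM_TOL):
            raise ValidationError(
                "polynomial kernel requires unit-norm inputs "
                "(or normalize=True on the KernelSpec)"
            )
        return X
    safe = np.where(norms == 0.0, 1.0, norms)
    return X / safe[:, None]


def gram_matrix(spec: KernelSpec, X, Y=None) -> np.ndarray:
    """Pairwise kernel evaluations; rows of ``X`` against rows of ``Y``.

    With ``Y`` omitted this is the training Gram matrix K0 (symmetric).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    symmetric = Y is None
    Y = X if symmetric else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValidationError(
            f"feature counts differ: {X.shape[1]} vs {Y.shape[1]}"
        )
    if spec.family == "dot":
        K = X @ Y.T
    elif spec.family == "polynomial":
        Xu = _unit_rows(X, strict=not spec.normalize)
        Yu = Xu if symmetric else _unit_rows(Y, strict=not spec.normalize)
        K = (Xu @ Yu.T + 1.0) ** int(spec.degree)
    elif spec.family == "gaussian_rbf":
        d2 = cdist(X, Y, "sqeuclidean")
        K = np.exp(-d2 / (2.0 * spec.sigma**2))
    else:  # exponential_rbf: unsquared distance over 2 sigma^2
        d = cdist(X, Y, "euclidean")
        K = np.exp(-d / (2.0 * spec.sigma**2))
    if symmetric:
        K = (K + K.T) / 2.0  # enforce exact symmetry against rounding
    return K


def kernel_eval(spec: KernelSpec, u, v) -> float:
    """Evaluate the kernel on a single pair of equal-length vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValidationError(f"length mismatch: {u.shape[0]} vs {v.shape[0]}")
    return float(gram_matrix(spec, u[None, :], v[None, :])[0, 0])


@dataclass
class GramCenterer:
    """Training statistics needed to center test kernel blocks."""

    col_means: np.ndarray  # mean over training rows of K0, per training column
    grand_mean: float

    @property
    def n_train(self) -> int:
        return self.col_means.shape[0]


def center_gram(K0) -> tuple[np.ndarray, GramCenterer]:
    """Double-center a square training Gram matrix: K1 = H K0 H."""
    K0 = np.asarray(K0, dtype=float)
    if K0.ndim != 2 or K0.shape[0] != K0.shape[1]:
        raise ValidationError("training Gram matrix must be square")
    col_means = K0.mean(axis=0)
    row_means = K0.mean(axis=1)
    grand = float(K0.mean())
    K1 = K0 - row_means[:, None] - col_means[None, :] + grand
    return K1, GramCenterer(col_means=col_means, grand_mean=grand)


def center_cross(K_cross, stats: GramCenterer) -> np.ndarray:
    """Center a test x train kernel block with training statistics."""
    K_cross = np.asarray(K_cross, dtype=float)
    if K_cross.ndim != 2 or K_cross.shape[1] != stats.n_train:
        raise ValidationError(
            f"cross-kernel block must have {stats.n_train} training columns"
        )
    return (
        K_cross
        - K_cross.mean(axis=1, keepdims=True)
        - stats.col_means[None, :]
        + stats.grand_mean
    )


def with_params(spec: KernelSpec, **kwargs) -> KernelSpec:
    """Return a copy of ``spec`` with fields replaced."""
    return replace(spec, **kwargs)
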
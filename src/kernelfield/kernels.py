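"""Kernel functions and kernel (Gram) matrices.

Four classical Mercer-style kernels are provided:

* linear        ``K(x, y) = <x, y> + theta``
* polynomial    ``K(x, y) = (<x, y> + theta) ** d``
* rbf           ``K(x, y) = exp(-||x - y||^2 / sigma^2)``
* sigmoid       ``K(x, y) = tanh(v <x, y> + r)``

Note the RBF form divides the squared distance by ``sigma**2`` with no
factor of two; this differs from the ``2 * sigma**2`` convention used by
e.g. scikit-learn's ``gamma = 1 / (2 * sigma**2)`` parameterisation, and is
kept deliberately because the projection models downstream are calibrated
against it.

The sigmoid kernel is not positive semi-definite for every ``(v, r)``; a
non-PSD sigmoid Gram matrix is let through with a logged warning rather
than rejected, since the eigendecomposition downstream simply discards the
negative part of the spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

KERNEL_NAMES = ("linear", "polynomial", "rbf", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """Which kernel to use and its hyperparameters.

    Only the fields relevant to ``name`` are ever read: ``theta`` for linear
    and polynomial, ``degree`` for polynomial, ``sigma`` for rbf, ``v`` and
    ``r`` for sigmoid.
    """

    name: str
    theta: float = 0.0
    degree: int = 2
    sigma: float = 1.0
    v: float = 1.0
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; expected one of {KERNEL_NAMES}")
        if self.name == "rbf" and not self.sigma > 0:
            raise ValueError(f"rbf kernel requires sigma > 0, got {self.sigma}")
        if self.name == "polynomial":
            if int(self.degree) != self.degree or self.degree < 1:
                raise ValueError(f"polynomial kernel requires integer degree >= 1, got {self.degree}")

    @property
    def relevant_params(self) -> dict:
        """The hyperparameters actually read for this kernel."""
        if self.name == "linear":
            return {"theta": self.theta}
        if self.name == "polynomial":
            return {"theta": self.theta, "degree": self.degree}
        if self.name == "rbf":
            return {"sigma": self.sigma}
        return {"v": self.v, "r": self.r}

    def to_dict(self) -> dict:
        return {"name": self.name, **self.relevant_params}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        known = {"name", "theta", "degree", "sigma", "v", "r"}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown kernel fields: {sorted(extra)}")
        return cls(**d)


@dataclass
class KernelMatrix:
    """An n x m kernel matrix with optional sample identifiers."""

    values: np.ndarray
    row_ids: Optional[tuple] = None
    col_ids: Optional[tuple] = None
    centered: bool = False

    @property
    def shape(self) -> tuple:
        return self.values.shape


def _as_matrix(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def kernel_eval(spec: KernelSpec, x: Sequence[float], y: Sequence[float]) -> float:
    """Evaluate the kernel on a single pair of vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"dimension mismatch: len(x)={x.shape[0]} vs len(y)={y.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("kernel_eval requires finite inputs")
    if spec.name == "linear":
        return float(x @ y + spec.theta)
    if spec.name == "polynomial":
        return float((x @ y + spec.theta) ** spec.degree)
    if spec.name == "rbf":
        d2 = float(np.sum((x - y) ** 2))
        return float(np.exp(-d2 / spec.sigma**2))
    return float(np.tanh(spec.v * (x @ y) + spec.r))


def kernel_matrix(
    spec: KernelSpec,
    X,
    Y=None,
    row_ids: Optional[Sequence] = None,
    col_ids: Optional[Sequence] = None,
) -> KernelMatrix:
    """Build the kernel matrix between the rows of X and the rows of Y.

    With ``Y=None`` the self-kernel ``K(X, X)`` is built. Entry (i, j)
    equals ``kernel_eval(spec, X[i], Y[j])``.
    """
    X = _as_matrix(X, "X")
    self_kernel = Y is None
    Y = X if self_kernel else _as_matrix(Y, "Y")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"column count mismatch: X has {X.shape[1]}, Y has {Y.shape[1]}")

    if spec.name == "rbf":
        d2 = cdist(X, Y, metric="sqeuclidean")
        V = np.exp(-d2 / spec.sigma**2)
    else:
        G = X @ Y.T
        if spec.name == "linear":
            V = G + spec.theta
        elif spec.name == "polynomial":
            V = (G + spec.theta) ** spec.degree
        else:
            V = np.tanh(spec.v * G + spec.r)

    if self_kernel:
        # enforce exact symmetry against rounding in the BLAS product
        V = (V + V.T) / 2.0
        if spec.name == "sigmoid" and V.shape[0] > 1:
            w = np.linalg.eigvalsh(V)
            if w[0] < -1e-8 * max(w[-1], 1.0):
                logger.warning(
                    "sigmoid kernel matrix is not PSD (min eigenvalue %.3g); "
                    "negative spectrum will be discarded by the projection step",
                    w[0],
                )
    row_ids = tuple(row_ids) if row_ids is not None else None
    if col_ids is not None:
        col_ids = tuple(col_ids)
    elif self_kernel:
        col_ids = row_ids
    return KernelMatrix(values=V, row_ids=row_ids, col_ids=col_ids, centered=False)


def center_kernel(K_train: KernelMatrix, K_test: Optional[KernelMatrix] = None) -> KernelMatrix:
    """Centre a kernel matrix in feature space.

    Training form: ``Kc = K - 1n K - K 1n + 1n K 1n`` with ``1n`` the n x n
    matrix of 1/n entries, i.e. the Gram matrix of the mean-subtracted
    mapped data. When ``K_test`` (an m x n cross-kernel against the same
    training samples) is given, the corresponding test-centering formula is
    applied and the centered test matrix is returned.
    """
    if K_train.centered:
        raise ValueError("K_train is already centered")
    K = K_train.values
    if K.shape[0] != K.shape[1]:
        raise ValueError(f"K_train must be square, got shape {K.shape}")
    n = K.shape[0]
    col_means = K.mean(axis=0)          # (n,)
    total_mean = float(K.mean())

    if K_test is None:
        Kc = K - col_means[None, :] - col_means[:, None] + total_mean
        return KernelMatrix(values=Kc, row_ids=K_train.row_ids, col_ids=K_train.col_ids, centered=True)

    if K_test.centered:
        raise ValueError("K_test is already centered")
    if K_train.col_ids is not None and K_test.col_ids is not None and K_test.col_ids != K_train.col_ids:
        raise ValueError("K_test columns must index the same training samples as K_train")
    Kt = K_test.values
    if Kt.shape[1] != n:
        raise ValueError(f"K_test has {Kt.shape[1]} columns but K_train is {n} x {n}")
    Ktc = Kt - Kt.mean(axis=1, keepdims=True) - col_means[None, :] + total_mean
    return KernelMatrix(values=Ktc, row_ids=K_test.row_ids, col_ids=K_test.col_ids, centered=True)
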
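"""Kernel PCA and kernel generalized discriminant analysis (GDA).

Both methods project samples into a k-dimensional (default 3) kernel space
without ever forming the mapped features explicitly: every projection
direction ``v`` in feature space is expanded over the mapped training
samples, ``v = sum_i alpha_i Phi(x_i)``, and only kernel evaluations are
needed to fit the dual coefficients ``alpha`` and to project new points.

Kernel PCA solves ``lambda alpha = (1/n) K alpha`` on the (by default
centered) kernel matrix and keeps the top-k eigenpairs. With a linear
kernel (theta=0) and centering this reduces exactly to classical PCA.

Kernel GDA maximizes the Fisher ratio

    lambda = (alpha^T K D K alpha) / (alpha^T K K alpha)

with ``D`` the block-diagonal matrix of ``1/n_c`` blocks (one block per
class), using the uncentered kernel matrix. ``alpha^T K K alpha`` is
singular whenever K is rank-deficient, so the problem is solved in the
eigenbasis of K: eigendecompose ``K = P Gamma P^T``, discard eigenvalues
below ``1e-10 * max``, solve the reduced symmetric eigenproblem
``P^T D P`` and map the eigenvectors back to dual coefficients. At most
C - 1 discriminants are retained for C classes.

In both models each retained direction is scaled to unit feature-space
norm (``alpha^T K alpha = 1``) and its sign fixed so the largest-magnitude
dual coefficient is positive, making repeated fits bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from kernelfield.kernels import KernelSpec, kernel_matrix, center_kernel, KernelMatrix

#: relative eigenvalue cutoff below which kernel-matrix directions are
#: treated as numerically null
EIG_RTOL = 1e-10


@dataclass
class ProjectedPoints:
    """Coordinates of samples in the fitted kernel space."""

    coords: np.ndarray
    ids: Optional[tuple] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("projected coordinates contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class ProjectionModel:
    """A fitted KPCA or GDA projection.

    ``dual_coeffs`` holds one column of alpha per retained direction;
    ``eigenvalues`` are the corresponding (descending, positive)
    eigenvalues — for KPCA the eigenvalues of (1/n) Kc, for GDA the Fisher
    ratios of the discriminants.
    """

    method: str
    spec: KernelSpec
    X_train: np.ndarray
    dual_coeffs: np.ndarray
    eigenvalues: np.ndarray
    k: int
    centered: bool
    train_scores: np.ndarray
    train_col_means: Optional[np.ndarray] = None  # centering stats (KPCA)
    train_total_mean: Optional[float] = None
    labels: Optional[np.ndarray] = None           # GDA only
    class_sizes: Optional[dict] = None            # GDA only
    ids: Optional[tuple] = None


def _fix_signs(alpha: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(alpha), axis=0)
    signs = np.sign(alpha[idx, np.arange(alpha.shape[1])])
    signs[signs == 0] = 1.0
    return alpha * signs


def fit_kpca(X, spec: KernelSpec, k: int = 3, center: bool = True,
             ids: Optional[Sequence] = None) -> ProjectionModel:
    """Fit kernel PCA, retaining the top-k kernel principal components."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")

    Km = kernel_matrix(spec, X)
    Kc = center_kernel(Km).values if center else Km.values

    gamma, U = scipy.linalg.eigh(Kc)           # ascending
    gamma, U = gamma[::-1], U[:, ::-1]         # descending
    pos = gamma > EIG_RTOL * max(gamma[0], 0.0) if gamma[0] > 0 else np.zeros_like(gamma, bool)
    n_pos = int(pos.sum())
    if k > n_pos:
        raise ValueError(
            f"requested k={k} components but the kernel matrix has only "
            f"{n_pos} positive eigenvalue(s)"
        )
    gamma, U = gamma[:k], U[:, :k]
    # unit feature-space norm: alpha^T Kc alpha = 1  =>  alpha = u / sqrt(gamma)
    alpha = _fix_signs(U / np.sqrt(gamma)[None, :])
    scores = Kc @ alpha

    model = ProjectionModel(
        method="kpca",
        spec=spec,
        X_train=X.copy(),
        dual_coeffs=alpha,
        eigenvalues=gamma / n,                 # eigenvalues of (1/n) Kc
        k=k,
        centered=center,
        train_scores=scores,
        ids=tuple(ids) if ids is not None else None,
    )
    if center:
        Kraw = Km.values
        model.train_col_means = Kraw.mean(axis=0)
        model.train_total_mean = float(Kraw.mean())
    return model


def fit_gda(X, labels, spec: KernelSpec, k: int = 3,
            ids: Optional[Sequence] = None) -> ProjectionModel:
    """Fit kernel GDA, retaining the top-k discriminant directions."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = X.shape[0]
    if labels.shape[0] != n:
        raise ValueError(f"{n} samples but {labels.shape[0]} labels")
    classes, counts = np.unique(labels, return_counts=True)
    C = len(classes)
    if C < 2:
        raise ValueError(f"GDA needs at least 2 classes, got {C}")
    singleton = classes[counts < 2]
    if singleton.size:
        raise ValueError(f"class {int(singleton[0])} has a single member; GDA needs >= 2 per class")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > C - 1:
        raise ValueError(f"k={k} exceeds C-1={C - 1} available discriminants for {C} classes")

    K = kernel_matrix(spec, X).values
    gamma, P = scipy.linalg.eigh(K)
    gamma, P = gamma[::-1], P[:, ::-1]
    keep = gamma > EIG_RTOL * max(gamma[0], 0.0) if gamma[0] > 0 else np.zeros_like(gamma, bool)
    if not keep.any():
        raise ValueError("kernel matrix is numerically zero; cannot fit GDA")
    gamma, P = gamma[keep], P[:, keep]

    # D = A A^T with A the normalised class-indicator matrix (n x C)
    A = np.zeros((n, C))
    for j, (c, m) in enumerate(zip(classes, counts)):
        A[labels == c, j] = 1.0 / np.sqrt(m)
    PA = P.T @ A                               # r x C
    S = PA @ PA.T                              # reduced P^T D P, symmetric PSD
    mu, B = scipy.linalg.eigh(S)
    mu, B = mu[::-1], B[:, ::-1]
    n_pos = int(np.sum(mu > 1e-12))
    if k > n_pos:
        raise ValueError(
            f"requested k={k} discriminants but only {n_pos} have a positive Fisher ratio"
        )
    mu, B = mu[:k], B[:, :k]

    alpha = P @ (B / gamma[:, None])           # map back: alpha = P Gamma^-1 beta
    norms = np.sqrt(np.sum(B**2 / gamma[:, None], axis=0))  # alpha^T K alpha = beta^T Gamma^-1 beta
    alpha = _fix_signs(alpha / norms[None, :])
    scores = K @ alpha

    return ProjectionModel(
        method="gda",
        spec=spec,
        X_train=X.copy(),
        dual_coeffs=alpha,
        eigenvalues=mu,                        # Fisher ratios, descending
        k=k,
        centered=False,
        train_scores=scores,
        labels=labels.copy(),
        class_sizes={int(c): int(m) for c, m in zip(classes, counts)},
        ids=tuple(ids) if ids is not None else None,
    )


def transform(model: ProjectionModel, X_new, ids: Optional[Sequence] = None) -> ProjectedPoints:
    """Project new samples into the fitted kernel space."""
    X_new = np.asarray(X_new, dtype=float)
    one_row = X_new.ndim == 1
    if one_row:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature count mismatch: model fitted on {model.X_train.shape[1]} "
            f"columns, got {X_new.shape[1]}"
        )
    Kt = kernel_matrix(model.spec, X_new, model.X_train).values
    if model.centered:
        Kt = (
            Kt
            - Kt.mean(axis=1, keepdims=True)
            - model.train_col_means[None, :]
            + model.train_total_mean
        )
    coords = Kt @ model.dual_coeffs
    return ProjectedPoints(coords=coords, ids=tuple(ids) if ids is not None else None)


def fisher_ratio(model: ProjectionModel, component: int = 0) -> float:
    """Recompute the Fisher ratio alpha^T K D K alpha / alpha^T K K alpha of a GDA direction."""
    if model.method != "gda":
        raise ValueError("fisher_ratio is defined for GDA models only")
    K = kernel_matrix(model.spec, model.X_train).values
    a = model.dual_coeffs[:, component]
    y = K @ a
    classes, counts = np.unique(model.labels, return_counts=True)
    num = sum((y[model.labels == c].sum() ** 2) / m for c, m in zip(classes, counts))
    return float(num / (y @ y))


def export_coordinates_tsv(path, points: ProjectedPoints) -> None:
    """Write projected coordinates as TSV: id, dim1..dimk[, label]."""
    import pandas as pd

    k = points.k
    cols = {f"dim{j + 1}": points.coords[:, j] for j in range(k)}
    ids = points.ids or tuple(f"s{i}" for i in range(points.coords.shape[0]))
    df = pd.DataFrame({"id": list(ids), **cols})
    if points.labels is not None:
        df["label"] = points.labels
    df.to_csv(path, sep="\t", index=False)
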
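"""Classification of projected points: KNN vote or class-intensity field.

The class-intensity model treats every projected training sample as a point
charge. Each sample of class C carries the Electric Quantity of Point
Charge

    EQPC_C = 1 / n_C,

so a class's total charge is 1 regardless of its size. By analogy with
Coulomb's law, the Intensity of Electric Field of one Point (IEFP) that a
class exerts at a query location is the inverse-square-distance-weighted
sum of its charges,

    IEFP_C = sum_{i in class C} EQPC_C / r_i^2,

with ``r_i`` the Euclidean distance from the query to training point i in
the projected space. The predicted class maximises IEFP.

The inverse-square law diverges as a query approaches a training point; a
query within ``epsilon_coincide`` of a training point is therefore assigned
that point's class directly, which matches the divergence's limit and keeps
leave-one-out evaluation well defined. IEFP ties (and KNN vote ties, after
the summed-distance rule) are broken deterministically towards the lowest
class index, with a log message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from kernelfield.projection import ProjectedPoints

logger = logging.getLogger(__name__)

DEFAULT_EPSILON_COINCIDE = 1e-12


class CoincidentQueryError(ValueError):
    """Raised by :func:`iefp` when the query touches a training point."""

    def __init__(self, label: int, index: int):
        self.label = int(label)
        self.index = int(index)
        super().__init__(
            f"query coincides with training point {index} (class {label}); IEFP diverges"
        )


@dataclass(frozen=True)
class DecisionRule:
    """How to classify a projected point: ``knn`` vote or ``intensity`` field."""

    method: str
    K: int = 3
    epsilon_coincide: float = DEFAULT_EPSILON_COINCIDE

    def __post_init__(self) -> None:
        if self.method not in ("knn", "intensity"):
            raise ValueError(f"unknown decision rule {self.method!r}")
        if self.method == "knn" and self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")

    def to_dict(self) -> dict:
        if self.method == "knn":
            return {"method": "knn", "K": self.K}
        return {"method": "intensity", "epsilon_coincide": self.epsilon_coincide}

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionRule":
        return cls(**d)


@dataclass
class ChargeField:
    """Projected training points with per-class charges (the classifier state)."""

    points: np.ndarray
    labels: np.ndarray
    eqpc_by_class: dict
    n_by_class: dict

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def classes(self) -> list:
        return sorted(self.n_by_class)


def _coords_labels(train, labels=None):
    if isinstance(train, ProjectedPoints):
        pts = train.coords
        if labels is None:
            labels = train.labels
    else:
        pts = np.asarray(train, dtype=float)
    if labels is None:
        raise ValueError("labels are required (either on ProjectedPoints or passed explicitly)")
    labels = np.asarray(labels, dtype=int)
    if pts.shape[0] != labels.shape[0]:
        raise ValueError(f"{pts.shape[0]} points but {labels.shape[0]} labels")
    if pts.shape[0] == 0:
        raise ValueError("empty training set")
    return pts, labels


def knn_predict(train, labels, query, K: int) -> int:
    """Majority vote among the K nearest projected training points.

    Ties are broken by the smallest summed distance among the tied classes'
    neighbours, then by the lowest class index.
    """
    pts, labels = _coords_labels(train, labels)
    if K < 1 or K > pts.shape[0]:
        raise ValueError(f"K={K} out of range for training size {pts.shape[0]}")
    query = np.asarray(query, dtype=float).ravel()
    d = np.sqrt(np.sum((pts - query[None, :]) ** 2, axis=1))
    nearest = np.argsort(d, kind="stable")[:K]
    nn_labels = labels[nearest]
    nn_d = d[nearest]

    votes: dict[int, int] = {}
    sums: dict[int, float] = {}
    for lab, dist in zip(nn_labels, nn_d):
        lab = int(lab)
        votes[lab] = votes.get(lab, 0) + 1
        sums[lab] = sums.get(lab, 0.0) + float(dist)
    best = max(votes.values())
    tied = [c for c, v in votes.items() if v == best]
    if len(tied) > 1:
        min_sum = min(sums[c] for c in tied)
        tied = [c for c in tied if sums[c] == min_sum]
        if len(tied) > 1:
            logger.info("KNN tie among classes %s; choosing lowest index", sorted(tied))
    return min(tied)


def build_charge_field(train, labels=None) -> ChargeField:
    """Assign each class its EQPC = 1/n_C and store the projected points."""
    pts, labels = _coords_labels(train, labels)
    classes, counts = np.unique(labels, return_counts=True)
    n_by_class = {int(c): int(m) for c, m in zip(classes, counts)}
    eqpc = {c: 1.0 / m for c, m in n_by_class.items()}
    return ChargeField(points=pts, labels=labels, eqpc_by_class=eqpc, n_by_class=n_by_class)


def iefp(field: ChargeField, query, c: int,
         epsilon_coincide: float = DEFAULT_EPSILON_COINCIDE) -> float:
    """Intensity of the class-c field at the query point (inverse-square sum)."""
    c = int(c)
    if c not in field.n_by_class:
        raise ValueError(f"unknown class {c}; field has classes {field.classes}")
    query = np.asarray(query, dtype=float).ravel()
    mask = field.labels == c
    d2 = np.sum((field.points[mask] - query[None, :]) ** 2, axis=1)
    hit = np.flatnonzero(np.sqrt(d2) < epsilon_coincide)
    if hit.size:
        idx = int(np.flatnonzero(mask)[hit[0]])
        raise CoincidentQueryError(label=c, index=idx)
    return float(np.sum(field.eqpc_by_class[c] / d2))


def intensity_predict(field: ChargeField, query,
                      epsilon_coincide: float = DEFAULT_EPSILON_COINCIDE) -> int:
    """Class with maximal IEFP at the query; coincident queries inherit the touched point's class."""
    if field.points.shape[0] == 0:
        raise ValueError("empty charge field")
    query = np.asarray(query, dtype=float).ravel()
    d = np.sqrt(np.sum((field.points - query[None, :]) ** 2, axis=1))
    nearest = int(np.argmin(d))
    if d[nearest] < epsilon_coincide:
        return int(field.labels[nearest])
    scores = {c: iefp(field, query, c, epsilon_coincide) for c in field.classes}
    best = max(scores.values())
    tied = sorted(c for c, s in scores.items() if s == best)
    if len(tied) > 1:
        logger.info("IEFP tie among classes %s; choosing lowest index", tied)
    return tied[0]


def predict(field: ChargeField, queries, rule: DecisionRule) -> np.ndarray:
    """Apply a decision rule to one or more query points."""
    queries = np.asarray(queries, dtype=float)
    if queries.ndim == 1:
        queries = queries[None, :]
    out = np.empty(queries.shape[0], dtype=int)
    for i, q in enumerate(queries):
        if rule.method == "knn":
            out[i] = knn_predict(field.points, field.labels, q, rule.K)
        else:
            out[i] = intensity_predict(field, q, rule.epsilon_coincide)
    return out
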
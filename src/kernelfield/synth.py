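"""Seeded synthetic-data generators.

Three generators cover the statistical structures the method is built for:

* ``make_gaussian_blobs`` — isotropic Gaussian clusters with controllable
  centre separation; the linearly separable base case.
* ``make_concentric_shells`` — points on noisy hyperspheres of distinct
  radii: linearly inseparable but radially separable, i.e. exactly the
  geometry a nonlinear (RBF) kernel projection untangles and a linear one
  cannot.
* ``make_biased_proteins`` — protein sequences drawn i.i.d. from per-class
  residue frequency profiles, so that classes differ in amino-acid
  composition the way composition-classifiable protein families do.
  Residues are i.i.d. because the downstream representation is composition,
  which is order-free; no positional or evolutionary structure is emulated.

Every generator is a pure function of its parameters and a mandatory seed.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from kernelfield.dataset import LabeledDataset
from kernelfield.features import AMINO_ACIDS, SequenceRecord

logger = logging.getLogger(__name__)


def _check_n(n_per_class) -> np.ndarray:
    n = np.asarray(n_per_class, dtype=int)
    if np.any(n <= 0):
        raise ValueError(f"n_per_class must be positive, got {n_per_class}")
    return n


def make_gaussian_blobs(
    n_per_class: Sequence[int],
    dimensions: int = 3,
    separation: float = 5.0,
    cluster_std: float = 1.0,
    seed: Optional[int] = None,
) -> LabeledDataset:
    """Isotropic Gaussian clusters; class centres are ``separation`` apart.

    Centres sit at ``separation / sqrt(2)`` times seeded random orthonormal
    directions, so every pair of centres is Euclidean distance
    ``separation`` apart (exactly, for dimensions >= n_classes).
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    n = _check_n(n_per_class)
    C = len(n)
    if C < 2:
        raise ValueError(f"need >= 2 classes, got {C}")
    rng = np.random.default_rng(seed)
    # orthonormal directions via QR of a random Gaussian matrix
    G = rng.standard_normal((dimensions, max(C, 1)))
    if dimensions >= C:
        Q, _ = np.linalg.qr(G)
        dirs = Q[:, :C].T
    else:
        dirs = G.T[:C]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = (separation / np.sqrt(2.0)) * dirs

    rows, labels, ids = [], [], []
    for c in range(C):
        pts = centers[c] + cluster_std * rng.standard_normal((n[c], dimensions))
        rows.append(pts)
        labels.extend([c] * n[c])
        ids.extend([f"blob{c}_{i}" for i in range(n[c])])
    return LabeledDataset(X=np.vstack(rows), labels=np.array(labels), ids=tuple(ids))


def make_concentric_shells(
    radii: Sequence[float],
    n_per_class: Sequence[int],
    noise: float = 0.1,
    dimensions: int = 3,
    seed: Optional[int] = None,
) -> LabeledDataset:
    """Noisy concentric hyperspheres, one radius per class.

    Each point is a uniform random direction scaled by its class radius plus
    Gaussian radial noise. Radii must be distinct; radii whose gap is within
    twice the noise scale trigger a warning since the shells then overlap.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    radii = np.asarray(radii, dtype=float)
    n = _check_n(n_per_class)
    if len(radii) != len(n):
        raise ValueError(f"{len(radii)} radii but {len(n)} class sizes")
    if len(np.unique(radii)) != len(radii):
        raise ValueError("shell radii must be distinct")
    gaps = np.diff(np.sort(radii))
    if np.any(gaps <= 2 * noise):
        logger.warning("shell radii gaps %s are within noise scale %g; classes overlap", gaps, noise)

    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for c, (r, m) in enumerate(zip(radii, n)):
        u = rng.standard_normal((m, dimensions))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rad = r + noise * rng.standard_normal(m)
        rows.append(u * rad[:, None])
        labels.extend([c] * m)
        ids.extend([f"shell{c}_{i}" for i in range(m)])
    return LabeledDataset(X=np.vstack(rows), labels=np.array(labels), ids=tuple(ids))


# ---------------------------------------------------------------------------
# composition-biased protein sequences


def default_protein_profiles(shift: float = 0.05) -> list[np.ndarray]:
    """Four residue-frequency profiles, each boosting a 5-residue group by ``shift``.

    Class 0 favours hydrophobic residues (A, I, L, V, F), class 1 charged
    (D, E, K, R, H), class 2 small/polar (S, T, N, Q, G), class 3 the
    remaining distinctive group (W, Y, C, M, P); the boost is compensated
    uniformly across the other 15 residues.
    """
    groups = [
        ("A", "I", "L", "V", "F"),
        ("D", "E", "K", "R", "H"),
        ("S", "T", "N", "Q", "G"),
        ("W", "Y", "C", "M", "P"),
    ]
    if not 0 <= shift <= 0.05:
        raise ValueError("shift must be in [0, 0.05] to keep frequencies non-negative")
    profiles = []
    for group in groups:
        p = np.full(20, 0.05)
        idx = [AMINO_ACIDS.index(a) for a in group]
        p[idx] += shift
        rest = [j for j in range(20) if j not in idx]
        p[rest] -= shift * len(idx) / len(rest)
        profiles.append(p)
    return profiles


def make_biased_proteins(
    profiles: Sequence[Sequence[float]],
    n_per_class: Sequence[int],
    length_range: tuple[int, int] = (200, 400),
    seed: Optional[int] = None,
) -> tuple[list[SequenceRecord], np.ndarray]:
    """Draw i.i.d. sequences from per-class residue profiles.

    Returns (records, labels); lengths are uniform over ``length_range``.
    Use :func:`kernelfield.features.write_fasta` and
    :func:`kernelfield.dataset.write_label_table` to materialise files.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    n = _check_n(n_per_class)
    profiles = [np.asarray(p, dtype=float) for p in profiles]
    if len(profiles) != len(n):
        raise ValueError(f"{len(profiles)} profiles but {len(n)} class sizes")
    for c, p in enumerate(profiles):
        if p.shape != (20,):
            raise ValueError(f"profile {c} must have 20 frequencies, got {p.shape}")
        if np.any(p < 0):
            raise ValueError(f"profile {c} has a negative frequency")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile {c} frequencies sum to {p.sum():.6g}, expected 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")

    rng = np.random.default_rng(seed)
    alphabet = np.array(AMINO_ACIDS)
    records, labels = [], []
    for c, (p, m) in enumerate(zip(profiles, n)):
        for i in range(m):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=p))
            records.append(SequenceRecord(id=f"prot{c}_{i}", sequence=seq))
            labels.append(c)
    return records, np.array(labels, dtype=int)


def biased_protein_dataset(
    profiles: Sequence[Sequence[float]],
    n_per_class: Sequence[int],
    length_range: tuple[int, int] = (200, 400),
    seed: Optional[int] = None,
) -> LabeledDataset:
    """Convenience: generate sequences and featurise them to compositions."""
    from kernelfield.features import composition_matrix

    records, labels = make_biased_proteins(profiles, n_per_class, length_range, seed)
    return LabeledDataset(
        X=composition_matrix(records),
        labels=labels,
        ids=tuple(r.id for r in records),
        feature_names=AMINO_ACIDS,
    )
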
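"""Affinity kernels and row-stochastic diffusion operators over subjects.

This module builds the graph machinery shared by both views of the
embedding pipeline: Euclidean pairwise distances, adaptive k-nearest-neighbor
bandwidths, the alpha-decay kernel, row normalization into a transition
(diffusion) operator, spectra of the operator's symmetric conjugate, and
von Neumann entropy based selection of the diffusion time scale ``t``.

All matrices are dense; the intended scale is up to a few thousand subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DataMatrix",
    "AffinityMatrix",
    "DiffusionOperator",
    "Spectrum",
    "pairwise_distances",
    "adaptive_bandwidths",
    "alpha_decay_kernel",
    "row_normalize",
    "symmetric_conjugate_eigenvalues",
    "operator_spectrum",
    "von_neumann_entropy",
    "entropy_curve",
    "knee_point",
    "select_diffusion_time",
    "power_operator",
]


@dataclass
class DataMatrix:
    """One view's subjects-by-features matrix with aligned subject IDs."""

    subject_ids: Sequence[str]
    values: np.ndarray
    view_name: str = "view"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = list(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x features matrix")
        n = self.values.shape[0]
        if n < 3:
            raise ValueError(f"need at least 3 subjects, got {n}")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class AffinityMatrix:
    """Symmetric subject-affinity matrix with kernel parameters."""

    values: np.ndarray
    k: int
    alpha: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("affinity must be square")
        if not np.allclose(K, K.T, atol=1e-12, rtol=0.0):
            raise ValueError("affinity must be symmetric within 1e-12")
        if K.min() < 0 or K.max() > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        if not np.allclose(np.diag(K), 1.0, atol=1e-12):
            raise ValueError("affinity diagonal must equal 1")


@dataclass
class DiffusionOperator:
    """Row-stochastic transition matrix over subjects.

    ``affinity`` keeps a handle on the symmetric kernel the operator was
    normalized from, when one exists; the symmetric-conjugate spectrum is
    only defined in that case. Operators produced by multiplying two
    operators carry ``affinity=None``.
    """

    values: np.ndarray
    t: int = 1
    source: str = "view"
    affinity: AffinityMatrix | None = None
    subject_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        P = self.values
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("operator must be square")
        if P.min() < 0:
            raise ValueError("operator entries must be non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("operator rows must sum to 1 within 1e-10")
        if int(self.t) < 1:
            raise ValueError("diffusion time t must be a positive integer")
        self.t = int(self.t)
        if self.subject_ids is not None:
            self.subject_ids = list(self.subject_ids)
            if len(self.subject_ids) != P.shape[0]:
                raise ValueError("subject_ids length does not match operator size")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class Spectrum:
    """Non-increasing real eigenvalue sequence of a diffusion operator.

    For operators built from a symmetric affinity these are the eigenvalues
    of the symmetric conjugate D^{1/2} P D^{-1/2}; for combined operators
    they are eigenvalue magnitudes of the operator itself. Either way the
    leading value is 1.
    """

    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=float)
        if lam.size == 0:
            raise ValueError("spectrum is empty")
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("eigenvalues must be sorted non-increasing")
        if abs(lam[0] - 1.0) > 1e-8:
            raise ValueError("leading eigenvalue must equal 1 within 1e-8")
        self.eigenvalues = lam


def pairwise_distances(data: DataMatrix | np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between subject rows.

    Returns a symmetric, zero-diagonal, non-negative ``n x n`` matrix.
    """
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains missing or non-finite values")
    return squareform(pdist(X, metric="euclidean"))


def adaptive_bandwidths(distances: np.ndarray, k: int) -> np.ndarray:
    """Per-point bandwidth: distance to the k-th nearest neighbor (self excluded).

    Duplicate points can make a bandwidth zero; those are replaced by the
    smallest positive distance from that point (or 1.0 if the point is
    equidistant-zero from everything) and a warning is emitted, since exact
    ties do occur in survey-derived views.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")
    # sorted row: position 0 is the self distance (0); position k is the
    # k-th nearest neighbor excluding self
    D_sorted = np.sort(D, axis=1)
    eps = D_sorted[:, k].copy()
    zero = eps <= 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} duplicate point(s): zero bandwidth replaced by the "
            "smallest positive row distance",
            UserWarning,
            stacklevel=2,
        )
        for i in np.flatnonzero(zero):
            positive = D[i][D[i] > 0.0]
            eps[i] = positive.min() if positive.size else 1.0
    return eps


def alpha_decay_kernel(
    distances: np.ndarray, bandwidths: np.ndarray, alpha: float, *, k: int = 0
) -> AffinityMatrix:
    """Symmetrized alpha-decay kernel.

    K(i, j) = 1/2 exp(-(d(i,j)/eps_i)^alpha) + 1/2 exp(-(d(i,j)/eps_j)^alpha)

    Sharp decay exponents (the default alpha=40 behaves almost like a hard
    k-NN cutoff) can underflow far-pair affinities to exactly zero; that is
    the correct limit and harmless downstream.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    D = np.asarray(distances, dtype=float)
    eps = np.asarray(bandwidths, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("bandwidths must be positive")
    with np.errstate(over="ignore"):
        Ki = np.exp(-((D / eps[:, None]) ** alpha))
        Kj = np.exp(-((D / eps[None, :]) ** alpha))
    K = 0.5 * Ki + 0.5 * Kj
    np.fill_diagonal(K, 1.0)
    return AffinityMatrix(values=K, k=int(k), alpha=float(alpha))


def _stable_row_sums(K: np.ndarray) -> np.ndarray:
    # summing each row in sorted order makes the operator exactly equivariant
    # under subject permutation (the per-row summand multiset is unchanged)
    return np.sort(K, axis=1).sum(axis=1)


def row_normalize(
    affinity: AffinityMatrix | np.ndarray,
    *,
    source: str = "view",
    subject_ids: Sequence[str] | None = None,
) -> DiffusionOperator:
    """Row-normalize a non-negative matrix into a transition matrix.

    Passing an :class:`AffinityMatrix` keeps the symmetric-kernel provenance
    (enabling the symmetric-conjugate spectrum); a plain array is accepted
    for generic non-negative matrices.
    """
    if isinstance(affinity, AffinityMatrix):
        K, aff = affinity.values, affinity
    else:
        K = np.asarray(affinity, dtype=float)
        aff = None
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("matrix must be square")
        if K.min() < 0:
            raise ValueError("matrix entries must be non-negative")
    d = _stable_row_sums(K)
    if np.any(d <= 0):
        raise ValueError("matrix has a zero row; cannot normalize")
    P = K / d[:, None]
    return DiffusionOperator(values=P, t=1, source=source, affinity=aff, subject_ids=subject_ids)


def symmetric_conjugate_eigenvalues(op: DiffusionOperator) -> Spectrum:
    """Spectrum of D^{1/2} P D^{-1/2}, the operator's symmetric conjugate.

    P = D^{-1} K shares its eigenvalues with the symmetric matrix
    D^{-1/2} K D^{-1/2}, which is what actually gets decomposed (``eigvalsh``
    is stable and guarantees real output). Requires the source affinity.
    """
    if op.affinity is None:
        raise ValueError("operator was not built from a symmetric affinity")
    K = op.affinity.values
    d = _stable_row_sums(K)
    inv_sqrt = 1.0 / np.sqrt(d)
    A = K * np.outer(inv_sqrt, inv_sqrt)
    lam = np.linalg.eigvalsh(A)[::-1]
    lam = np.clip(lam, -1.0, None)
    lam[0] = min(lam[0], 1.0)
    return Spectrum(eigenvalues=lam)


def operator_spectrum(op: DiffusionOperator) -> Spectrum:
    """Spectrum used for time-scale selection.

    Uses the symmetric conjugate when the operator carries its source
    affinity; otherwise (e.g. a dual-diffusion product, which need not be
    diagonalizable over the reals) falls back to eigenvalue magnitudes of
    the operator itself. A row-stochastic matrix has spectral radius 1, so
    the leading magnitude is 1 either way.
    """
    if op.affinity is not None:
        return symmetric_conjugate_eigenvalues(op)
    lam = np.abs(np.linalg.eigvals(op.values))
    lam = np.sort(lam)[::-1]
    lam[0] = min(lam[0], 1.0)
    return Spectrum(eigenvalues=lam)


def von_neumann_entropy(spectrum: Spectrum, t: int) -> float:
    """Von Neumann entropy (nats) of the normalized powered spectrum.

    H(t) = -sum_i eta_i log eta_i with eta_i = |lambda_i|^t / sum_j |lambda_j|^t.
    Terms with eta_i = 0 contribute 0. Absolute values guard against tiny
    negative eigenvalues from finite-precision decompositions.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    lam = np.abs(spectrum.eigenvalues)
    with np.errstate(under="ignore"):
        w = lam**t
    total = w.sum()
    eta = w / total
    nz = eta > 0
    return float(-(eta[nz] * np.log(eta[nz])).sum())


def entropy_curve(spectrum: Spectrum, t_max: int) -> np.ndarray:
    """H(t) for t = 1 .. t_max (vectorized over t)."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    lam = np.abs(spectrum.eigenvalues)
    ts = np.arange(1, t_max + 1)
    with np.errstate(under="ignore", divide="ignore", invalid="ignore"):
        w = lam[None, :] ** ts[:, None]
        eta = w / w.sum(axis=1, keepdims=True)
        terms = np.where(eta > 0, eta * np.log(np.where(eta > 0, eta, 1.0)), 0.0)
    return -terms.sum(axis=1)


def select_diffusion_time(spectrum: Spectrum, t_max: int = 150) -> int:
    """Pick t at the knee of the von Neumann entropy curve.

    The knee is the t in [1, t_max] maximizing the perpendicular distance to
    the chord joining (1, H(1)) and (t_max, H(t_max)); ties break to the
    smallest t (so a flat curve yields t=1). Invariant to affine rescaling
    of H, since rescaling scales all perpendicular numerators uniformly.
    """
    if t_max < 2:
        raise ValueError("t_max must be >= 2")
    return knee_point(entropy_curve(spectrum, t_max)) + 1


def knee_point(curve: np.ndarray) -> int:
    """Index of the point farthest (perpendicular) from the first-last chord.

    Ties break to the smallest index; a flat curve yields 0. Invariant to
    affine rescaling of the curve values (rescaling scales all perpendicular
    numerators uniformly while the chord denominator is common).
    """
    y = np.asarray(curve, dtype=float)
    x = np.arange(y.size, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    # |cross product| of (chord) x (point - chord start); the common
    # denominator does not affect the argmax
    num = np.abs(dx * (y - y[0]) - dy * (x - x[0]))
    return int(np.argmax(num))


def power_operator(op: DiffusionOperator, t: int) -> DiffusionOperator:
    """t-step transition operator P^t."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if t == 1:
        return op
    Pt = np.linalg.matrix_power(op.values, t)
    # renormalize away accumulated round-off; rows stay within 1e-8 regardless
    Pt = np.clip(Pt, 0.0, None)
    Pt /= Pt.sum(axis=1, keepdims=True)
    return DiffusionOperator(
        values=Pt, t=op.t * t, source=op.source, affinity=op.affinity, subject_ids=op.subject_ids
    )
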
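"""Potential distances, metric MDS, and the PHATE / E-PHATE estimators.

The embedding pipeline turns a diffusion operator into coordinates:

1. power the operator to the selected diffusion time ``t`` (knee of the von
   Neumann entropy curve of the operator's spectrum);
2. compute potential distances ``U(i, j) = || log P^t(i, .) - log P^t(j, .) ||_2``
   with probabilities clamped at a small floor before the log;
3. initialize coordinates with classical (Torgerson) MDS on ``U``;
4. refine with metric-stress SMACOF majorization.

``PHATE`` embeds a single data view; ``EPHATE`` additionally takes a
low-dimensional exogenous view, fuses the two transition operators by dual
diffusion, and embeds the fused operator. Both follow the scikit-learn
estimator API (``fit`` / ``fit_transform``, fitted attributes with a
trailing underscore). Out-of-sample ``transform`` is deliberately not
offered: diffusion embeddings of a fixed cohort do not extend to new
subjects without a separate extension scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SKPCA

from .graph import (
    DataMatrix,
    DiffusionOperator,
    operator_spectrum,
    power_operator,
    select_diffusion_time,
)
from .graph import AffinityMatrix, row_normalize
from .multiview import (
    ExogenousMatrix,
    ViewConfig,
    dual_diffusion_combine,
    exogenous_affinity,
    joint_affinity,
    resolve_k_env,
    standardize_exogenous,
    view_affinity,
    view_operator,
)

__all__ = [
    "PotentialDistances",
    "Embedding",
    "potential_distance",
    "classical_mds",
    "smacof_refine",
    "PHATE",
    "EPHATE",
    "phate_embed",
    "ephate_embed",
    "pca_embed",
]


@dataclass
class PotentialDistances:
    """Symmetric zero-diagonal matrix of log-potential distances."""

    values: np.ndarray
    t: int
    log_floor: float

    def __post_init__(self) -> None:
        U = np.asarray(self.values, dtype=float)
        if not np.allclose(U, U.T, atol=1e-8, rtol=0.0):
            raise ValueError("potential distances must be symmetric within 1e-8")
        if np.any(np.abs(np.diag(U)) > 1e-12) or U.min() < 0:
            raise ValueError("potential distances must be non-negative with zero diagonal")
        self.values = U


@dataclass
class Embedding:
    """Low-dimensional coordinates plus the provenance to regenerate them."""

    subject_ids: Sequence[str]
    coords: np.ndarray
    method: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    stress: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.subject_ids = list(self.subject_ids)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be 2-D with at least one dimension")
        if len(self.subject_ids) != self.coords.shape[0]:
            raise ValueError("subject_ids length does not match coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")


def potential_distance(
    op: DiffusionOperator, t: int, log_floor: float = 1e-7
) -> PotentialDistances:
    """Pairwise Euclidean distances between log-transformed rows of P^t."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if not (0.0 < log_floor < 1.0):
        raise ValueError("log_floor must lie in (0, 1)")
    P = op.values
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("operator is not row-stochastic")
    Pt = power_operator(op, t).values if t > 1 else P
    logP = np.log(np.clip(Pt, log_floor, None))
    U = squareform(pdist(logP, metric="euclidean"))
    return PotentialDistances(values=U, t=t, log_floor=log_floor)


def classical_mds(distances: np.ndarray, D: int) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates.

    Double-centers the squared distance matrix and takes the top-D
    eigenpairs, scaling eigenvectors by root-eigenvalues. Negative
    eigenvalues (non-Euclidean input) are truncated at zero.
    """
    U = np.asarray(distances, dtype=float)
    n = U.shape[0]
    if not (1 <= D < n):
        raise ValueError(f"D must satisfy 1 <= D < n, got D={D}, n={n}")
    if not np.allclose(U, U.T, atol=1e-8) or np.any(np.abs(np.diag(U)) > 1e-12):
        raise ValueError("distances must be symmetric with zero diagonal")
    U2 = U**2
    row_mean = U2.mean(axis=1)
    B = -0.5 * (U2 - row_mean[:, None] - row_mean[None, :] + U2.mean())
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1][:D]
    lam_top = np.clip(lam[order], 0.0, None)
    return vec[:, order] * np.sqrt(lam_top)[None, :]


def _stress(U: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    d = squareform(pdist(X))
    raw = ((U - d) ** 2).sum() / 2.0
    return raw, d


def smacof_refine(
    distances: np.ndarray,
    init_coords: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-6,
    *,
    return_history: bool = False,
):
    """Metric-stress majorization (SMACOF) from a given initialization.

    Iterates the Guttman transform, which guarantees a non-increasing raw
    stress sequence; stops when the relative stress change drops below
    ``tol``. Returns ``(coords, stress)`` where stress is normalized by the
    total squared target distance (so 0 means perfect reproduction); with
    ``return_history=True`` the per-iteration normalized stress sequence is
    appended.
    """
    U = np.asarray(distances, dtype=float)
    X = np.array(init_coords, dtype=float)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("initial coordinates must be finite")
    n = U.shape[0]
    denom = (U**2).sum() / 2.0
    if denom == 0.0:
        out = (X, 0.0)
        return (*out, [0.0]) if return_history else out
    raw, d = _stress(U, X)
    history = [raw / denom]
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, U / np.where(d > 0, d, 1.0), 0.0)
        B = -ratio
        B[np.arange(n), np.arange(n)] = ratio.sum(axis=1)
        X_new = (B @ X) / n
        raw_new, d_new = _stress(U, X_new)
        stop = raw > 0 and (raw - raw_new) / raw < tol
        X, raw, d = X_new, raw_new, d_new
        history.append(raw / denom)
        if stop or raw == 0.0:
            break
    out = (X, raw / denom)
    return (*out, history) if return_history else out


class PHATE(BaseEstimator):
    """Diffusion-potential embedding of one high-dimensional view.

    Parameters
    ----------
    n_components : int, default=20
        Embedding dimensionality D (20 for analysis, 2-3 for plotting).
    knn : int, default=5
        Neighbors used for the adaptive kernel bandwidth.
    decay : float, default=40.0
        Alpha-decay exponent of the kernel.
    t : int or "auto", default="auto"
        Diffusion time; "auto" selects the knee of the von Neumann entropy
        curve over ``1..t_max``.
    t_max : int, default=150
        Search range for automatic t selection.
    log_floor : float, default=1e-7
        Smallest transition probability before the log transform.
    mds_max_iter, mds_tol :
        SMACOF stopping parameters.
    random_state : int or None
        Recorded for provenance; the pipeline is deterministic (SMACOF is
        initialized from classical MDS, not at random).

    Attributes
    ----------
    embedding_ : ndarray of shape (n_subjects, n_components)
    t_ : int, the diffusion time actually used
    stress_ : float, final normalized SMACOF stress
    eigenvalues_ : ndarray, spectrum used for t selection
    diffusion_operator_ : DiffusionOperator
    potential_distances_ : PotentialDistances
    """

    def __init__(
        self,
        n_components: int = 20,
        knn: int = 5,
        decay: float = 40.0,
        t: int | str = "auto",
        t_max: int = 150,
        log_floor: float = 1e-7,
        mds_max_iter: int = 300,
        mds_tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.knn = knn
        self.decay = decay
        self.t = t
        self.t_max = t_max
        self.log_floor = log_floor
        self.mds_max_iter = mds_max_iter
        self.mds_tol = mds_tol
        self.random_state = random_state

    # -- pipeline pieces (overridden by EPHATE) --------------------------------
    def _build_operator(self, X: np.ndarray, X_env=None) -> DiffusionOperator:
        return view_operator(X, self.knn, self.decay, source="data")

    def _fit(self, X: np.ndarray, X_env=None) -> "PHATE":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n_features_in_ = X.shape[1]
        op = self._build_operator(X, X_env)
        spectrum = operator_spectrum(op)
        self.eigenvalues_ = spectrum.eigenvalues
        if self.t == "auto":
            self.t_ = select_diffusion_time(spectrum, self.t_max)
        else:
            self.t_ = int(self.t)
        self.diffusion_operator_ = op
        self.potential_distances_ = potential_distance(op, self.t_, self.log_floor)
        U = self.potential_distances_.values
        init = classical_mds(U, self.n_components)
        coords, stress = smacof_refine(U, init, self.mds_max_iter, self.mds_tol)
        self.embedding_ = coords
        self.stress_ = stress
        return self

    def fit(self, X, y=None):
        """Compute the embedding of ``X``; returns self."""
        return self._fit(X)

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Compute and return the embedding coordinates of ``X``."""
        return self.fit(X).embedding_


class EPHATE(PHATE):
    """Exogenous PHATE: multi-view fusion of a high-dimensional data view
    with an exogenous covariate view, embedded with metric MDS.

    With the default ``fusion='kernel'`` the fused affinity is the
    elementwise product of the data-view kernel (``knn``/``decay``) and the
    exogenous-view kernel (``knn_env``/``decay_env`` on z-scored
    covariates): a fused-walk step must be plausible under both views, so
    the diffusion geometry — and hence the embedding — resolves joint
    (data, environment) structure, including their nonlinear interaction.
    With ``fusion='operator'`` the two row-normalized transition matrices
    are multiplied in ``combine_order`` (classical dual diffusion); an
    identity environment operator then reduces E-PHATE to PHATE exactly.

    ``fit(X, X_env)`` takes the two views; subject order must match.
    ``X_env`` may be a raw array, an :class:`ExogenousMatrix`, a pre-built
    environment :class:`AffinityMatrix` (kernel fusion), or a pre-built
    environment :class:`DiffusionOperator` (operator fusion).
    """

    def __init__(
        self,
        n_components: int = 20,
        knn: int = 5,
        decay: float = 40.0,
        knn_env: int | None = None,
        decay_env: float = 5.0,
        standardize_env: bool = True,
        fusion: str = "kernel",
        combine_order: str = "brain_env",
        t: int | str = "auto",
        t_max: int = 150,
        log_floor: float = 1e-7,
        mds_max_iter: int = 300,
        mds_tol: float = 1e-6,
        random_state: int | None = None,
    ):
        super().__init__(
            n_components=n_components, knn=knn, decay=decay, t=t, t_max=t_max,
            log_floor=log_floor, mds_max_iter=mds_max_iter, mds_tol=mds_tol,
            random_state=random_state,
        )
        self.knn_env = knn_env
        self.decay_env = decay_env
        self.standardize_env = standardize_env
        self.fusion = fusion
        self.combine_order = combine_order

    def _view_config(self) -> ViewConfig:
        return ViewConfig(
            k_brain=self.knn, alpha_brain=self.decay,
            k_env=self.knn_env, alpha_env=self.decay_env,
            standardize_env=self.standardize_env, fusion=self.fusion,
            combine_order=self.combine_order,
        )

    def _as_env_matrix(self, X_env) -> ExogenousMatrix:
        if isinstance(X_env, ExogenousMatrix):
            return X_env
        X_env = np.asarray(X_env, dtype=float)
        return ExogenousMatrix(
            subject_ids=[f"s{i}" for i in range(X_env.shape[0])], values=X_env
        )

    def _build_operator(self, X: np.ndarray, X_env=None) -> DiffusionOperator:
        if X_env is None:
            raise ValueError("EPHATE requires the exogenous view X_env")
        cfg = self._view_config()
        if cfg.fusion == "kernel":
            if isinstance(X_env, DiffusionOperator):
                raise ValueError(
                    "a pre-built environment DiffusionOperator requires fusion='operator'"
                )
            k_data = view_affinity(X, self.knn, self.decay)
            if isinstance(X_env, AffinityMatrix):
                k_env = X_env
            else:
                env = self._as_env_matrix(X_env)
                if env.n_subjects != X.shape[0]:
                    raise ValueError("data and exogenous views differ in length")
                env_used = standardize_exogenous(env) if cfg.standardize_env else env
                k_env = view_affinity(
                    env_used.values,
                    resolve_k_env(env.n_subjects, cfg.k_env),
                    cfg.alpha_env,
                )
            fused = joint_affinity(k_data, k_env)
            return row_normalize(fused, source="joint(data,environment)")
        # operator fusion: classical dual diffusion
        p_data = view_operator(X, self.knn, self.decay, source="data")
        if isinstance(X_env, DiffusionOperator):
            p_env = X_env
        else:
            p_env = exogenous_affinity(self._as_env_matrix(X_env), cfg)
        return dual_diffusion_combine(p_data, p_env, cfg)

    def fit(self, X, X_env=None):
        """Compute the fused embedding from the data view ``X`` and the
        exogenous view ``X_env`` (array, ExogenousMatrix, or a pre-built
        DiffusionOperator); returns self."""
        return self._fit(X, X_env)

    def fit_transform(self, X, X_env=None) -> np.ndarray:
        return self.fit(X, X_env).embedding_


def _provenance(est: PHATE) -> dict[str, Any]:
    rec = dict(est.get_params())
    rec["t_selected"] = est.t_
    return rec


def phate_embed(
    data: DataMatrix, cfg: ViewConfig | None = None, D: int = 20, seed: int = 0
) -> Embedding:
    """Embed one data view with PHATE; thin wrapper over the estimator."""
    cfg = cfg or ViewConfig()
    est = PHATE(n_components=D, knn=cfg.k_brain, decay=cfg.alpha_brain, random_state=seed)
    est.fit(data.values)
    return Embedding(
        subject_ids=data.subject_ids, coords=est.embedding_, method="phate",
        params=_provenance(est), seed=seed, stress=est.stress_,
    )


def ephate_embed(
    data: DataMatrix,
    env: ExogenousMatrix | DiffusionOperator,
    cfg: ViewConfig | None = None,
    D: int = 20,
    seed: int = 0,
) -> Embedding:
    """Embed a data view fused with an exogenous view via dual diffusion."""
    cfg = cfg or ViewConfig()
    if isinstance(env, ExogenousMatrix) and list(env.subject_ids) != list(data.subject_ids):
        raise ValueError("subject IDs of data and exogenous views are misaligned")
    est = EPHATE(
        n_components=D, knn=cfg.k_brain, decay=cfg.alpha_brain,
        knn_env=cfg.k_env, decay_env=cfg.alpha_env,
        standardize_env=cfg.standardize_env, fusion=cfg.fusion,
        combine_order=cfg.combine_order, random_state=seed,
    )
    est.fit(data.values, env)
    return Embedding(
        subject_ids=data.subject_ids, coords=est.embedding_, method="ephate",
        params=_provenance(est), seed=seed, stress=est.stress_,
    )


def pca_embed(data: DataMatrix, D: int = 20) -> Embedding:
    """Scores on the top-D principal components of the centered view."""
    n, p = data.values.shape
    if D > min(n, p):
        raise ValueError(f"D={D} exceeds min(n, p)={min(n, p)}")
    pca = _SKPCA(n_components=D, svd_solver="full")
    coords = pca.fit_transform(data.values)
    return Embedding(
        subject_ids=data.subject_ids, coords=coords, method="pca",
        params={"n_components": D}, seed=None, stress=None,
    )
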
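"""Synthetic cohorts with the structure the fused embedding assumes.

The generator emulates, at desk scale, the statistical shape of the real
inputs: a low-dimensional latent "brain" variable lifted by a fixed smooth
nonlinear map into a high-dimensional data view (standing in for voxel-wise
task-contrast betas), a correlated low-dimensional "environment" latent
observed through a handful of noisy covariate columns (named after the five
family/neighborhood adversity scores), and outcomes driven by main effects
plus a brain-latent x environment-latent interaction, with an additive
pseudo-scanner covariate. Everything is a deterministic function of
``(config, seed)``; each generation stage draws from its own seeded stream
so the stages can also be called in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import OutcomeTable
from .graph import DataMatrix
from .multiview import ExogenousMatrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_latents",
           "generate_brain_view", "generate_environment_view",
           "generate_outcomes", "generate_dataset"]

# default column names mirror the five exogenous adversity scores:
# family conflict, caregiver acceptance, youth/caregiver perceived
# neighborhood safety-crime, and the area deprivation index
ENV_FEATURE_NAMES = ("FES", "CRPBI", "NCY", "NSC", "ADI")

# per-stage offsets for independent deterministic streams
_STAGE = {"latents": 0, "brain": 1, "env": 2, "outcome": 3}


@dataclass
class SyntheticConfig:
    """Generation parameters.

    The defaults define the standard study conditions used throughout the
    tests: 300 subjects, a 200-feature brain view, five environment
    covariates, 1-D brain and environment latents correlated at 0.3, and an
    interaction-dominant outcome (interaction weight 1.0 vs. main-effect
    weights 0.3).
    """

    n: int = 300
    p: int = 200
    q: int = 5
    latent_dims: tuple[int, int] = (1, 1)
    env_brain_corr: float = 0.3
    interaction_weight: float = 1.0
    main_effect_weights: tuple[float, float] = (0.3, 0.3)
    noise_sd_brain: float = 0.1
    noise_sd_env: float = 0.3
    noise_sd_outcome: float = 0.5
    nonlinearity: str = "sinusoid"
    freq_scale: float = 1.0
    n_scanners: int = 3
    scanner_effect_sd: float = 0.1
    include_baseline: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        for name in ("noise_sd_brain", "noise_sd_env", "noise_sd_outcome"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (-1.0 <= self.env_brain_corr <= 1.0):
            raise ValueError("env_brain_corr must lie in [-1, 1]")
        if self.nonlinearity != "sinusoid":
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.n_scanners < 1:
            raise ValueError("n_scanners must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated views, outcomes, and the ground-truth latents behind them."""

    brain: DataMatrix
    env: ExogenousMatrix
    outcomes: OutcomeTable
    latents: np.ndarray
    config: SyntheticConfig

    @property
    def subject_ids(self) -> list[str]:
        return list(self.brain.subject_ids)


def _rng(cfg: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STAGE[stage]])


def generate_latents(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Brain latents on a smooth 1-2-D manifold plus correlated environment
    latents.

    The first brain latent dimension is the arc parameter, drawn on a
    jittered regular grid over [0, 1] (one point per cell, uniform within
    the cell) and standardized. Jittered-grid sampling keeps the arc evenly
    covered: with iid-uniform draws the largest sampling gap grows like
    log(n)/n and routinely exceeds the adaptive k-NN bandwidth, splitting
    the affinity graph into disconnected components, which no diffusion
    method can order. A second dimension, when requested, adds a small
    transverse wobble. Environment latents share correlation
    ``env_brain_corr`` with the corresponding brain latent (independent
    beyond the shared dimensions).
    """
    rng = _rng(cfg, "latents")
    db, de = cfg.latent_dims
    theta = (np.arange(cfg.n) + rng.uniform(0.0, 1.0, size=cfg.n)) / cfg.n
    b1 = (theta - theta.mean()) / theta.std()
    B = np.empty((cfg.n, db))
    B[:, 0] = b1
    for j in range(1, db):
        B[:, j] = 0.3 * np.sin((j + 1) * np.pi * theta) + 0.1 * rng.standard_normal(cfg.n)
    r = cfg.env_brain_corr
    E = np.empty((cfg.n, de))
    for j in range(de):
        z = rng.standard_normal(cfg.n)
        base = B[:, j] if j < db else rng.standard_normal(cfg.n)
        E[:, j] = r * base + np.sqrt(1.0 - r**2) * z
    return B, E


def generate_brain_view(latents_brain: np.ndarray, cfg: SyntheticConfig) -> DataMatrix:
    """Lift the brain latents through a fixed random sinusoidal feature map.

    Each of the ``p`` features is sin(w . b + phi) with frequencies drawn
    once (seeded) from N(0, freq_scale^2) and phases uniform on [0, 2pi),
    plus Gaussian observation noise. The map is smooth and genuinely
    nonlinear, so no linear method can read the latent off directly, while
    local distances still track the latent along the manifold.
    """
    B = np.atleast_2d(np.asarray(latents_brain, dtype=float))
    if B.shape[0] == 1 and cfg.n != 1:
        B = B.T
    rng = _rng(cfg, "brain")
    db = B.shape[1]
    W = rng.normal(0.0, cfg.freq_scale, size=(db, cfg.p))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=cfg.p)
    X = np.sin(B @ W + phi)
    X = X + cfg.noise_sd_brain * rng.standard_normal(X.shape)
    ids = [f"sub-{i:04d}" for i in range(B.shape[0])]
    return DataMatrix(subject_ids=ids, values=X, view_name="brain")


def generate_environment_view(
    latents_env: np.ndarray, cfg: SyntheticConfig
) -> ExogenousMatrix:
    """Observe the environment latents through q noisy linear mixes."""
    E = np.atleast_2d(np.asarray(latents_env, dtype=float))
    if E.shape[0] == 1 and cfg.n != 1:
        E = E.T
    rng = _rng(cfg, "env")
    de = E.shape[1]
    M = rng.normal(0.0, 1.0, size=(de, cfg.q))
    V = E @ M + cfg.noise_sd_env * rng.standard_normal((E.shape[0], cfg.q))
    if cfg.q <= len(ENV_FEATURE_NAMES):
        names = list(ENV_FEATURE_NAMES[: cfg.q])
    else:
        names = list(ENV_FEATURE_NAMES) + [
            f"ENV{j}" for j in range(len(ENV_FEATURE_NAMES), cfg.q)
        ]
    ids = [f"sub-{i:04d}" for i in range(E.shape[0])]
    return ExogenousMatrix(subject_ids=ids, values=V, feature_names=names)


def generate_outcomes(
    latents_brain: np.ndarray, latents_env: np.ndarray, cfg: SyntheticConfig
) -> OutcomeTable:
    """Outcome = main effects + interaction of the two first latents + noise.

    y = w_b * b + w_e * e + w_int * (b * e) + scanner shift + noise.
    A categorical pseudo-scanner covariate adds a small seeded level shift;
    with ``include_baseline`` a correlated baseline score is emitted as a
    numeric covariate for longitudinal-style analyses.
    """
    B = np.atleast_2d(np.asarray(latents_brain, dtype=float))
    E = np.atleast_2d(np.asarray(latents_env, dtype=float))
    if B.shape[0] == 1 and cfg.n != 1:
        B = B.T
    if E.shape[0] == 1 and cfg.n != 1:
        E = E.T
    rng = _rng(cfg, "outcome")
    b, e = B[:, 0], E[:, 0]
    wb, we = cfg.main_effect_weights
    signal = wb * b + we * e + cfg.interaction_weight * b * e
    scanner = rng.integers(0, cfg.n_scanners, size=b.size)
    shifts = rng.normal(0.0, cfg.scanner_effect_sd, size=cfg.n_scanners)
    y = signal + shifts[scanner] + cfg.noise_sd_outcome * rng.standard_normal(b.size)
    ids = [f"sub-{i:04d}" for i in range(b.size)]
    cov = pd.DataFrame(
        {"scanner": pd.Categorical([f"scanner_{s}" for s in scanner])}, index=ids
    )
    if cfg.include_baseline:
        cov["baseline"] = 0.5 * signal + 0.5 * rng.standard_normal(b.size)
    outcomes = pd.DataFrame({"problem_total": y}, index=ids)
    return OutcomeTable(subject_ids=ids, outcomes=outcomes, covariates=cov)


def generate_dataset(cfg: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """Compose latents, both views, and outcomes into one dataset."""
    if cfg is None:
        cfg = SyntheticConfig(**overrides)
    elif overrides:
        cfg = SyntheticConfig(**{**asdict(cfg), **overrides})
    B, E = generate_latents(cfg)
    brain = generate_brain_view(B, cfg)
    env = generate_environment_view(E, cfg)
    outcomes = generate_outcomes(B, E, cfg)
    return SyntheticDataset(
        brain=brain, env=env, outcomes=outcomes,
        latents=np.hstack([B, E]), config=cfg,
    )
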
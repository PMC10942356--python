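"""Representation construction and the benchmarking loop.

Ties the embedding and evaluation modules into the standard comparison: for
each requested representation of the data view (raw features, PCA, PHATE,
PHATE + environment concatenation, E-PHATE, and the E-PHATE noise control)
build the feature matrix, score it by cross-validated prediction of an
outcome, and compare representations pairwise with Bonferroni-corrected
sign-flip permutation tests.

Representations
---------------
voxel
    The raw data-view matrix, untouched.
pca
    Scores on the top-D principal components.
phate
    Diffusion-potential embedding of the data view alone.
phate_plus_env
    PHATE coordinates concatenated with the z-scored exogenous columns —
    the *linear* way to add the exogenous view, used to show the fused
    embedding's gain is attributable to the nonlinear combination.
ephate
    The dual-diffusion fused embedding.
ephate_control
    E-PHATE with the exogenous view replaced by seeded standard-normal
    noise of matching shape — more data about each subject, but no
    environmental information.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import Embedding, ephate_embed, pca_embed, phate_embed
from .evaluation import (
    FoldScores,
    ComparisonResult,
    bonferroni_adjust,
    evaluate_representation,
    pairwise_permutation_test,
)
from .graph import DataMatrix
from .multiview import ExogenousMatrix, ViewConfig, standardize_exogenous
from .synthetic import SyntheticDataset

__all__ = [
    "REPRESENTATIONS",
    "noise_environment",
    "compute_representations",
    "benchmark_representations",
    "scores_to_frames",
]

REPRESENTATIONS = ("voxel", "pca", "phate", "phate_plus_env", "ephate", "ephate_control")

_NOISE_STREAM = 9001  # sub-stream tag for the control view's noise


def noise_environment(env: ExogenousMatrix, seed: int) -> ExogenousMatrix:
    """Seeded standard-normal stand-in for the exogenous view (same shape)."""
    rng = np.random.default_rng([seed, _NOISE_STREAM])
    values = rng.standard_normal(env.values.shape)
    return ExogenousMatrix(
        subject_ids=env.subject_ids,
        values=values,
        feature_names=[f"noise_{name}" for name in env.feature_names],
    )


def compute_representations(
    brain: DataMatrix,
    env: ExogenousMatrix,
    names: Sequence[str] = REPRESENTATIONS,
    cfg: ViewConfig | None = None,
    D: int = 20,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, Embedding | None]]:
    """Feature matrix (and Embedding, where one exists) per representation.

    The PHATE embedding is computed once and shared between ``phate`` and
    ``phate_plus_env``.
    """
    cfg = cfg or ViewConfig()
    unknown = set(names) - set(REPRESENTATIONS)
    if unknown:
        raise ValueError(f"unknown representation(s): {sorted(unknown)}")
    out: dict[str, tuple[np.ndarray, Embedding | None]] = {}
    phate_result: Embedding | None = None
    if {"phate", "phate_plus_env"} & set(names):
        phate_result = phate_embed(brain, cfg, D=D, seed=seed)
    for name in names:
        if name == "voxel":
            out[name] = (brain.values, None)
        elif name == "pca":
            emb = pca_embed(brain, D=D)
            out[name] = (emb.coords, emb)
        elif name == "phate":
            out[name] = (phate_result.coords, phate_result)
        elif name == "phate_plus_env":
            env_std = standardize_exogenous(env)
            out[name] = (np.hstack([phate_result.coords, env_std.values]), None)
        elif name == "ephate":
            emb = ephate_embed(brain, env, cfg, D=D, seed=seed)
            out[name] = (emb.coords, emb)
        elif name == "ephate_control":
            emb = ephate_embed(brain, noise_environment(env, seed), cfg, D=D, seed=seed)
            out[name] = (emb.coords, emb)
    return out


def benchmark_representations(
    dataset: SyntheticDataset,
    names: Sequence[str] = REPRESENTATIONS,
    outcome_name: str | None = None,
    cfg: ViewConfig | None = None,
    D: int = 20,
    F: int = 20,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[dict[str, FoldScores], list[ComparisonResult]]:
    """Score every requested representation and compare all pairs.

    Every representation is evaluated on the same fold split (same seed),
    so fold scores are paired and the sign-flip test applies. Bonferroni
    corrects over the number of pairs tested.
    """
    reps = compute_representations(
        dataset.brain, dataset.env, names, cfg=cfg, D=D, seed=seed
    )
    scores = {
        name: evaluate_representation(
            matrix, dataset.outcomes, outcome_name=outcome_name, F=F, seed=seed,
            representation_name=name,
        )
        for name, (matrix, _) in reps.items()
    }
    pairs = list(combinations(names, 2))
    raw = [
        pairwise_permutation_test(
            scores[a].per_fold_rho, scores[b].per_fold_rho, n_perm=n_perm, seed=seed
        )
        for a, b in pairs
    ]
    adjusted = bonferroni_adjust(raw, m=len(pairs)) if pairs else []
    comparisons = [
        ComparisonResult(
            pair=(a, b),
            outcome_name=scores[a].outcome_name,
            p_raw=p,
            p_adjusted=float(pa),
            n_permutations=n_perm,
        )
        for (a, b), p, pa in zip(pairs, raw, adjusted)
    ]
    return scores, comparisons


def scores_to_frames(
    scores: dict[str, FoldScores], comparisons: list[ComparisonResult]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Long per-fold table, summary table, and pairwise-comparison table."""
    fold_rows = [
        {
            "representation": s.representation_name,
            "outcome": s.outcome_name,
            "fold": f,
            "rho": rho,
        }
        for s in scores.values()
        for f, rho in enumerate(s.per_fold_rho)
    ]
    summary_rows = [
        {
            "representation": s.representation_name,
            "outcome": s.outcome_name,
            "mean_rho": s.mean_rho,
            "ci95_low": s.ci95[0],
            "ci95_high": s.ci95[1],
            "n_folds": s.per_fold_rho.size,
        }
        for s in scores.values()
    ]
    comp_rows = [
        {
            "representation_a": c.pair[0],
            "representation_b": c.pair[1],
            "outcome": c.outcome_name,
            "p_raw": c.p_raw,
            "p_bonferroni": c.p_adjusted,
            "n_permutations": c.n_permutations,
        }
        for c in comparisons
    ]
    return pd.DataFrame(fold_rows), pd.DataFrame(summary_rows), pd.DataFrame(comp_rows)
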
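"""Cross-validated linear prediction scored with partial Spearman correlation.

A representation (embedding coordinates or the raw feature matrix) is scored
by k-fold cross-validation: ordinary least squares with intercept is fit on
the training subjects and applied to the held-out subjects, and each fold is
scored as the partial Spearman correlation between predicted and true
outcome, controlling for covariates (categorical covariates one-hot
encoded). Representations are compared fold-wise with a paired two-sided
sign-flip permutation test, Bonferroni-corrected over the set of
comparisons. A signal-detection d' with the log-linear (Hautus) correction
is provided for scoring n-back-style task performance from trial counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .embedding import Embedding

__all__ = [
    "OutcomeTable",
    "FoldScores",
    "ComparisonResult",
    "kfold_split",
    "fit_predict_linear",
    "partial_spearman",
    "evaluate_representation",
    "pairwise_permutation_test",
    "bonferroni_adjust",
    "dprime_hautus",
]


@dataclass
class OutcomeTable:
    """Outcomes and covariates aligned with a representation's subjects."""

    subject_ids: Sequence[str]
    outcomes: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.subject_ids = list(self.subject_ids)
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if len(self.outcomes) != n:
            raise ValueError("outcomes length does not match subject_ids")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariates length does not match subject_ids")

    def covariate_design(self) -> np.ndarray | None:
        """Numeric covariate design: numeric columns as-is, categorical
        one-hot with the reference level dropped. None when no covariates."""
        if self.covariates is None or self.covariates.shape[1] == 0:
            return None
        cols = []
        for name in self.covariates.columns:
            col = self.covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float)[:, None])
            else:
                dummies = pd.get_dummies(col.astype(str), drop_first=True)
                cols.append(dummies.to_numpy(dtype=float))
        return np.hstack(cols) if cols else None


@dataclass
class FoldScores:
    """Per-fold partial Spearman scores for one representation/outcome pair."""

    representation_name: str
    outcome_name: str
    per_fold_rho: np.ndarray
    mean_rho: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        rho = np.asarray(self.per_fold_rho, dtype=float)
        if np.any(np.abs(rho) > 1 + 1e-12):
            raise ValueError("fold correlations must lie in [-1, 1]")
        self.per_fold_rho = rho
        self.mean_rho = float(rho.mean())
        f = rho.size
        if f > 1 and rho.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, f - 1) * rho.std(ddof=1) / np.sqrt(f)
        else:
            half = 0.0
        self.ci95 = (self.mean_rho - half, self.mean_rho + half)


@dataclass
class ComparisonResult:
    """Paired permutation-test result for one pair of representations."""

    pair: tuple[str, str]
    outcome_name: str
    p_raw: float
    p_adjusted: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_raw <= 1.0 and 0.0 < self.p_adjusted <= 1.0):
            raise ValueError("p values must lie in (0, 1]")
        if self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p cannot be smaller than raw p")


def kfold_split(
    subject_ids: Sequence[str], F: int = 20, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold split keyed on subject IDs, not positions.

    Fold membership is decided on the sorted ID list (then shuffled with the
    seed), so the same seed assigns the same subjects to the same folds
    regardless of row order. Returns (train, test) position-index pairs;
    test sets are disjoint, cover everyone, and differ in size by at most 1.
    With the default F=20 each fold holds out 5% of subjects.
    """
    ids = list(subject_ids)
    n = len(ids)
    if F < 2:
        raise ValueError("F must be >= 2")
    if F > n:
        raise ValueError(f"F={F} exceeds the number of subjects n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(ids))
    pos = {sid: i for i, sid in enumerate(ids)}
    folds = []
    chunks = np.array_split(order, F)
    for chunk in chunks:
        test = np.array(sorted(pos[sid] for sid in chunk), dtype=int)
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        folds.append((np.flatnonzero(mask), test))
    return folds


def fit_predict_linear(
    rep_coords: np.ndarray,
    outcome: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Out-of-fold OLS predictions, one per subject.

    Each fold fits ordinary least squares with intercept on the training
    subjects and predicts the held-out subjects. Rank-deficient designs are
    solved by the minimum-norm least-squares solution with a warning.
    """
    X = np.asarray(rep_coords, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("rep_coords and outcome are misaligned")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain missing values")
    pred = np.full(y.shape[0], np.nan)
    for train, test in folds:
        A = np.column_stack([np.ones(train.size), X[train]])
        beta, _, rank, _ = np.linalg.lstsq(A, y[train], rcond=None)
        if rank < A.shape[1]:
            warnings.warn(
                "rank-deficient regression design; using minimum-norm solution",
                UserWarning,
                stacklevel=2,
            )
        pred[test] = np.column_stack([np.ones(test.size), X[test]]) @ beta
    if np.any(np.isnan(pred)):
        raise ValueError("folds do not cover all subjects")
    return pred


def _residualize(v: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    design = np.ones((v.size, 1)) if Z is None else np.column_stack([np.ones(v.size), Z])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_spearman(
    pred: np.ndarray, truth: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Spearman correlation of pred and truth, partialling out covariates.

    Both vectors are rank-transformed (average ranks on ties), each rank
    vector is residualized on the covariate design (with intercept) by least
    squares, and the Pearson correlation of the residuals is returned. With
    no covariates this equals the plain Spearman correlation exactly.
    """
    a = np.asarray(pred, dtype=float)
    b = np.asarray(truth, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("pred and truth must have equal length >= 3")
    Z = None
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[1] == 0:
            Z = None
        elif Z.shape[0] != a.size:
            raise ValueError("covariates misaligned with pred/truth")
    ra = _residualize(stats.rankdata(a), Z)
    rb = _residualize(stats.rankdata(b), Z)
    na, nb = np.linalg.norm(ra), np.linalg.norm(rb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-variance residuals: correlation undefined")
    return float(np.clip(ra @ rb / (na * nb), -1.0, 1.0))


def evaluate_representation(
    rep: Embedding | np.ndarray,
    outcomes: OutcomeTable,
    outcome_name: str | None = None,
    F: int = 20,
    seed: int = 0,
    representation_name: str | None = None,
) -> FoldScores:
    """Cross-validated prediction of one outcome from one representation.

    For each of ``F`` folds, OLS maps the representation to the outcome on
    the training subjects; held-out predictions are scored with the partial
    Spearman correlation against the true outcome, controlling for the
    table's covariates. The mean across folds carries a 95% t-interval.
    """
    if isinstance(rep, Embedding):
        coords = rep.coords
        if list(rep.subject_ids) != list(outcomes.subject_ids):
            raise ValueError("representation and outcome subject IDs are misaligned")
        name = representation_name or rep.method
    else:
        coords = np.asarray(rep, dtype=float)
        if coords.shape[0] != len(outcomes.subject_ids):
            raise ValueError("representation and outcome table differ in length")
        name = representation_name or "raw"
    outcome_name = outcome_name or outcomes.outcomes.columns[0]
    y = outcomes.outcomes[outcome_name].to_numpy(dtype=float)
    Z = outcomes.covariate_design()
    folds = kfold_split(outcomes.subject_ids, F=F, seed=seed)
    pred = fit_predict_linear(coords, y, folds)
    rhos = []
    for _, test in folds:
        Zt = Z[test] if Z is not None else None
        rhos.append(partial_spearman(pred[test], y[test], Zt))
    return FoldScores(
        representation_name=name, outcome_name=outcome_name, per_fold_rho=np.array(rhos)
    )


def pairwise_permutation_test(
    fold_rhos_a: np.ndarray,
    fold_rhos_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided paired sign-flip permutation test on per-fold differences.

    The statistic is the mean fold difference; under the null the sign of
    each paired difference is exchangeable, so signs are flipped uniformly.
    p = (1 + #{permuted |mean| >= observed |mean|}) / (n_perm + 1).
    """
    a = np.asarray(fold_rhos_a, dtype=float)
    b = np.asarray(fold_rhos_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold score vectors differ in length")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = a - b
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    perm = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(perm >= obs - 1e-12)) / (n_perm + 1))


def bonferroni_adjust(p_values: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError("m must be at least the number of p values")
    return np.minimum(1.0, m * p)


def dprime_hautus(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> float:
    """Signal-detection d' with the log-linear (Hautus) correction.

    Adds 0.5 to each cell count (1 to each trial total) before computing
    rates, so perfect or zero rates stay inside (0, 1):
    d' = Phi^-1((hits+0.5)/(hits+misses+1)) - Phi^-1((fa+0.5)/(fa+cr+1)).
    """
    counts = (hits, misses, false_alarms, correct_rejections)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if hits + misses < 1 or false_alarms + correct_rejections < 1:
        raise ValueError("need at least one signal trial and one noise trial")
    hr = (hits + 0.5) / (hits + misses + 1.0)
    far = (false_alarms + 0.5) / (false_alarms + correct_rejections + 1.0)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))
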
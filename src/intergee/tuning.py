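"""Subject-level five-fold cross-validation over a (lambda1, lambda2) grid.

Folds partition subjects (all k repeated measures of a subject share a
fold) so held-out prediction error is computed on unseen clusters. The
default grid is 8 log-spaced values per dimension spanning [0.01, 1.0] on
the scale of a standardized response; when built from data it is
multiplied by the response standard deviation, which makes the grid
invariant to rescaling the response. Coarse by design for desk-scale runs
and overridable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignMatrix, LongitudinalDataset, build_design, interaction_gram
from .solver import DesignCache, FitConfig, FitResult, fit_pgee, lasso_initialize

__all__ = [
    "TuningGrid",
    "CVResult",
    "default_grid",
    "make_subject_folds",
    "prediction_error",
    "cv_select",
]

GAMMA_PROBE_SET = (1.8, 3.0, 4.5, 6.0, 10.0)


@dataclass
class TuningGrid:
    """Descending positive candidate sequences for the two tuning levels."""

    lambda1_values: np.ndarray
    lambda2_values: np.ndarray
    gamma: float = 3.0

    def __post_init__(self) -> None:
        self.lambda1_values = np.sort(np.asarray(self.lambda1_values, dtype=float))[::-1]
        self.lambda2_values = np.sort(np.asarray(self.lambda2_values, dtype=float))[::-1]
        for name, vals in (("lambda1", self.lambda1_values), ("lambda2", self.lambda2_values)):
            if vals.size == 0:
                raise ValueError(f"{name}_values must be nonempty")
            if np.any(vals <= 0):
                raise ValueError(f"{name}_values must be strictly positive")


def default_grid(y: np.ndarray | None = None, n_values: int = 8,
                 lo: float = 0.01, hi: float = 1.0, gamma: float = 3.0) -> TuningGrid:
    """Log-spaced grid on [lo, hi], scaled by sd(y) when a response is given."""
    scale = float(np.std(y)) if y is not None else 1.0
    if scale == 0.0:
        scale = 1.0
    values = np.geomspace(hi, lo, n_values) * scale
    return TuningGrid(lambda1_values=values, lambda2_values=values.copy(), gamma=gamma)


def make_subject_folds(subject_ids: np.ndarray, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic subject-level fold assignment; sizes differ by <= 1.

    Returns an integer array aligned with ``subject_ids`` giving each
    subject's fold in 0..n_folds-1.
    """
    subject_ids = np.asarray(subject_ids)
    n = subject_ids.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} subjects for {n_folds} folds, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    # First (n % n_folds) folds get the extra subject, matching balanced remainders.
    sizes = np.full(n_folds, n // n_folds)
    sizes[: n % n_folds] += 1
    start = 0
    for f, size in enumerate(sizes):
        assignment[order[start: start + size]] = f
        start += size
    return assignment


def prediction_error(fit: FitResult | np.ndarray, test_data: LongitudinalDataset,
                     test_design: DesignMatrix | None = None) -> float:
    """Mean squared prediction error over all held-out (subject, time) cells."""
    beta = fit.beta if isinstance(fit, FitResult) else np.asarray(fit, dtype=float)
    if test_design is None:
        test_design, _ = build_design(test_data)
    resid = test_data.y.reshape(-1) - test_design.Z @ beta
    return float(np.mean(resid**2))


@dataclass
class CVResult:
    """Cross-validation error surface and the winning tuning pair."""

    errors: np.ndarray              # (len(lambda1), len(lambda2)) mean CV error
    fold_errors: np.ndarray         # (n_folds, len(lambda1), len(lambda2))
    converged: np.ndarray           # same shape as fold_errors, bool
    best_lambda1: float
    best_lambda2: float
    grid: TuningGrid
    fold_assignment: np.ndarray

    @property
    def best_error(self) -> float:
        i = np.where(self.grid.lambda1_values == self.best_lambda1)[0][0]
        j = np.where(self.grid.lambda2_values == self.best_lambda2)[0][0]
        return float(self.errors[i, j])


def cv_select(
    data: LongitudinalDataset,
    grid: TuningGrid,
    cfg: FitConfig,
    seed: int = 0,
    n_folds: int = 5,
) -> CVResult:
    """Five-fold subject-level CV over the full (lambda1, lambda2) grid.

    Each training fold's design, interaction Gram matrices, cross-product
    cache, and LASSO initializer are computed once and reused across all
    grid cells. A fold fit that fails to converge still contributes its
    held-out error, flagged in ``converged``.
    """
    assignment = make_subject_folds(data.subject_ids, n_folds=n_folds, seed=seed)
    L1, L2 = grid.lambda1_values, grid.lambda2_values
    fold_errors = np.full((n_folds, L1.size, L2.size), np.nan)
    converged = np.zeros((n_folds, L1.size, L2.size), dtype=bool)
    for f in range(n_folds):
        train = data.subset(np.where(assignment != f)[0])
        test = data.subset(np.where(assignment == f)[0])
        design, _ = build_design(train)
        test_design, _ = build_design(test)
        grams = interaction_gram(design) if cfg.group_interactions else None
        cache = DesignCache(design)
        beta0 = lasso_initialize(train, design, seed=seed)
        for i, lam1 in enumerate(L1):
            for j, lam2 in enumerate(L2):
                fit = fit_pgee(
                    train, cfg.with_lambdas(lam1, lam2),
                    design=design, grams=grams, beta0=beta0, cache=cache,
                )
                fold_errors[f, i, j] = prediction_error(fit, test, test_design)
                converged[f, i, j] = fit.converged
    errors = fold_errors.mean(axis=0)
    best = np.min(errors)
    ties = np.argwhere(errors == best)
    # break exact ties toward the larger lambda1 + lambda2
    sums = L1[ties[:, 0]] + L2[ties[:, 1]]
    i, j = ties[np.argmax(sums)]
    return CVResult(
        errors=errors, fold_errors=fold_errors, converged=converged,
        best_lambda1=float(L1[i]), best_lambda2=float(L2[j]),
        grid=grid, fold_assignment=assignment,
    )
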
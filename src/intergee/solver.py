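"""Penalized GEE Newton-Raphson fitter.

Given tuning parameters, the coefficient vector is updated by

    b_new = b + (T + n W)^-1 (U - n W b),

where U is the GEE score, T = sum_i Z_i' V^-1 Z_i its derivative, and W
the diagonal MCP/group-MCP shrinkage matrix. Iterations start from a
LASSO solution on the pooled observations; the dispersion and correlation
nuisance parameters are re-estimated from the residuals at every
iteration. Convergence is declared when the L1 change in the coefficients
drops below ``tol``; near-zero estimates are then snapped to exact zeros
at the ``zero_threshold``.

The six method labels used throughout map onto (working correlation,
group-level interaction penalty): A1 = (exchangeable, on), A2 = (AR1, on),
A3 = (independence, on), A4 = (exchangeable, off), A5 = (AR1, off),
A6 = (independence, off).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .correlation import WorkingCorrelationModel, build_V_inv
from .design import DesignMatrix, GroupGram, GroupMap, LongitudinalDataset, build_design, interaction_gram
from .penalty import PenaltyConfig, build_shrinkage_matrix

__all__ = [
    "METHODS",
    "FitConfig",
    "FitResult",
    "DesignCache",
    "gee_score",
    "gee_information",
    "newton_update",
    "lasso_initialize",
    "fit_pgee",
    "sparsify",
]

logger = logging.getLogger(__name__)

# method label -> (working correlation structure, group-level interaction penalty)
METHODS: dict[str, tuple[str, bool]] = {
    "A1": ("exchangeable", True),
    "A2": ("ar1", True),
    "A3": ("independence", True),
    "A4": ("exchangeable", False),
    "A5": ("ar1", False),
    "A6": ("independence", False),
}


@dataclass
class FitConfig:
    """Everything needed to fit at one fixed tuning-parameter pair."""

    structure: str = "exchangeable"
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    group_interactions: bool = True
    max_iter: int = 50
    tol: float = 1e-3
    zero_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.zero_threshold < 0:
            raise ValueError("zero_threshold must be nonnegative")

    @classmethod
    def from_method(cls, method: str, lambda1: float = 0.0, lambda2: float = 0.0,
                    gamma: float = 3.0, **kwargs) -> "FitConfig":
        """Build a config from a method label A1..A6."""
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
        structure, grouped = METHODS[method]
        penalty = PenaltyConfig(lambda1=lambda1, lambda2=lambda2, gamma=gamma)
        return cls(structure=structure, penalty=penalty,
                   group_interactions=grouped, **kwargs)

    def with_lambdas(self, lambda1: float, lambda2: float) -> "FitConfig":
        return replace(self, penalty=replace(self.penalty, lambda1=lambda1, lambda2=lambda2))


@dataclass
class FitResult:
    """Outcome of one penalized GEE fit."""

    beta: np.ndarray            # thresholded coefficient vector
    beta_raw: np.ndarray        # last Newton iterate before thresholding
    selected: np.ndarray        # column indices with nonzero (or unpenalized) estimates
    converged: bool
    n_iter: int
    deltas: list[float]         # per-iteration L1 coefficient changes
    eta: float
    phi: float
    config: FitConfig

    @property
    def selected_mask(self) -> np.ndarray:
        mask = np.zeros(self.beta.shape[0], dtype=bool)
        mask[self.selected] = True
        return mask


class DesignCache:
    """Precomputed per-time-pair cross products so T can be assembled for
    any V^-1 in O(k^2 d^2) instead of O(n k d^2).

    ``cross[j, l] = sum_i Z_ij Z_il'`` (d x d per time pair). Falls back to
    direct accumulation when the cache would exceed ``max_bytes``.
    """

    def __init__(self, design: DesignMatrix, max_bytes: float = 6e8) -> None:
        self.design = design
        Z3 = design.Z3
        n, k, d = Z3.shape
        self.cross: np.ndarray | None = None
        if k * k * d * d * 8 <= max_bytes:
            cross = np.empty((k, k, d, d))
            for j in range(k):
                for l in range(j, k):
                    C = Z3[:, j, :].T @ Z3[:, l, :]
                    cross[j, l] = C
                    if l != j:
                        cross[l, j] = C.T
            self.cross = cross

    def information(self, V_inv: np.ndarray) -> np.ndarray:
        if self.cross is not None:
            k = V_inv.shape[0]
            d = self.cross.shape[-1]
            T = np.zeros((d, d))
            for j in range(k):
                for l in range(k):
                    T += V_inv[j, l] * self.cross[j, l]
        else:
            T = gee_information(self.design, V_inv)
        return (T + T.T) / 2.0


def gee_score(beta: np.ndarray, design: DesignMatrix, V_inv: np.ndarray,
              y: np.ndarray) -> np.ndarray:
    """GEE score U(b) = sum_i Z_i' V^-1 (Y_i - Z_i b) under the identity link."""
    n, k, d = design.n, design.k, design.d
    resid = y.reshape(n, k) - (design.Z @ beta).reshape(n, k)
    s = resid @ V_inv  # (n, k)
    return design.Z.T @ s.reshape(n * k)


def gee_information(design: DesignMatrix, V_inv: np.ndarray) -> np.ndarray:
    """T = sum_i Z_i' V^-1 Z_i; symmetric positive semidefinite and, under
    the identity link, independent of beta."""
    Z3 = design.Z3
    A = np.einsum("jl,nle->nje", V_inv, Z3)
    n, k, d = Z3.shape
    T = Z3.reshape(n * k, d).T @ A.reshape(n * k, d)
    return (T + T.T) / 2.0


def newton_update(beta: np.ndarray, U: np.ndarray, T: np.ndarray,
                  w: np.ndarray, n: int, jitter: float = 1e-10) -> np.ndarray:
    """One Newton-Raphson step b + (T + nW)^-1 (U - nW b).

    ``w`` is the diagonal of W. The system is solved by Cholesky with a
    diagonal jitter fallback; a genuinely singular system (possible at
    lambda1 = lambda2 = 0 when d exceeds the observation count) is
    rejected.
    """
    M = T + n * np.diag(w)
    rhs = U - n * w * beta
    try:
        c = cho_factor(M, lower=True, check_finite=False)
        step = cho_solve(c, rhs, check_finite=False)
    except np.linalg.LinAlgError:
        cond = np.linalg.cond(M)
        logger.debug("Cholesky failed (cond %.3e); retrying with jitter", cond)
        try:
            c = cho_factor(M + jitter * np.trace(M) / M.shape[0] * np.eye(M.shape[0]),
                           lower=True, check_finite=False)
            step = cho_solve(c, rhs, check_finite=False)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"T + nW singular (condition number {cond:.3e}); "
                "increase the penalties or reduce the dimension"
            ) from err
    return beta + step


def lasso_initialize(
    data: LongitudinalDataset,
    design: DesignMatrix | None = None,
    seed: int = 0,
    n_alphas: int = 40,
    cv: int = 5,
) -> np.ndarray:
    """Initial coefficients from L1-penalized least squares on the pooled
    observations (within-subject correlation ignored).

    The intercept and environment columns are left unpenalized: the
    response and the penalized block are first residualized against
    [1, E], the LASSO (with its own 5-fold CV over the regularization
    path) is fit on the residualized problem, and the unpenalized
    coefficients are recovered by least squares on the remainder.

    Rows are put in a canonical subject order (sorted by subject id)
    before the internal CV split, so the initializer -- and therefore the
    whole fit -- is invariant to permutations of the subject order.
    """
    if design is None:
        design, _ = build_design(data)
    order = np.argsort(data.subject_ids, kind="stable")
    Z = design.Z3[order].reshape(design.n * design.k, design.d)
    q = design.groups.q
    y = data.y[order].reshape(-1)
    beta0 = np.zeros(design.d)
    Q = Z[:, : 1 + q]
    coef_unpen, *_ = np.linalg.lstsq(Q, y, rcond=None)
    resid_y = y - Q @ coef_unpen
    if design.d == 1 + q or np.allclose(resid_y, 0.0):
        beta0[: 1 + q] = coef_unpen
        return beta0
    P = Z[:, 1 + q:]
    proj, *_ = np.linalg.lstsq(Q, P, rcond=None)
    P_res = P - Q @ proj
    if np.std(resid_y) == 0:
        beta0[: 1 + q] = coef_unpen
        return beta0
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    lasso = LassoCV(
        alphas=n_alphas, cv=folds, fit_intercept=False,
        max_iter=5000, tol=1e-4, random_state=seed,
    )
    lasso.fit(P_res, resid_y)
    beta_pen = lasso.coef_
    coef_unpen, *_ = np.linalg.lstsq(Q, y - P @ beta_pen, rcond=None)
    beta0[: 1 + q] = coef_unpen
    beta0[1 + q:] = beta_pen
    return beta0


def sparsify(beta: np.ndarray, tau: float, groups: GroupMap) -> tuple[np.ndarray, np.ndarray]:
    """Zero entries with |b| < tau and return (thresholded beta, selected
    column indices). The intercept and environment columns are never
    thresholded and always count as selected."""
    beta = np.asarray(beta, dtype=float).copy()
    pen = np.arange(1 + groups.q, groups.d)
    small = pen[np.abs(beta[pen]) < tau]
    beta[small] = 0.0
    selected = np.concatenate([np.arange(1 + groups.q), pen[beta[pen] != 0.0]])
    return beta, selected


def fit_pgee(
    data: LongitudinalDataset,
    cfg: FitConfig,
    design: DesignMatrix | None = None,
    grams: GroupGram | None = None,
    beta0: np.ndarray | None = None,
    cache: DesignCache | None = None,
    lasso_seed: int = 0,
) -> FitResult:
    """Fit the penalized GEE at fixed tuning parameters.

    ``design``, ``grams``, ``cache`` and ``beta0`` may be precomputed and
    shared across fits on the same data (cross-validation reuses them
    across the tuning grid); they are derived from ``data`` when omitted.
    """
    if design is None:
        design, _ = build_design(data)
    groups = design.groups
    if cfg.group_interactions and grams is None:
        grams = interaction_gram(design)
    if beta0 is None:
        beta0 = lasso_initialize(data, design, seed=lasso_seed)
    if cache is None:
        cache = DesignCache(design)
    y = data.y.reshape(-1)
    n, k = design.n, design.k

    beta = np.asarray(beta0, dtype=float).copy()
    deltas: list[float] = []
    converged = False
    eta = 0.0
    phi = 1.0
    for it in range(cfg.max_iter):
        resid = (y - design.Z @ beta).reshape(n, k)
        model = WorkingCorrelationModel.from_residuals(resid, cfg.structure)
        eta, phi = model.eta, model.phi
        V_inv = build_V_inv(model)
        U = gee_score(beta, design, V_inv, y)
        T = cache.information(V_inv)
        w = build_shrinkage_matrix(
            beta, groups, cfg.penalty, grams=grams,
            group_interactions=cfg.group_interactions,
        )
        beta_new = newton_update(beta, U, T, w, n)
        delta = float(np.abs(beta_new - beta).sum())
        deltas.append(delta)
        beta = beta_new
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning("pGEE did not converge in %d iterations (last L1 delta %.3e)",
                       cfg.max_iter, deltas[-1] if deltas else float("nan"))
    beta_hat, selected = sparsify(beta, cfg.zero_threshold, groups)
    return FitResult(
        beta=beta_hat, beta_raw=beta, selected=selected,
        converged=converged, n_iter=len(deltas), deltas=deltas,
        eta=eta, phi=phi, config=cfg,
    )
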
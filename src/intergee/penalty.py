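"""Minimax concave penalty (MCP), its group form, and the shrinkage matrix W.

MCP applies LASSO-like shrinkage near zero and none beyond ``t = gamma *
lambda``, which keeps large estimates nearly unbiased. Main-effect
coefficients are penalized individually at level ``lambda1``; each
feature's q interaction coefficients are penalized as a group through the
empirical norm ||b||_Sigma at level ``q * lambda2``. The Newton step uses
the local quadratic approximation ``n * W``, a diagonal matrix with entry
``rho'(|b|) / (eps + |b|)`` per penalized coordinate; intercept and
environment columns are never shrunk.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import GroupGram, GroupMap, group_empirical_norms

__all__ = ["PenaltyConfig", "mcp_value", "mcp_deriv", "build_shrinkage_matrix"]


@dataclass
class PenaltyConfig:
    """Tuning parameters of the two-level penalty.

    lambda1 : individual-level tuning for main feature effects (>= 0).
    lambda2 : group-level tuning for interaction groups (>= 0); the group
        penalty level is q * lambda2 (``group_scale="sqrt_q"`` switches to
        sqrt(q) * lambda2 for sensitivity checks).
    gamma : MCP regularization parameter (> 1), default 3.
    epsilon : ridge stabilizer in the W denominators, default 1e-6.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    gamma: float = 3.0
    epsilon: float = 1e-6
    group_scale: str = "q"

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.group_scale not in ("q", "sqrt_q"):
            raise ValueError("group_scale must be 'q' or 'sqrt_q'")

    def group_lambda(self, q: int) -> float:
        scale = q if self.group_scale == "q" else float(np.sqrt(q))
        return scale * self.lambda2


def _check_nonneg(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("MCP is evaluated at magnitudes; t must be >= 0")
    return t


def mcp_value(t, lam: float, gamma: float):
    """MCP rho(t; lambda, gamma) = lambda * t - t^2/(2 gamma) for
    t <= gamma*lambda, saturating at gamma*lambda^2/2 beyond."""
    t = _check_nonneg(t)
    out = np.where(
        t <= gamma * lam,
        lam * t - t**2 / (2.0 * gamma),
        gamma * lam**2 / 2.0,
    )
    return out if out.ndim else float(out)


def mcp_deriv(t, lam: float, gamma: float):
    """MCP derivative rho'(t) = (lambda - t/gamma) for t <= gamma*lambda,
    zero beyond the saturation point."""
    t = _check_nonneg(t)
    out = np.where(t <= gamma * lam, lam - t / gamma, 0.0)
    return out if out.ndim else float(out)


def build_shrinkage_matrix(
    beta: np.ndarray,
    groups: GroupMap,
    cfg: PenaltyConfig,
    grams: GroupGram | None = None,
    group_interactions: bool = True,
) -> np.ndarray:
    """Diagonal of the shrinkage matrix W for the current coefficients.

    The first 1 + q entries (intercept, environment dummies) are zero.
    Main-effect entries are rho'(|b|; lambda1, gamma) / (eps + |b|). With
    ``group_interactions`` on, every column of interaction group h carries
    rho'(||b_3h||_Sigma_h; q*lambda2, gamma) / (eps + ||b_3h||_Sigma_h);
    with it off, each interaction column is penalized individually at
    level lambda2.

    Returns the diagonal as a length-d vector.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (groups.d,):
        raise ValueError(f"beta has length {beta.shape}, expected ({groups.d},)")
    w = np.zeros(groups.d)
    t_main = np.abs(beta[groups.main_cols])
    w[groups.main_cols] = mcp_deriv(t_main, cfg.lambda1, cfg.gamma) / (cfg.epsilon + t_main)
    if groups.p == 0:
        return w
    if group_interactions:
        if grams is None:
            raise ValueError("group-level penalty requires the interaction Gram matrices")
        norms = group_empirical_norms(beta, groups, grams)  # (p,)
        lam_g = cfg.group_lambda(groups.q)
        w_group = mcp_deriv(norms, lam_g, cfg.gamma) / (cfg.epsilon + norms)
        w[groups.group_col_matrix] = w_group[:, None]
    else:
        t_int = np.abs(beta[groups.inter_cols])
        w[groups.inter_cols] = mcp_deriv(t_int, cfg.lambda2, cfg.gamma) / (cfg.epsilon + t_int)
    return w
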
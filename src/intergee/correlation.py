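"""Working-correlation machinery for the Gaussian identity-link GEE.

The marginal model has constant variance, so the subject covariance is
``V = phi * R(eta)`` with dispersion ``phi`` and a working correlation
``R(eta)`` that is independence, exchangeable, or AR(1). ``phi`` and
``eta`` are Liang-Zeger moment estimates from the current residuals;
denominators are raw pair counts (no degrees-of-freedom correction, since
the coefficient dimension can exceed the number of observations).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "STRUCTURES",
    "WorkingCorrelationModel",
    "estimate_dispersion",
    "estimate_eta",
    "build_R",
    "build_V_inv",
]

STRUCTURES = ("independence", "exchangeable", "ar1")

PHI_FLOOR = 1e-8


def _check_structure(structure: str) -> None:
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {STRUCTURES}")


@dataclass
class WorkingCorrelationModel:
    """Working covariance V = phi * R(eta) for one cluster of size k."""

    structure: str
    eta: float
    phi: float
    k: int

    def __post_init__(self) -> None:
        _check_structure(self.structure)
        if self.structure == "independence" and self.eta != 0.0:
            raise ValueError("independence structure forces eta = 0")
        if not abs(self.eta) < 1.0:
            raise ValueError(f"|eta| must be < 1, got {self.eta}")

    @classmethod
    def from_residuals(cls, residuals: np.ndarray, structure: str) -> "WorkingCorrelationModel":
        """Moment-estimate phi and eta from an (n, k) residual matrix."""
        residuals = np.asarray(residuals, dtype=float)
        phi = estimate_dispersion(residuals)
        eta = estimate_eta(residuals, structure, phi=phi)
        return cls(structure=structure, eta=eta, phi=phi, k=residuals.shape[1])


def estimate_dispersion(residuals: np.ndarray) -> float:
    """Moment estimate phi = sum(r^2) / (n*k) of the common variance.

    Returns exactly 0.0 for all-zero residuals; callers substitute a small
    floor (1e-8) before inverting V.
    """
    residuals = np.asarray(residuals, dtype=float)
    return float(np.mean(residuals**2))


def estimate_eta(residuals: np.ndarray, structure: str, phi: float | None = None) -> float:
    """Moment estimate of the working-correlation parameter.

    exchangeable : average standardized product over all within-subject
        pairs j < j' (denominator n*k(k-1)/2).
    ar1 : average over adjacent pairs (denominator n*(k-1)).

    The result is clipped to [-0.99, 0.99]; the exchangeable estimate is
    additionally floored just above -1/(k-1) so R(eta) stays positive
    definite.
    """
    _check_structure(structure)
    if structure == "independence":
        return 0.0
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    n, k = residuals.shape
    if k < 2:
        raise ValueError(f"structure {structure!r} needs k >= 2 time points, got k={k}")
    if phi is None:
        phi = estimate_dispersion(residuals)
    phi = max(phi, PHI_FLOOR)
    r = residuals / np.sqrt(phi)
    if structure == "exchangeable":
        # sum over pairs j<j' via (sum_j r)^2 - sum_j r^2
        pair_sum = ((r.sum(axis=1) ** 2 - (r**2).sum(axis=1)) / 2.0).sum()
        eta = pair_sum / (n * k * (k - 1) / 2.0)
        lower = max(-0.99, -1.0 / (k - 1) + 1e-3)
        return float(np.clip(eta, lower, 0.99))
    # ar1
    eta = (r[:, :-1] * r[:, 1:]).sum() / (n * (k - 1))
    return float(np.clip(eta, -0.99, 0.99))


def build_R(structure: str, eta: float, k: int) -> np.ndarray:
    """The k x k working correlation matrix R(eta)."""
    _check_structure(structure)
    if structure != "independence" and not abs(eta) < 1.0:
        raise ValueError(f"|eta| must be < 1, got {eta}")
    if structure == "independence":
        return np.eye(k)
    if structure == "exchangeable":
        return np.full((k, k), eta) + (1.0 - eta) * np.eye(k)
    # ar1: eta^|j - j'|
    return toeplitz(eta ** np.arange(k))


def build_V_inv(model: WorkingCorrelationModel, max_cond: float = 1e12) -> np.ndarray:
    """Inverse working covariance (phi * R(eta))^-1, shared by all subjects.

    The design is balanced with constant marginal variance, so one k x k
    inverse serves every cluster. A near-singular R is rejected with its
    condition number.
    """
    R = build_R(model.structure, model.eta, model.k)
    phi = max(model.phi, PHI_FLOOR)
    V = phi * R
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > max_cond:
        raise np.linalg.LinAlgError(
            f"working covariance numerically singular (condition number {cond:.3e})"
        )
    V_inv = np.linalg.inv(V)
    return (V_inv + V_inv.T) / 2.0
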
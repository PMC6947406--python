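"""Design-matrix construction for longitudinal feature-environment interaction models.

The marginal model is

    Y_ij = beta0 + E_ij' b1 + X_ij' b2 + (X_ij (x) E_ij)' b3 + eps_ij,

where ``X_ij`` holds the p continuous features (e.g. lipid species) of
subject i at time j, ``E_ij`` holds q binary environment/treatment dummies,
and ``(x)`` is the Kronecker product, so the interaction block has pq
columns ordered feature-major, dummy-minor:
``x1*e1, x1*e2, ..., x1*eq, x2*e1, ..., xp*eq``.

Each feature's q interaction coefficients form a group that is selected or
dropped as a unit by the group penalty; the group metric is the empirical
Gram matrix of the group's design columns.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LongitudinalDataset",
    "DesignMatrix",
    "GroupMap",
    "GroupGram",
    "build_design",
    "interaction_gram",
    "group_empirical_norm",
]


@dataclass
class LongitudinalDataset:
    """Balanced repeated-measures data: n subjects, k times each.

    Parameters
    ----------
    y : ndarray of shape (n, k)
        Continuous response per (subject, time).
    X : ndarray of shape (n, k, p)
        Feature values (p continuous features).
    E : ndarray of shape (n, k, q)
        Environment dummy codes, each entry in {0, 1}.
    subject_ids : ndarray of shape (n,), optional
        Stable ordering key; defaults to 0..n-1.
    """

    y: np.ndarray
    X: np.ndarray
    E: np.ndarray
    subject_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.X = np.asarray(self.X, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must have shape (n, k)")
        n, k = self.y.shape
        if self.X.ndim != 3 or self.X.shape[:2] != (n, k):
            raise ValueError(f"X must have shape (n, k, p) = ({n}, {k}, p)")
        if self.E.ndim != 3 or self.E.shape[:2] != (n, k):
            raise ValueError(f"E must have shape (n, k, q) = ({n}, {k}, q)")
        if self.subject_ids is None:
            self.subject_ids = np.arange(n)
        else:
            self.subject_ids = np.asarray(self.subject_ids)
            if self.subject_ids.shape != (n,):
                raise ValueError("subject_ids must have shape (n,)")
        for name, arr in (("y", self.y), ("X", self.X), ("E", self.E)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing or non-finite values")
        if not np.isin(self.E, (0.0, 1.0)).all():
            raise ValueError("E entries must be binary (0/1)")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.y.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[2]

    @property
    def q(self) -> int:
        return self.E.shape[2]

    def subset(self, idx) -> "LongitudinalDataset":
        """Dataset restricted to the subjects in ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return LongitudinalDataset(
            y=self.y[idx], X=self.X[idx], E=self.E[idx],
            subject_ids=self.subject_ids[idx],
        )


@dataclass
class GroupMap:
    """Column bookkeeping: one main-effect column and one q-column
    interaction group per feature.

    Columns are 0-based: intercept at 0, environment dummies at
    ``1..q``, main effects at ``1+q..q+p``, and the interaction group of
    feature h (0-based) at ``1+q+p+h*q .. 1+q+p+(h+1)*q - 1``.
    """

    p: int
    q: int

    @property
    def d(self) -> int:
        return 1 + self.q + self.p + self.p * self.q

    @property
    def env_cols(self) -> np.ndarray:
        return np.arange(1, 1 + self.q)

    @property
    def main_cols(self) -> np.ndarray:
        return np.arange(1 + self.q, 1 + self.q + self.p)

    @property
    def inter_cols(self) -> np.ndarray:
        return np.arange(1 + self.q + self.p, self.d)

    def group_cols(self, h: int) -> np.ndarray:
        """Interaction-group columns of feature ``h`` (0-based)."""
        if not 0 <= h < self.p:
            raise IndexError(f"feature index {h} out of range [0, {self.p})")
        start = 1 + self.q + self.p + h * self.q
        return np.arange(start, start + self.q)

    @property
    def group_col_matrix(self) -> np.ndarray:
        """(p, q) array; row h holds the columns of feature h's group."""
        return self.inter_cols.reshape(self.p, self.q)


@dataclass
class DesignMatrix:
    """Stacked design: Z has n*k rows (subject-major, then time) and
    width d = 1 + q + p + pq."""

    Z: np.ndarray
    n: int
    k: int
    groups: GroupMap

    @property
    def d(self) -> int:
        return self.Z.shape[1]

    @property
    def Z3(self) -> np.ndarray:
        """Per-subject view of shape (n, k, d)."""
        return self.Z.reshape(self.n, self.k, self.d)


@dataclass
class GroupGram:
    """Per-feature q x q empirical Gram matrices Sigma_h = B_h' B_h / n."""

    grams: np.ndarray  # (p, q, q)
    divisor: int

    def __getitem__(self, h: int) -> np.ndarray:
        return self.grams[h]


def build_design(data: LongitudinalDataset) -> tuple[DesignMatrix, GroupMap]:
    """Stack the (1, E, X, X(x)E) rows for all subjects and times.

    Raises for an empty dataset and for q = 0 (the interaction block is
    undefined without environment dummies). p = 0 is allowed and yields a
    width of 1 + q with no feature or interaction columns.
    """
    if data.n == 0 or data.k == 0:
        raise ValueError("empty dataset: no subjects or no time points")
    if data.q == 0:
        raise ValueError("q = 0: interaction model requires environment dummies")
    n, k, p, q = data.n, data.k, data.p, data.q
    ones = np.ones((n, k, 1))
    # Kronecker expansion per row, feature-major then dummy-minor.
    inter = np.einsum("nkp,nkq->nkpq", data.X, data.E).reshape(n, k, p * q)
    Z = np.concatenate([ones, data.E, data.X, inter], axis=2).reshape(n * k, -1)
    groups = GroupMap(p=p, q=q)
    assert Z.shape[1] == groups.d
    return DesignMatrix(Z=Z, n=n, k=k, groups=groups), groups


def interaction_gram(
    design: DesignMatrix, groups: GroupMap | None = None, divisor: str = "n"
) -> GroupGram:
    """Empirical Gram Sigma_h = B_h' B_h / n for every interaction group.

    ``B_h`` stacks all n*k rows of feature h's q interaction columns. The
    divisor is the subject count n by default; ``divisor="nk"`` uses the
    row count n*k instead (a per-observation scaling useful for
    sensitivity checks).
    """
    if groups is None:
        groups = design.groups
    if divisor == "n":
        denom = design.n
    elif divisor == "nk":
        denom = design.n * design.k
    else:
        raise ValueError("divisor must be 'n' or 'nk'")
    B = design.Z[:, groups.inter_cols].reshape(-1, groups.p, groups.q)
    grams = np.einsum("mhq,mhr->hqr", B, B) / denom
    return GroupGram(grams=grams, divisor=denom)


def group_empirical_norm(beta_group: np.ndarray, gram: np.ndarray) -> float:
    """Empirical norm ||b||_Sigma = sqrt(b' Sigma b) of a group coefficient.

    A (numerically) negative quadratic form is clamped to zero with a
    warning; Sigma is nonnegative definite in exact arithmetic.
    """
    beta_group = np.asarray(beta_group, dtype=float)
    quad = float(beta_group @ np.asarray(gram, dtype=float) @ beta_group)
    if quad < 0:
        if quad < -1e-10:
            warnings.warn(
                f"negative quadratic form {quad:.3e} clamped to 0", RuntimeWarning
            )
        quad = 0.0
    return float(np.sqrt(quad))


def group_empirical_norms(beta: np.ndarray, groups: GroupMap, grams: GroupGram) -> np.ndarray:
    """Vector of ||b_3h||_Sigma_h over all p interaction groups."""
    B = beta[groups.group_col_matrix]  # (p, q)
    quad = np.einsum("hq,hqr,hr->h", B, grams.grams, B)
    return np.sqrt(np.clip(quad, 0.0, None))
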
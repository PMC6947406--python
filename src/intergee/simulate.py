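"""Synthetic longitudinal datasets with feature-environment interactions.

The generator emulates a weight-control lipidomics study: each subject
carries one feature profile (p correlated continuous features, AR1
cross-feature correlation) and one treatment assignment (a 4-level factor
coded as q = 3 baseline-contrast dummies), both constant over the k
repeated measures; responses follow the linear interaction model with
within-subject AR1 Gaussian errors of unit marginal variance.

Truth modes
-----------
interactions : intercept, the q environment dummies, 4 feature main
    effects, and 3 complete interaction groups (3q coefficients) are
    nonzero -- 17 nonzero coefficients at q = 3. Magnitudes are drawn
    from U[coef_low, coef_high] (default U[0.4, 0.8]; the case-study
    scale uses U[1.4, 1.8]).
main_only_8 : eight feature main effects (plus intercept and environment
    terms), no interactions; used to probe behaviour under a misspecified
    interaction search.
null : every coefficient is zero; the response is pure noise.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, toeplitz

from .design import LongitudinalDataset, GroupMap, build_design

__all__ = ["SimulationDesign", "SimulationTruth", "truth_vector", "simulate_dataset"]

TRUTH_MODES = ("interactions", "main_only_8", "null")
E_MODES = ("quartile-4level", "tercile-3level")

N_TRUE_MAINS = 4
N_TRUE_GROUPS = 3
N_TRUE_MAINS_MAIN_ONLY = 8


@dataclass
class SimulationDesign:
    """Study conditions for one synthetic dataset.

    rho_error : within-subject AR1 error correlation (0.5 or 0.8 in the
        standard settings).
    rho_X : AR1 cross-feature correlation of the feature profile.
    coef_low, coef_high : support of the uniform draw for nonzero
        coefficients (0.4/0.8 default; 1.4/1.8 at the case-study scale).
    E_mode : "quartile-4level" (default) cuts a latent standard normal at
        its 25th/50th/75th percentiles into a 4-level factor coded as 3
        baseline-contrast dummies. "tercile-3level" cuts at the 30th/70th
        percentiles and one-hot codes all three categories, which is rank
        deficient alongside an intercept and kept only for sensitivity
        checks.
    placement : "random" (default) draws the true-effect positions
        uniformly without replacement from the p features, so true effects
        are not systematically placed on neighbouring (hence correlated)
        features; "first" pins them to the leading features, which keeps
        truth indices fixed across replicates but makes the true effects
        mutually correlated under the AR1 feature covariance.
    X_mode : "subject" (default) draws one feature profile per subject and
        repeats it across the k time points (a single assay per animal);
        "time-varying" draws a fresh profile at every time point.
    """

    n: int = 250
    p: int = 75
    k: int = 5
    q: int = 3
    rho_error: float = 0.5
    rho_X: float = 0.5
    coef_low: float = 0.4
    coef_high: float = 0.8
    truth_mode: str = "interactions"
    E_mode: str = "quartile-4level"
    placement: str = "random"
    X_mode: str = "subject"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.k, self.p, self.q) <= 0:
            raise ValueError("n, k, p, q must be positive")
        for name, rho in (("rho_error", self.rho_error), ("rho_X", self.rho_X)):
            if not 0 <= rho < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rho}")
        if self.truth_mode not in TRUTH_MODES:
            raise ValueError(f"truth_mode must be one of {TRUTH_MODES}")
        if self.E_mode not in E_MODES:
            raise ValueError(f"E_mode must be one of {E_MODES}")
        if self.placement not in ("first", "random"):
            raise ValueError("placement must be 'first' or 'random'")
        if self.X_mode not in ("time-varying", "subject"):
            raise ValueError("X_mode must be 'time-varying' or 'subject'")
        if self.E_mode == "quartile-4level" and self.q != 3:
            raise ValueError("quartile-4level environment coding requires q = 3")

    @property
    def d(self) -> int:
        return 1 + self.q + self.p + self.p * self.q


@dataclass
class SimulationTruth:
    """True coefficient vector and the indices of its nonzero effects."""

    beta: np.ndarray
    true_main_features: np.ndarray    # feature indices (0-based) with nonzero mains
    true_group_features: np.ndarray   # feature indices with nonzero interaction groups
    groups: GroupMap

    @property
    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.beta))

    @property
    def true_main_cols(self) -> np.ndarray:
        return self.groups.main_cols[self.true_main_features]

    @property
    def true_inter_cols(self) -> np.ndarray:
        if self.true_group_features.size == 0:
            return np.empty(0, dtype=int)
        return np.concatenate(
            [self.groups.group_cols(h) for h in self.true_group_features]
        )


def _ar1_chol(rho: float, m: int) -> np.ndarray:
    return cholesky(toeplitz(rho ** np.arange(m)), lower=True)


def truth_vector(design: SimulationDesign,
                 rng: np.random.Generator | None = None) -> SimulationTruth:
    """Draw the sparse true coefficient vector for the given study design."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    groups = GroupMap(p=design.p, q=design.q)
    beta = np.zeros(groups.d)
    if design.truth_mode == "null":
        return SimulationTruth(
            beta=beta,
            true_main_features=np.empty(0, dtype=int),
            true_group_features=np.empty(0, dtype=int),
            groups=groups,
        )
    n_mains = (N_TRUE_MAINS_MAIN_ONLY if design.truth_mode == "main_only_8"
               else N_TRUE_MAINS)
    n_groups = 0 if design.truth_mode == "main_only_8" else N_TRUE_GROUPS
    if design.p < max(n_mains, n_groups):
        raise ValueError(
            f"p = {design.p} too small for {n_mains} true mains and "
            f"{n_groups} true interaction groups"
        )
    if design.placement == "first":
        mains = np.arange(n_mains)
        grp = np.arange(n_groups)
    else:
        mains = np.sort(rng.choice(design.p, size=n_mains, replace=False))
        grp = np.sort(rng.choice(design.p, size=n_groups, replace=False))

    def draw(size: int) -> np.ndarray:
        return rng.uniform(design.coef_low, design.coef_high, size=size)

    beta[0] = draw(1)[0]
    beta[groups.env_cols] = draw(design.q)
    beta[groups.main_cols[mains]] = draw(n_mains)
    for h in grp:
        beta[groups.group_cols(h)] = draw(design.q)
    return SimulationTruth(
        beta=beta, true_main_features=mains, true_group_features=grp, groups=groups,
    )


def _environment_dummies(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Per-subject (n, q) dummy codes from a latent standard normal."""
    latent = rng.standard_normal(design.n)
    if design.E_mode == "quartile-4level":
        cuts = np.quantile(latent, [0.25, 0.50, 0.75])
        level = np.digitize(latent, cuts)  # 0..3; level 0 is the baseline arm
        E = np.zeros((design.n, design.q))
        for l in range(1, 4):
            E[:, l - 1] = (level == l).astype(float)
        return E
    # tercile-3level: cut at the 30th/70th percentiles, one-hot all three
    # categories (sums to one, hence collinear with an intercept).
    warnings.warn(
        "tercile-3level one-hot coding is rank deficient with an intercept; "
        "intended for sensitivity checks only",
        UserWarning,
    )
    cuts = np.quantile(latent, [0.30, 0.70])
    level = np.digitize(latent, cuts)  # 0..2
    E = np.zeros((design.n, design.q))
    for l in range(min(3, design.q)):
        E[:, l] = (level == l).astype(float)
    return E


def simulate_dataset(
    design: SimulationDesign,
    truth: SimulationTruth | None = None,
) -> tuple[LongitudinalDataset, SimulationTruth]:
    """Generate one dataset (and its truth) reproducibly from the seed.

    Features are drawn from N(0, AR1(rho_X)) with unit marginal variance,
    once per subject under the default X_mode and fresh at every
    (subject, time) under ``X_mode="time-varying"``. The treatment
    assignment is constant over time. Errors are k-variate
    N(0, AR1(rho_error)) per subject. The response is Z beta_true + error.
    """
    rng = np.random.default_rng(design.seed)
    if truth is None:
        truth = truth_vector(design, rng)
    n, k, p, q = design.n, design.k, design.p, design.q

    if design.X_mode == "time-varying":
        X = rng.standard_normal((n, k, p)) @ _ar1_chol(design.rho_X, p).T
    else:
        X_subj = rng.standard_normal((n, p)) @ _ar1_chol(design.rho_X, p).T
        X = np.repeat(X_subj[:, None, :], k, axis=1)
    E_subj = _environment_dummies(design, rng)
    E = np.repeat(E_subj[:, None, :], k, axis=1)
    eps = rng.standard_normal((n, k)) @ _ar1_chol(design.rho_error, k).T

    data = LongitudinalDataset(y=np.zeros((n, k)), X=X, E=E)
    dm, _ = build_design(data)
    y = (dm.Z @ truth.beta).reshape(n, k) + eps
    data = LongitudinalDataset(y=y, X=X, E=E)
    if design.d >= n * k:
        import logging

        logging.getLogger(__name__).info(
            "high-dimensional regime: d = %d >= n*k = %d", design.d, n * k
        )
    return data, truth
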
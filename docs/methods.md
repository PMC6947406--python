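# Methods

`intergee` selects main effects and grouped feature–environment
interactions from high-dimensional longitudinal data by solving a
penalized generalized estimating equation (GEE). This note records the
model, the algorithm, the synthetic-data generator, and the numerical and
design choices a maintainer would want to know about.

## Model

For subject i = 1..n observed at j = 1..k times,

    Y_ij = b0 + E_ij' b1 + X_ij' b2 + (X_ij ⊗ E_ij)' b3 + e_ij
         = Z_ij' b + e_ij,

with p continuous features X_ij (e.g. lipid species), q binary
environment/treatment dummies E_ij, and the Kronecker product supplying
the pq interaction columns (feature-major, dummy-minor). The stacked
design width is d = 1 + q + p + pq. Repeated measures within a subject
are dependent; subjects are independent. The marginal model is Gaussian
with identity link and constant variance, so the working covariance of a
cluster is V = phi * R(eta) with dispersion phi and a working correlation
R(eta) that is independence, exchangeable, or AR(1). GEE estimates remain
consistent when R is misspecified, which is why the package exposes all
three structures as interchangeable method variants.

## Penalized estimating equation

The score U(b) = sum_i Z_i' V^-1 (Y_i - Z_i b) is penalized at two
levels:

* main feature effects individually, by the minimax concave penalty
  (MCP) rho(t; lambda1, gamma);
* each feature's q interaction coefficients as a group, by MCP applied
  to the empirical norm ||b_3h||_Sigma_h = sqrt(b_3h' Sigma_h b_3h) at
  level q * lambda2, where Sigma_h = B_h' B_h / n and B_h stacks the
  group's n*k design rows.

The intercept and the q environment terms are never penalized: the
treatment factor is designed into the study and is not subject to
selection. Grouping reflects how the dummies are built — a feature either
interacts with the treatment factor or it does not, so its q interaction
coefficients should enter or leave together. The benchmark variants that
penalize interaction coefficients individually (no group structure) are
retained for comparison; the method roster is A1/A2/A3 = grouped with
exchangeable/AR(1)/independence working correlation and A4/A5/A6 = the
individual-penalty counterparts.

MCP is used because it applies LASSO-like shrinkage near zero but none
beyond t = gamma*lambda, keeping large coefficients nearly unbiased. The
regularization parameter gamma defaults to 3; the probe set
{1.8, 3, 4.5, 6, 10} is exposed for sensitivity runs.

## Algorithm

Newton–Raphson with a local quadratic approximation of the penalty:

    b_(d+1) = b_(d) + [T + n W]^-1 [U - n W b_(d)],

with T = sum_i Z_i' V^-1 Z_i and W diagonal with entries
rho'(|b_j|)/(eps + |b_j|) per penalized coordinate (group coordinates
share rho'(||b_3h||_Sigma_h; q lambda2, gamma)/(eps + ||b_3h||_Sigma_h)).
eps = 1e-6 stabilizes vanishing denominators. Iterations start from a
LASSO solution on the pooled n*k observations (within-subject correlation
ignored; its own internal five-fold CV chooses the L1 level; intercept
and environment columns unpenalized via residualization). phi and eta are
re-estimated from the current residuals at every iteration by Liang–Zeger
moment estimators with raw-count denominators (n*k, n*k(k-1)/2, n(k-1));
no degrees-of-freedom correction is applied because d can exceed n*k.
Convergence is declared when the L1 change in b drops below tol = 1e-3
(max_iter = 50, non-convergence flagged and the last iterate returned).

A consequence of the eps-stabilized approximation worth knowing: a
coordinate whose current value is exactly zero carries penalty weight
lambda/eps, so it stays (numerically) at zero. The Newton iterations
therefore prune and re-weight the LASSO support rather than growing it —
except that a grouped interaction column can re-enter whenever any member
of its group keeps the group norm away from zero. This is the mechanism
by which the grouped variants recover complete interaction groups that
the individual-penalty variants pick up only partially.

Because the update never produces exact zeros, estimates with
|b| < tau = 1e-3 are snapped to zero after convergence; tau matches the
convergence tolerance scale. The intercept and environment columns are
never thresholded.

Numerical choices: T + nW is solved by Cholesky with a one-shot
relative diagonal jitter (1e-10 * mean diagonal) fallback; a genuinely
singular system (lambda1 = lambda2 = 0 with d > n*k) is rejected with its
condition number. The k x k working covariance is inverted directly; a
condition number above 1e12 is rejected. The exchangeable eta estimate is
floored just above -1/(k-1) (positive definiteness), on top of the
[-0.99, 0.99] clip shared by all structures. Sigma_h uses the subject
count n as divisor exactly as the estimating-equation formulation states,
even though B_h has n*k rows; a per-observation divisor n*k is exposed as
an option for sensitivity checks. The group penalty level is q * lambda2
(literal), with sqrt(q) * lambda2 available as an option.

## Tuning

Five-fold cross-validation at the subject level (all k rows of a subject
share a fold) over a two-dimensional (lambda1, lambda2) grid; the loss is
held-out mean squared prediction error, and the winning pair attains the
minimal mean error (exact ties broken toward the larger lambda1+lambda2).
The default grid has 8 log-spaced values per dimension spanning
[0.01, 1.0] on the scale of a standardized response (i.e. multiplied by
sd(y)), which makes tuning invariant to rescaling the response. The grid
is deliberately coarse — a desk-scale default meant to be overridden for
serious analyses. Replicate studies can either re-run CV per replicate or
run a pilot CV and fix the winner for the rest ("pilot" mode); the
replicate harness defaults to pilot mode, which is what the packaged
studies use.

Pilot mode averages the CV error surface over the first few replicate
datasets (default 3) before taking the argmin. The reason is a
degeneracy specific to this design: with one feature profile per subject
every design column is constant within subject, so when d approaches or
exceeds n the model can trade a complete interaction group for a "proxy"
main effect on the same feature (the main absorbs the
average-over-arms slope) at almost no cost in held-out prediction error.
On a single pilot dataset the all-groups-dropped model can tie the
correct model to within fold noise, and a one-replicate pilot then fixes
a degenerate tuning pair for the entire study. Averaging over three
pilot surfaces resolves the tie in favour of the truly
better-predicting regime while keeping the fixed-tuning timing
behaviour.

Known limitation: prediction-error CV is only loosely aligned with
support recovery for nonconvex penalties. The error surface is typically
flat across a range of (lambda1, lambda2) whose selection behaviour
differs a lot, and on the coarse default grid the argmin regularly admits
more false positives (smaller lambda1) or drops more interaction groups
(larger lambda2) than the best grid cell would. The replicate harness
reports both identification and estimation metrics so this gap is
visible rather than hidden.

## Synthetic data

The generator emulates a weight-control rodent lipidomics study: n
animals in four treatment arms, body weight recorded at k = 5 times, one
lipid profile per animal.

* Features: p-variate normal, mean zero, AR1(rho_X = 0.5) covariance
  with unit marginal variance; one draw per subject, repeated across the
  k times (`X_mode="time-varying"` draws fresh profiles per time point).
* Environment: a latent standard normal per subject cut at its empirical
  quartiles gives a 4-level factor; the lowest level is the baseline and
  q = 3 one-hot dummies encode the rest. This mirrors a four-arm design
  and avoids the exact collinearity (dummies summing to the intercept)
  that a three-category one-hot coding produces; that literal coding is
  kept as `E_mode="tercile-3level"` with a warning, for sensitivity use
  only.
* Errors: k-variate normal per subject, AR1(rho_error in {0.5, 0.8}),
  unit marginal variance.
* Truth: in `interactions` mode the intercept, the q environment terms,
  4 feature mains, and 3 complete interaction groups are nonzero (17
  nonzero coefficients at q = 3), with magnitudes U[0.4, 0.8]
  (U[1.4, 1.8] at the case-study scale n = 60, p = 30). `main_only_8`
  has eight true mains and no interactions (misspecified-search probe);
  `null` has no signal at all.
* Placement: the positions of true mains and true interaction groups are
  drawn uniformly without replacement (seeded). This is deliberate: with
  AR1 feature correlation, pinning the true effects to the first columns
  makes them mutually correlated (adjacent features at r = 0.5), and the
  nonconvex group fit then shows winner-takes-all behaviour — one of the
  correlated true groups absorbs the others' signal with inflated
  coefficients while the rest are dropped. That is a statement about
  correlated truths, not about the estimator's behaviour under the
  intended sparse design, so the default decorrelates the truth
  placement; `placement="first"` reproduces the correlated variant.

What the generator does not emulate: real lipid concentration scales and
detection limits, panel sizes beyond p, unbalanced designs, missing
visits, or time-varying treatment. Passing the packaged studies therefore
says the estimator recovers sparse grouped signals under Gaussian AR1
longitudinal noise at these sizes — not that it handles real-data
pathologies.

## Metrics and study harness

A coefficient counts as selected iff its post-threshold estimate is
nonzero. TP/FP are counted per coefficient over penalized columns (a
partially recovered group contributes fractionally, so interaction TP
runs to 3q = 9). The unpenalized intercept/environment terms are excluded
from FP everywhere; the *inclusive* TP convention credits them when truly
nonzero (headline tables, TP up to 17), the *exclusive* convention counts
penalized columns only — both are reported. MSE/NMSE are mean squared
coefficient errors over truly nonzero / truly zero coordinates; TMSE is
the full-vector squared error divided by d; all are averaged over
replicates.

The replicate harness runs simulate → tune → fit → score for each method
over R replicate datasets and reports means and standard deviations in a
tidy table. The packaged studies use R = 30 replicates (the published
tables of record in this literature use 100; 30 keeps a full study on one
CPU in minutes at n = 250, p = 75, d = 304) and pilot-fixed tuning.
Stability selection draws B subject subsamples without replacement
(e.g. 200 of 250), refits at fixed tuning, and reports per-coefficient
selection proportions.

## Performance notes

The information matrix is assembled from cached per-time-pair cross
products (sum_i Z_ij Z_il', k x k of them), so each Newton iteration
costs O(k^2 d^2) instead of O(n k d^2); the cache is shared across all
fits on the same dataset (CV cells, method variants). The cache is
skipped above ~600 MB and T is then accumulated directly.

## Known limitations

* Balanced designs only (equal k per subject); missingness is rejected
  at load, not modelled.
* Gaussian identity-link marginal model only.
* The CV-loss/selection misalignment described above; model-size-aware
  criteria (BIC-type) are out of scope.
* MCP is nonconvex: raising lambda1 does not provably shrink the
  selected set monotonically, and distinct initializations can reach
  different local solutions. The LASSO initialization makes results
  deterministic given the seed.
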
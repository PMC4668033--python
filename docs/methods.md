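# Methods

## The model

`tapermix` models the over-bark diameter profile of a tree stem with a
variable-exponent taper equation.  For a tree of breast-height diameter
`d` (cm) and total height `h` (m), the diameter at height `h_i` (m) is

    d_i = a0 * d^a1 * h^a2 * x^B
    B   = b1*q^4 + b2*exp(-d/h) + b3*x^0.1 + b4/d + b5*h^w + b6*x

with `q = h_i/h`, `w = 1 - q^(1/3)` and
`x = (1 - q^(1/3)) / (1 - (1.3/h)^(1/3))`.  Two structural facts follow
directly from the definitions and are load-bearing throughout the package:
`x = 1` at breast height (so the curve is pinned near the measured DBH
there, and any coefficient that enters only through a power of `x` has no
influence at 1.3 m), and `x = 0` at the tip, where the predicted diameter
is defined to be 0.  The variable exponent `B` lets one smooth curve
render the neiloid butt, the paraboloid mid-stem and the conic top.

Because the equation has no closed-form inverse, merchantable height to a
top-diameter limit is found by bracketing the upper monotone segment on a
fine grid and polishing with Brent's method, and volumes are obtained by
adaptive quadrature of `pi * (d_i(t)/200)^2` (absolute tolerance 1e-8 m^3
by default, far below the 4-figure volumes of practical interest).

## Two-level mixed structure

Stem-analysis data are doubly grouped — sections within trees, trees
within plots — so a chosen subset of coefficients (by default `a1` and
`b3`) is expanded with additive random effects at both levels:

    theta_ij = beta + b_i + b_ij,   b_i ~ N(0, D_p),  b_ij ~ N(0, D_t).

Residuals are heteroscedastic with an SD-scale power-of-DBH weight:
`sd(eps) = sigma * d^delta`, i.e. `Var(eps) = sigma^2 * d^(2*delta)`.
The squared-weight convention is deliberate: it is the form under which
the packaged published variance components are coherent (with
`sigma^2 = 6.117e-3` and `delta = 0.7405`, a typical 23.5 cm tree gives an
ordinary-residual variance of ≈ 0.65–0.70, matching the published value
0.6866, whereas a linear-weight reading is off by an order of magnitude).
Optionally, within-tree serial correlation follows a continuous AR(1) in
the height separation in metres, `corr = phi^|h_k - h_k'|`, appropriate
because stem sections are unequally spaced.

## Estimation

* **OLS** — pooled nonlinear least squares (Levenberg–Marquardt), fixed
  starting point `a0 = 1, a1 = 1, a2 = 0, b1..b6 = 0.1`.
* **GLS** — Gaussian ML; `(delta, phi)` are searched by Nelder–Mead with
  the coefficients re-solved by whitened least squares inside, and the
  residual scale profiled out.
* **FOCE** — the first-order conditional expectation linearization with a
  Lindstrom–Bates alternation:
  1. *EBLUP step.* At the current estimates, every plot's joint
     plot/tree effect vector is predicted by the iterative update below.
  2. *LME step.* The profile is linearized around those EBLUPs
     (finite-difference design matrices; the derivative with respect to an
     effect equals the derivative with respect to its coefficient because
     effects enter the coefficient vector linearly).  The working linear
     mixed model is maximized over the variance parameters by L-BFGS-B,
     with the fixed coefficients solved by GLS and `sigma^2` profiled
     analytically; ML and REML criteria are both available.  Covariances
     are parameterized by log-Cholesky factors scaled by `sigma^2`, which
     keeps them positive semidefinite and unconstrained.
  The loop stops when the relative change of -2 log L drops below 1e-8
  (cap 200 alternations; non-convergence raises, carrying the objective
  trace).  Variance-parameter starting values are fixed for
  reproducibility: `D = 0.01 I` at both levels, `delta = 0.5`,
  `phi = 0.5`.  Near-singular working covariances encountered during the
  line search are jittered, and a finite penalty replaces the objective
  where the Cholesky still fails — this keeps L-BFGS-B inside the
  well-behaved region instead of stalling on an infinite trial step.
  Reported AIC/BIC use the linearized-model likelihood at convergence with
  `k` = fixed coefficients + free variance-covariance parameters.
  Standard errors come from the linearized GLS information matrix.

Likelihood-ratio tests for a variance component on the boundary use the
naive chi-square reference (no mixture correction), which is
conservative.  REML fits with different fixed structures are refused in
nested comparisons.

## Calibration (localization)

For a new plot with trees carrying at least one extra diameter
measurement, the joint effect vector solves the fixed point

    b = D Z' (Z D Z' + R)^{-1} [ y - f(beta, b) + Z b ],

with `D = blockdiag(D_p, D_t, ..., D_t)`, Z holding the profile
derivatives evaluated at the current `b` (the plot-effect column block
repeats the tree-effect entries on every row; tree blocks are block
diagonal) and `R = sigma^2 * blockdiag(g_j^2 M_j)`.  By the Woodbury
identity this fixed point is exactly the stationary point of the
penalized criterion `||y - f(b)||^2_{R^-1} + b' D^-1 b` — the tests
exploit that equivalence as an independent oracle.  Z is re-evaluated at
the updated `b` every pass (consistent with FOCE fitting); a
single-linearization variant is available via `reeval_z=False`.
Iteration stops when the largest absolute update falls below 1e-8
(cap 100).  When the expanded coefficient enters linearly the update
lands on the closed-form BLUP in one step.

The calibration-height sweep calibrates every evaluation tree on each of
its measured sections in turn (the tree treated as the sole tree of a new
plot), scores the remaining sections and, optionally, total stem volume
(predicted and observed volumes use the same height interval, first
section to tip), and pools errors by the relative height of the
calibrating section in classes of width 0.1.  Classes containing no
calibrating section are reported with `n = 0` and missing statistics
rather than zeros.

## Responses and evaluation

Three prediction modes: **M** (fixed coefficients only), **PA**
(population-averaged: plain Monte Carlo over `N(0, D_p)` and `N(0, D_t)`
draws with a fixed seed and one shared draw set across all sections —
quadrature was rejected because two correlated bivariate levels make the
integral four-dimensional, while MC error is controllably
`O(1/sqrt(n_draws))`), and **SS** (subject-specific, adding predicted
effects).  When both covariance matrices are exactly zero PA returns the
M response verbatim, keeping the degenerate identity exact.

Accuracy statistics are `RMSE = sqrt(SSE / (n - p))` and the percentage
mean prediction error `100 * mean(y - yhat) / mean(y)`.  The denominator
count `p` is configurable and defaults to 0 in disaggregated tables (one
pooled `p` cannot be apportioned to cells unambiguously); pooled
model-level statistics conventionally use the fixed-coefficient count for
every response type, since no random-effect penalty is defined.

## Random-effects sensitivity

Quantile taper envelopes for a probe tree come in three modes.
*Separate* varies one expanded coefficient at a time, using the combined
variance `D_p[r,r] + D_t[r,r]` (a new tree's effect is the sum of two
independent draws); b3-only bands pinch to zero exactly at breast height
because `x = 1` there.  *Joint* draws full effect vectors from
`N(0, D_p + D_t)` and reports pointwise empirical quantiles of the curve
ensemble — the construction that respects the estimated correlation.
*Joint-quantile* sets all expanded coefficients to their marginal
quantiles at one common probability (co-monotone variation); its curves
all cross the mean response where the SD-weighted sensitivities cancel,
`sum_r sd_r * df/dtheta_r = 0`.  With the packaged components and a
24 cm / 14 m probe tree that crossing sits near 4.9 m — about one-third
of total height.  The two joint modes answer different questions: the
ensemble gives calibrated pointwise prediction bands, the co-monotone
family exposes the structural compensation between coefficients.  With
the packaged components the a1/b3 effect correlation is weak (~0.06), so
the ensemble bands do *not* pinch mid-stem; only the co-monotone family
does.

## Synthetic data

The generator emulates the study design the packaged coefficients came
from: 70 plots of 6 felled trees (defaults), DBH lognormal with mean
23.5 cm and SD 10.2 cm truncated to 6.5–56.9 cm, height from the
allometry `h = 1.3 + 1.4 * d^0.7` with lognormal noise (CV 0.08, capped
at 29.5 m) — chosen to span the observed 3.8–29.5 m range over the
observed DBH range — a stump section uniform on 0.03–0.40 m, then logs of
uniform length between 0.3 m and `min(2.5, max(0.5, h/8))` m.  The
shrinking per-tree cap mimics the shorter logs cut from smaller stems and
keeps section counts inside the observed 7–24 range (schedules outside
that range are redrawn, at most 50 times).  Diameters are the
subject-specific profile plus Gaussian noise with the power variance
function and optional CAR(1) correlation; negative simulated diameters
(possible near the tip) are truncated at zero and counted.  Measurement
rounding (0.1 cm / 0.01 m) is available but off by default so recovery
studies see the exact error law.  Everything is reproducible from a
single seed.

What the generator does *not* emulate: abnormal stems (large knots,
damage), crew measurement error beyond the residual law, the field
protocol's gap in section heights between 1.3 and 3.3 m, or sociological
tree classes.  Passing recovery tests therefore demonstrate correctness
of the estimation machinery under the assumed model, not robustness to
real-data violations of it.

## Problem sizes used in checks

The parameter-recovery check runs 10 replicates of the full 70 x 6
design.  The calibration-sweep property pools three independently
generated 100-plot evaluation sets (~19,000 single-section calibrations):
the class-RMSE profile has a broad, shallow valley between relative
heights 0.3 and 0.7, and smaller sets leave the literal argmin dominated
by Monte-Carlo noise.  Oracle comparisons (penalized-criterion EBLUP,
closed-form BLUP, linear random-intercept ML) run on systems of at most
three subjects where dense algebra is unambiguous.

## Known limitations

* FOCE is an approximation; its likelihood is that of the linearized
  working model, so criteria are comparable across models fitted the same
  way but are not exact marginal likelihoods.
* Standard errors ignore the uncertainty of the variance parameters.
* The CAR(1) coefficient is weakly identified when random effects already
  absorb most within-tree correlation; bounds keep `phi` in [0, 0.999].
* Plot-level-only calibration is supported but de-emphasized: with the
  packaged components the plot level explains far less variability than
  the tree level.
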
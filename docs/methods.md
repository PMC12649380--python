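# Methods

`flumefish` implements a complete analysis chain for open-channel flume
experiments on fish swimming performance and fine-scale path selection under
high flow. This note documents the models, the choices made where the design
was genuinely open, and what the synthetic test bed does and does not show.

## Hydraulic field statistics

Each velocimeter point series `(u_i, v_i, w_i)` (longitudinal, lateral,
vertical, m/s) is reduced to time-averaged velocities, turbulent kinetic
energy

    TKE = 1/2 * (var(u) + var(v) + var(w))        [m^2/s^2]

and Reynolds shear stresses `tau_ab = -rho * cov(a, b)` [N/m^2], with
**population (1/n) divisors** throughout — the estimator follows the defining
sums, not the unbiased 1/(n-1) variant; at the operating record length
(n = 1500, i.e. 25 Hz x 60 s) the difference is negligible. Water density is
fixed at 1000 kg/m^3 (configurable).

The grid of 25 sections x 5 points (0.25 m x 0.10 m spacing over the 6.0 m x
0.5 m test area) becomes a `HydraulicField`. Interpolation between nodes is
**bilinear**: the simplest scheme exact at the nodes, and exact for globally
linear fields, which is all the downstream covariate attachment requires.
Coordinates: `x` increases upstream from the downstream end of the test
area, `y` across the width; the mean longitudinal velocity is therefore
negative (flow runs downstream). Only the monitored 0.10 m depth layer is
modelled. Queries outside the grid's bounding rectangle raise an error;
callers (step tables, candidate construction) drop such points and log the
count rather than clipping, because clipping would distort the hydraulic
contrasts.

The nominal velocity `V_nom` of a trial is the arithmetic mean point speed
across the central monitoring cross-section (section 12 of 25).

## Trajectory kinematics

Ground velocity is the raw frame difference times the frame rate (18 Hz);
no smoothing is applied. Swim velocity is `Vs = Vg - Vf`, with the flow
vector `Vf` interpolated at the step's starting position. The movement mode
is classified from the angle theta between `Vg` and `Vf`: downstream
[0, pi/3), cross-stream [pi/3, 2pi/3] (closed on both ends — a measure-zero
tie-break fixed for determinism), upstream (2pi/3, pi]. Steps with
`|Vg| <= 0.05 BL/s` (configurable) are labelled stationary and excluded
from selection analyses; the threshold is a package choice, small enough
that genuine movement is never discarded at 18 Hz.

Speed profiles pool steps (optionally one movement mode) into 0.1 m bins
along `x` and report means with normal-approximation 95% CIs
(mean ± 1.96 SE); single-observation bins report the mean with a missing
CI. A per-fish pooling option exists but pooled steps are the default.

## Endurance: breakpoint Weibull AFT

Fatigue time `T` is the total time spent above the sustained-swimming
threshold (3.83 BL/s, a named constant); `mean_Vs` is the arithmetic mean
speed over those steps. By default one record is produced per continuous
supra-threshold excursion, with per-fish aggregation available; a record is
right-censored when the cumulative upstream displacement of the excursion
reaches the 6.0 m test-area length.

The endurance model is an accelerated failure time regression
`ln T = X beta + sigma * eps` with minimum-extreme-value errors (Weibull
time). The regime indicator `C_ps` (prolonged vs sprint, split at a
breakpoint swim speed) interacts with every covariate **and** the scale:
the model is fitted as two independent Weibull AFT regressions, one per
regime, which is exactly the all-interactions parametrisation with
regime-specific `Log(scale)`. Fitting is direct maximum likelihood (BFGS on
the log-time likelihood with analytic score; observed-information standard
errors from finite differences of the score; reported log-likelihoods use
the conventional time-scale density). Wald p-values assume the observed
information.

The breakpoint is searched over the observed distinct mean swim speeds
(moving-point regression). Candidates must leave at least
`len(covariates) + 3` records in each regime — with two covariates each
regime estimates four parameters, so a fixed two-record trim would leave
inestimable fits. The candidate minimising the summed two-regime AIC wins;
ties within 1e-6 go to the higher Harrell C-index. The C-index counts pairs
whose ordering is observable under right-censoring (ties in prediction count
one half). Covariate-subset selection enumerates the 15 non-empty subsets of
{Vs, BL, Temp, DO} at the selected breakpoint and ranks them by AIC with
Akaike weights.

**Search resolution.** Simulation at the study's conditions (185 records
split 47/138, published coefficients and scales as truth, 10% censoring)
shows the search is essentially unbiased in speed terms — the median
selected breakpoint sits within ~0.02 BL/s of the planted 6.13 BL/s, and
~70% of replicates land within 0.1 BL/s — but single-order-statistic
resolution is not achievable: the regime jump in mean log-time at the
boundary is ~1.2 sigma, so AIC differences of order one span several
neighbouring candidates. Users should read the selected breakpoint with an
uncertainty of a few candidate steps.

`predict_T` is `exp(linear predictor)` — the location of the log-time
distribution, a fixed quantile of the Weibull time distribution — with the
regime chosen by the query speed. The endurance state integrates depletion
at 1/T per second over supra-threshold steps,

    E_k = 1 - sum_{j<=k} dt / T(Vs_j),   dt = 1/frame_rate,

clamped at 0, with the regime decided per step from the instantaneous
speed. Sub-threshold swimming costs nothing, consistent with the
sustained-swimming definition.

## Use-availability resource selection

For each non-stationary step P0 -> P1 the three available alternatives are
the rotations of the step vector by pi/2, pi, 3pi/2 about P0 (same step
length). Covariates are **signed** hydraulic differences (candidate minus
P0) in u, v, TKE and the three shear-stress components; signed differences
are the only reading under which reported negative preference ranges make
sense. Candidates outside the grid are discarded and counted (walls make
some rotations physically impossible). The endurance state of the step is
attached to all four rows.

Collinearity screening drops one member of any pair with |r| > 0.6 (the
member with the larger mean absolute correlation to the rest), then removes
the max-VIF covariate until all VIF <= 3.

The selection model is a binomial logit GAMM: per-mode penalized smooths of
each retained covariate, tensor-product interaction surfaces of each
covariate (except `dtau_uv`, which is kept only in the mode-stratified
smooths) with E, and random intercepts for movement mode and fish. Smooths
are cubic B-splines with second-order difference penalties (P-splines),
basis dimension k = 5 (configurable within 3-5). Each smooth block absorbs
a sum-to-zero constraint, so its fitted contribution averages to zero over
the data and positive/negative effects are directly interpretable. Every
smooth additionally carries a null-space penalty (the double-penalty device
used for term selection in modern GAM practice); this both lets REML shrink
irrelevant terms to effectively zero degrees of freedom and resolves the
exact concurvity between tensor margins and the per-mode smooths.
Smoothing parameters are chosen by the Fellner-Schall REML update
interleaved with penalized IRLS; credible intervals come from the Bayesian
posterior covariance `(X'WX + S)^-1`. Term p-values are approximate Wald
tests on coefficient blocks and should be read as screening statistics.

No additional spatial smooth over (x, y) is included by default: every term
of the model equation is a covariate smooth, and a coordinate smooth would
absorb the hydraulic gradients that are the object of inference. Random
effects for unseen fish predict at the population mean.

Cross-validation is grouped by fish (no fish in both training and
validation folds), k = 10 by default; reported metrics are mean AUC, recall
of used rows and balanced accuracy at a probability threshold of 0.25 — the
base rate of used rows in the 1:3 design, since no other threshold is
canonical. Partial-dependence curves report the centered link-scale
contribution with 95% bands, the optimal effect point (grid argmax) and
positive-effect ranges (sign-change intervals, linearly interpolated);
reference values for the other terms are zero contrast, mean E, and zero
random effects.

## Synthetic test bed

The generators define the study conditions the tests and the acceptance
script run under:

* **Velocimeter series**: multivariate Gaussian fluctuations with the exact
  inverse of the point estimator (variances summing to 2 TKE, covariances
  `-tau/rho`), 1500 samples at 25 Hz.
* **Flow field**: a smooth analytic speed surface increasing upstream and
  toward one bank, rescaled so the central-section mean equals `V_nom`
  exactly; TKE peaks where the speed contrast is largest, with maxima
  interpolated between 0.05 m^2/s^2 (at 1.80 m/s) and 0.30 m^2/s^2 (at
  2.50 m/s); shear-stress bands hug the walls with |tau_uv| up to 7.55 N/m^2
  at the strongest flow. A small seeded harmonic perturbation keeps fields
  from being artificially symmetric; everything is deterministic given the
  seed.
* **Fish**: body lengths Normal(0.3916 m, 0.045 m) truncated above 0.25 m;
  water temperature ~12.8 degC, dissolved oxygen ~6.18 mg/L, matching the
  trial environment.
* **Fatigue times**: drawn from the two-regime AFT truth (the published
  coefficient tables are the defaults) with `ln T = lp + sigma ln(Exp(1))`.
  Censoring is applied at each record's own conditional 1-f survival
  quantile, so each fish independently has probability f (default 10%) of
  traversing the course — the independent-censoring assumption of the
  estimator. A distance-based rule is used when full trajectories are
  simulated.
* **Trajectories**: an 18 Hz walk whose step speeds are log-normal with mean
  2 BL/s (CV 0.4; the observed ground speeds are order 1-3 BL/s and the
  literature gives means, not distributions). At each step the four
  candidate headings are scored by a configurable additive link-scale
  selection function of the hydraulic-difference covariates, candidate
  movement mode and current endurance state, and the next position is a
  multinomial-logit draw — the exact generative inverse of the RSF, so
  "recovery" of a planted preference is well defined.

**What the test bed does not emulate:** real velocimeter noise is neither
Gaussian nor white (Doppler spikes, filtering); real fish trajectories have
autocorrelated headings, burst-and-coast structure and wall-following not
captured by a four-heading logit walk; the flow field is smooth and
stationary with no vortex structure. Passing recovery tests therefore
demonstrates the correctness of the estimators under their assumed data
model, not robustness to the messiness of field data.

A note on planted-preference recovery: because the walk's positions are
endogenous to the preference, a strongly avoided covariate region is rarely
visited and the realized covariate range contracts. Planted optima must lie
inside the reachable contrast range to be recoverable; tests place them
there deliberately.

## Problem sizes

Simulation-based checks use 200 replicates for coefficient recovery
(n = 47 and n = 138 per replicate), 100 replicates for the breakpoint
search (n = 185), 10 fish x 200 steps for the null-selection
cross-validation and 10 fish x 500 steps for planted-preference recovery —
sizes at which Monte-Carlo error is small relative to every tolerance
asserted, while the full suite stays fast.

## Known limitations

* The GAMM's Fellner-Schall iteration targets the REML optimum but is
  stopped on a smoothing-parameter step tolerance (2% on the log scale);
  effective degrees of freedom can differ slightly from a fully converged
  mgcv-style fit. P-values for smooth terms are block Wald approximations
  without the refinements of dedicated GAM software.
* AFT standard errors use the observed information; no small-sample or
  robust correction is applied. At n = 47 the maximum-likelihood slope
  estimates carry a relative bias of about 1%.
* The breakpoint's sampling uncertainty is not propagated into the
  downstream endurance-state integral; E is conditional on the selected
  model.
* Bilinear interpolation underestimates curvature of the hydraulic surfaces
  between nodes; at 0.25 m x 0.10 m spacing this is below the measurement
  noise of typical velocimeter campaigns.
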
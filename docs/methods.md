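# Methods

## Model

The frailty process is a time-homogeneous continuous-time Markov chain on
four states — robust (1), pre-frail (2), frail (3), death (4) — with
transitions restricted to adjacent severities and death reachable from
every living state; death is absorbing. The seven free intensities
(per-year instantaneous hazards) are q12, q14, q21, q23, q24, q32, q34;
all other off-diagonal generator entries are structurally zero and each
row sums to zero. Direct robust↔frail jumps are excluded from the
structure, though P(t) correctly assigns them positive probability for
t > 0 through multi-step paths.

Covariates act proportionally on each transition:
q_ij(z) = q0_ij · exp(β_ij′ z). Every covariate enters every allowed
transition (including the death transitions), so the hazard-ratio table
is a full transition × covariate grid. The model is time-homogeneous
conditional on covariates; there is no calendar-time or duration
dependence (no semi-Markov effects) and no misclassification layer.

**Covariate handling.** Covariates are piecewise-constant per observation
interval, evaluated at the interval's start. Age is by default
time-varying — attained age = baseline age + elapsed time at the interval
start — with a config switch for fixed-at-baseline, since panel analyses
are split on this choice. Age is centered at 60 years (configurable)
wherever it enters, which anchors the baseline intensities at a realistic
profile and keeps the age × male product term in the interaction model
roughly orthogonal to the male main effect. Reference categories: female,
below-middle-school education, not married/partnered, rural, never
smoker, never drinker.

## Frailty index

The FI is the proportion of deficits present out of 32 items (31 binary,
one continuous cognitive deficit in [0,1]). Up to 3 missing items (10%)
are tolerated, with the denominator renormalised to the non-missing
count; beyond that the FI is missing and the wave is dropped from the
subject's sequence. Cutoffs: robust FI ≤ 0.10, pre-frail 0.10 < FI <
0.25, frail FI ≥ 0.25 — the boundary values belong to robust and frail
respectively. The shipped 32-item template (chronic conditions, ADL/IADL
limitations, physical function, depressive symptoms, self-rated health,
cognition) is a documented default; any 32-item encoding can be supplied
as a JSON/YAML item-spec file. Subjects need at least two usable
observations (a terminal death record counts toward the pair); exclusions
are tallied in a report rather than forced to match any external flow
chart.

## Likelihood and estimation

For consecutive observations (t_k, s_k) → (t_{k+1}, s_{k+1}) the
contribution is log P(Δt)[s_k, s_{k+1}] with P(Δt) = exp(Δt·Q(z_k)).
Two death conventions are supported: **exact** (default) — the death date
is known and contributes the density log Σ_{j∈{1,2,3}} P(Δt)[s_k, j] ·
q_{j,death}; **interval** — death is only bracketed by waves, recorded at
the interval midpoint and contributing log P(Δt)[s_k, death]. Observation
pairs that are impossible under the structure are floored at 1e-300
(overwhelmingly penalised, never a crash) and a diagnostics routine lists
the offending subject-intervals with their probabilities.

Intervals sharing a (Δt, covariate) pattern share one matrix exponential,
so evaluation cost scales with the number of distinct patterns rather
than subjects. The matrix exponential uses scaling-and-squaring with a
degree-13 Padé approximant, vectorised over the whole batch of 4×4
generators (`frailmsm._linalg.expm_batch`); an eigendecomposition route
was rejected because a generator may be defective. The gradient is exact:
for each pattern only seven directional derivatives of exp(Δt·Q) are
needed — one per transition rate, regardless of how many covariates enter
— each obtained as the top-right block of exp of the 8×8 block matrix
[[A, E], [0, A]] (Fréchet derivative), then spread over baseline and
coefficient parameters by the chain rule.

Maximisation is dense-BFGS from deterministic occurrence/exposure
starting values (observed adjacent-wave changes over person-time, floored
at 1e-3/year; coefficients start at zero), declaring convergence at
gradient max-norm < 1e-4. No random multistart is used, so a fit is a
pure function of the data. The observed information is a central finite
difference of the exact gradient; its inverse provides Wald standard
errors, with HR = exp(β̂) and 95% CI exp(β̂ ± 1.96·SE). Parameters left
with numerically zero curvature by sparse cells (e.g. a covariate on
robust→death in a small sample) get NaN covariance rows — confidence
intervals degrade per parameter, flagged in the HR table, rather than
wholesale. Note that occurrence/exposure starting values are biased
toward zero when sojourn times are short relative to the wave spacing
(multiple jumps collapse into one observed change); they are starting
values only, and the MLE corrects this.

Stratified analyses refit independently on baseline age bands 45–54,
55–64, ≥65 (closed on the left) and/or gender, skipping strata below a
configurable minimum of 100 subjects.

## Derived quantities

- **Mean sojourn time** in transient state i: 1 / Σ_{j≠i} q_ij, the mean
  of the exponential holding time; delta-method CIs on the log scale
  propagate the fitted covariance through a numerical gradient.
- **Interval transition probabilities**: P(t) at requested horizons
  (default 1, 3, 5 years), evaluated at a covariate profile; the default
  profile is cohort-mean age with modal categories.
- **Total length of stay** over [0, T] from start state r:
  L_i = ∫₀ᵀ P(t)[r, i] dt by composite Simpson quadrature (initial step
  0.05 y, step-halving to tolerance 1e-6). Proportions are reported
  relative to expected time alive, L_i / Σ_{j transient} L_j, so they sum
  to one over the living states. Default horizon 10 years.

## Synthetic cohorts

The generator emulates a CHARLS-like panel: waves at 0, 2, 4, 7 years
(optional ±0.25-y per-subject jitter on follow-up waves, off by default
so interval lengths stay on a small grid), baseline state mix
44.3/39.4/16.3% robust/pre-frail/frail, integer ages from a truncated
normal (mean 59.1, SD 9.7, range [45, 90)), and binary/categorical
covariates at the cohort marginals (51.1% female complement → p_male
0.489; education 67.2/20.6/12.2%; 87.4% married; 38.7% urban; 40.3% ever
smokers; 42.0% ever drinkers). Latent trajectories are Gillespie
simulations — exponential holding times at the total exit rate, next
state proportional to competing intensities, age refreshed at each state
entry when age effects are time-varying (intensities are held constant
within a sojourn, a first-order approximation to a truly age-inhomogeneous
process). Trajectories are projected onto the wave grid with no
post-death observations; deaths are recorded exactly or at interval
midpoints per the configured convention.

The default covariate-free intensities (0.290, 0.003, 0.255, 0.435,
0.005, 0.373, 0.160 per year, in transition order) come from a one-time
least-squares calibration of the homogeneous generator to realistic
1/3/5-year pre-frail and frail transition-probability rows. The two
candidate calibration anchors available for such cohorts — fitted
interval transition probabilities versus raw wave-level death shares —
are mutually inconsistent (raw wave mortality is depressed by attrition),
and the defaults follow the transition-probability surface; synthetic
cohorts therefore show higher wave-level mortality than raw survey
tabulations. The covariate model's baselines divide these rates by the
population-average multiplier E[exp(β′z)] under the default covariate mix
(Monte Carlo at n = 200 000), so cohort-level dynamics match the
covariate-free generator; its hazard ratios are plausible defaults (age
accelerates progression and mortality and slows recovery; men recover
more but die more from frailty; education, urban residency and marriage
protective; smoking and drinking adverse), not ground truth.

Optional item emission inverts the FI scorer: a target FI is drawn
uniformly within the latent state's band (frail capped at 0.65), its
integer part becomes randomly placed binary deficits and the fractional
remainder the continuous cognition item, so scoring recovers the latent
state exactly when no items are missing. Missingness is MCAR by default
(items 2%, covariates 0%), with an age-dependent MAR option for
imputation stress tests; age itself anchors the MAR mechanism and is
never removed. What the generator does **not** emulate: survey sampling
design and household clustering, realistic item marginals and inter-item
correlation, state-dependent attrition, or informative missingness —
passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Multiple imputation

Missing covariates (never FI items — their missingness is handled by the
scorer's renormalisation) are imputed by chained equations: 10 cycles of
per-column conditional draws, with predictive-mean matching (5 donors)
for continuous columns and regularised logistic/multinomial sampling for
binary/categorical ones; each cycle refits the conditional model on a
bootstrap resample so parameter uncertainty propagates into the draws.
m = 5 completed datasets by default (all of m, cycles, donors
configurable, seeded and chain-independent). Fits on completed datasets
are pooled on the log-intensity / log-HR scale with Rubin's rules —
total variance = mean within-variance + (1 + 1/m) × between-variance —
then exponentiated for the pooled HR table.

## Problem sizes and numerical choices

The test suite and acceptance script use scaled-down cohorts chosen as
the smallest sizes at which each property is statistically decidable:
n = 2000 (7 replicates) for intensity recovery (median relative bias
≤ 10% on transitions with ≥ 50 observed events), n = 250 × 200 replicates
for Wald-interval coverage of a binary covariate effect (accept 90–99%
at nominal 95%), n = 3000 for the deterministic pipeline run. Likelihood
agreement with uniformization is required to 1e-8 relative and with a
Δ = 1e-4 discrete-time grid to 1e-4; Chapman–Kolmogorov and two-state
closed forms to 1e-8. Probability floors (1e-300), the linear-predictor
clip (±25), and the crude-rate floor (1e-3/y) guard degenerate inputs.

## Known limitations

- Time-homogeneity given covariates; no semi-Markov or calendar-time
  effects and no state misclassification model.
- The exact-death likelihood assumes the death date is known; when only
  a reporting interval is known, the midpoint/interval convention is an
  approximation.
- Wald intervals and delta-method CIs rely on asymptotic normality;
  sparse transitions in small samples surface as NaN intervals rather
  than being silently extrapolated.
- The age-varying simulation holds intensities fixed within a sojourn;
  for sojourns of a few years and age HRs near 1.03–1.07/y the induced
  bias is small but not zero.
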
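# Methods

This note documents the model, the numerical scheme, the synthetic-data
generator and the estimation machinery implemented in `thyropmx`, including
the design choices that were genuinely open and the known limitations.

## Structural model

The drug side is a linear mammillary system for carbimazole (CMZ) and its
active metabolite methimazole (MMZ): first-order absorption of the prodrug
(kaC = 144/day), a metabolic transit step (kt = 28.8/day) producing MMZ with
the molecular-weight mass factor f^M = 0.61, first-order MMZ elimination
(kelM = 2.77/day, i.e. a 6 h half-life) and symmetric peripheral distribution
(k12 = k21 = 2.4/day). These constants are fixed (taken from product labels
and published PK studies, not estimable from FT4 data); together they place
the single-dose MMZ concentration peak at ~2 h, inside the 1–2 h label
window. MMZ concentration is the central amount divided by a weight-
proportional volume fVM * W(t) with fVM = 0.5 l/kg.

The response side is a turnover model for total T4 (nmol): zero-order
disease-elevated production kendoT4, inhibited by MMZ through the standard
term 1 − Imax·C/(IC50 + C) (Imax = 0.9 fixed; IC50 estimated), first-order
elimination kelT4 = 0.1/day (fixed), and, under block-and-replace therapy,
an oral LT4 input (bioavailability 0.6, absorption 20/day, both fixed;
1 mcg = 1.29 nmol). The observable is FT4 = 0.3·T4/V_T4 with the allometric
volume V_T4 = fVT4·(W/WRef)^beta, WRef = 42.7 kg. The 0.3 bundles two
conventions — a 0.03% free fraction and the nmol/l→pmol/l unit change — and
is deliberately hard-coded: the sub-factors are not independently
identifiable and splitting them would only invite misconfiguration. The
initial condition T4(0) = kendoT4/kelT4 encodes pre-treatment equilibrium.

Doses are instantaneous boluses at their recorded times (the standard
convention for oral first-order absorption); three-times-daily CMZ is split
into equal parts at 8-hour offsets from the top of the dosing day, LT4 is
given once daily at the top of the day. Clock times are a convention, not
data: only the sub-day placement matters and its influence on weekly-scale
FT4 is negligible.

### Simplified PK variant

For fitting, the four-state PK block can be replaced by a one-compartment
daily IV bolus F^C·D_day (F^C defaults to f^M = 0.61) with the same kelM and
volume. The two variants deliver the same daily AUC, but the simplified
profile has a higher peak and a deeper trough, so its time-averaged
inhibition is weaker: **at identical IC50 the simplified model's steady-state
FT4 sits 15–25% above the full model's** across the clinical dose range.
The discrepancy is absorbed entirely by the half-maximal concentration:
`pd.calibrate_simplified_ic50` refits IC50 alone (to a lower value, ~0.014–
0.016 mg/l against the full model's 0.024 mg/l) after which the FT4
trajectories agree to well under 3% beyond the equilibration transient. This
is the precise sense in which the simplified model "performs equally well":
equivalent fits and predictions, with an IC50 whose numerical value is tied
to the PK representation used. Both variants are first-class; the default
everywhere speed matters is the simplified mode.

## Numerical scheme

Between dose events every equation is linear with constant coefficients, so
the integrator is semi-analytic rather than a general ODE solver:

* full-model PK amounts propagate exactly via the eigenmodes of the 4×4
  system matrix (matrix exponentials for the mass-balance-augmented 5-state
  variant), with bolus jumps applied exactly at event times;
* the simplified-model amount is an explicit bolus-decay recursion, evaluated
  by a blocked cumulative sum that never overflows regardless of horizon;
* the T4 state uses the exact variation-of-constants update; the inhibition
  forcing integral (no closed form) is evaluated per interval with 8-node
  Gauss–Legendre quadrature. Intervals are capped at 1 day (30 min in full-PK
  mode, where absorption/transit modes of 144 and 28.8/day must be resolved),
  keeping the integrand smooth on each panel; order 8 agrees with order 16 to
  ~1e−11 and with an adaptive LSODA reference (rtol 1e−10) to better than
  1e−7 relative error — both comparisons are part of the test suite.

The scheme is ~10³ times faster than restarting an adaptive solver at every
dose event, which is what makes the NLME machinery below tractable: a
patient's FT4 prediction re-evaluates in ~50–100 µs after a one-off
precomputation of the concentration at all quadrature nodes (the forcing does
not depend on any estimated parameter).

Degenerate inputs are handled explicitly: empty regimens reproduce the
analytic equilibrium to machine precision; zero doses, zero omegas
(random effects pinned to zero, with an internal floor of 1e−6 on estimated
omegas), and tie-broken concentration peaks (earliest time wins) are all
covered by tests.

## Synthetic cohort

The generator emulates the study conditions the model was built for: 44
patients split 13/15/16 across mild/moderate/severe strata (graded by FT4 at
diagnosis: <50 / 50–70 inclusive / >70 pmol/l, mild the reference class);
per-stratum log-normal age and FT4-at-diagnosis distributions calibrated to
the reported medians and IQRs (FT4 truncated to its stratum, so labels and
values never disagree; note this FT4-at-diagnosis is a covariate — the
simulated observation at t = 0 is the model's own equilibrium
0.3·kendo/(kelT4·V_T4), which orders the strata correctly but need not fall
inside the stratum's nominal range for every patient); 75% girls; CMZ started at median 0.72 mg/kg/day tid
(draws truncated to the observed 0.36–1.40 range); a 17/44 probability of
switching to block-and-replace at a log-normal switch day (median 75, IQR
52–183, truncated to 28–364) with CMZ cut to 0.42 mg/kg/day and LT4 started
at 1.86 mcg/kg/day; visits at weeks 0, 2, 4, 6, 8 and then 12-weekly with
±4-day jitter, censored at a log-normal follow-up (median 1.89 y), yielding
~11 FT4 observations per patient. Body weight grows deterministically at
+3 kg/year from a per-stratum log-normal baseline; only the scale of W(t)
matters to the model, so growth-chart fidelity was not a goal.

The source cohort's dose titration followed unrecorded clinical judgement,
so the generator uses a minimal synthetic controller: at each visit the
patient's FT4 is *measured* (the model prediction with proportional residual
error applied — the same value recorded as that visit's observation) and the
CMZ dose is halved below 12 pmol/l or raised 25% above 22 pmol/l, effective
the next day; after the switch the same thresholds titrate LT4 instead.
Titrating on the measured value rather than the latent noise-free prediction
matters statistically, not just cosmetically: it keeps dosing a function of
the observed history only (sequential ignorability), so likelihood-based
refitting of generated cohorts is consistent. In early versions that
titrated on the noise-free value, dose histories leaked information about
the unobserved random effects and all covariate coefficients attenuated
markedly on refit.

What passing tests on these cohorts do **not** show: robustness to real-data
features the generator omits — non-adherence, dropout, assay changes across
centers and years, tablet-strength dose rounding, TSH dynamics and
weight-loss-then-catch-up growth. The generator is a test harness for the
estimation machinery, not a claim about clinical data.

## Estimation

The fitting objective is the marginal likelihood with log-normal random
effects on kendoT4 and IC50 (optionally also on fVT4 and beta, whose omegas
are fixed at 0.1 and 0.25 and never estimated), proportional residual error
y = f·(1 + σε), and the covariate model on log kendoT4. Per patient the
integral over the random effects is approximated by Laplace expansion at the
MAP eta: the inner problem is solved by BFGS with *analytic* gradients (the
T4 path is linear in kendo; the IC50 sensitivity integrates a closed-form
integrand through the same turnover kernel), warm-started across outer
iterations; the inner Hessian is assembled from central differences of that
analytic gradient plus the exact prior curvature. If the Hessian is not
positive definite the patient's contribution falls back to an
importance-sampling estimate and the fit is flagged. An independent
importance-sampling estimator (Gaussian proposal at the MAP with the Laplace
covariance) doubles as the numerical oracle: Laplace and IS agree within 1%
on heterogeneous toy cohorts.

The outer problem maximizes the summed marginal likelihood over
(kendoT4, IC50, fVT4, beta) on the log scale, the three covariate
coefficients on the natural scale, and (ω_kendo, ω_IC50, σ) on the log scale
with an ω floor of 1e−6. The default outer optimizer is a short
Nelder–Mead warmup (moving off the starting point, where finite-difference
gradients are least reliable) followed by bounded L-BFGS-B
with forward-difference gradients (step 1e−4; the tightly-converged,
warm-started inner problems leave the objective smooth at that scale,
verified by symmetric-difference probes), stopping at a relative objective
change below 1e−8; it reaches lower −2LL values in roughly a third of the
evaluations an adaptive Nelder–Mead simplex needs on this problem's
kendo–fVT4 likelihood ridge, and the simplex search remains available as a
derivative-free fallback (`FitSettings.outer_method`).
Relative standard errors use the observed information: the finite-difference
Hessian of −2LL in the transformed parameters, Cov = 2H⁻¹, reported as
100·SE(log p) for log-scale parameters (delta method) and 100·SE/|estimate|
otherwise. Recovery runs start from the generating values perturbed by a
factor of 2 on every estimated parameter.

Two properties of this estimator are worth knowing. First, with proportional
error the MAP of an individual is *not* exactly the truth even on noise-free
data: the log((σf)²) term rewards slightly smaller predictions, shifting
eta_kendo by about −n_obs·ω² (≈0.008 here) — the effect vanishes as σ→0 and
is dwarfed by the residual noise at the clinical σ = 0.344. Second, kendoT4
and fVT4 are separately identified mainly through the LT4-treated arm (known
absolute hormone input), so their individual uncertainties at n = 44 are
larger than the uncertainty of their ratio.

### Problem sizes

The packaged recovery experiment refits cohorts of n = 44 (the study size,
~500 observations); the test suite runs ten seeded replicates with an outer
budget of 800 evaluations (every replicate converges by the relative-change
criterion well inside that budget). Oracle comparisons (Laplace vs
importance sampling) use 5-patient toy cohorts with 10,000 draws. Recovery
is assessed the way simulation studies conventionally do: bias criteria on
the mean across replicates (bias is an expectation; a single draw conflates
bias with sampling error — the across-seed SD of the kendoT4 estimate is
~20%, reflecting the kendo–fVT4 ridge), confidence-interval performance as
per-parameter 2-SE coverage (nominal ~95%; note that the joint event "all
seven fixed effects inside 2 SE at once" has nominal probability only
0.95⁷ ≈ 0.7 even with perfect standard errors). The moderate-vs-mild
coefficient (truth 0.16) is intrinsically noisy at n = 44 — its published
relative standard error was ~49% — so its sign, too, is judged on the
replicate mean.

## Known limitations

* No TSH feedback, T3 dynamics or TRAB model: FT4 under antithyroid therapy
  is modeled as production-inhibition only.
* MMZ PK is never fitted to concentration data here (none exist in this
  population's routine care); the PK constants are literature-informed and
  fixed, and CMZ bioavailability is absorbed into fVM.
* The exploratory on/off treatment-type covariate on kendoT4 is exposed
  (`use_treatment_covariate`) but off by default and never estimated; no
  final value for it is established.
* The Laplace approximation can be optimistic for patients with very few
  observations and large |eta|; the IS fallback and oracle bound that error
  at the ~1% level in the regimes tested.
* Estimates reported by `fit_population` are maximum-likelihood point
  estimates; no finite-sample bias correction is applied.
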
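# thyropmx

Pharmacometrics simulation and nonlinear mixed-effects (NLME) estimation of
free-thyroxine (FT4) dynamics in **pediatric Graves' disease** under
carbimazole (CMZ) monotherapy and CMZ/levothyroxine (LT4) block-and-replace
therapy.

Graves' disease drives endogenous T4 production far above normal; treatment
blocks that production with the CMZ metabolite methimazole (MMZ) and, in
block-and-replace regimens, substitutes hormone with oral LT4. Titrating
these drugs in children is hard: disease activity fluctuates, visits are
sparse, and both over- and under-dosing carry real costs. This package
implements a compact, clinically-oriented PK/PD model of that system for
simulation, virtual-cohort generation, and population (NLME) estimation —
aimed at modelers studying dose individualization in rare pediatric
endocrine disease.

## The model

**PK (Component I).** Oral CMZ is absorbed (kaC), converted to MMZ in a
transit step (kt, mass factor f^M = 0.61), eliminated (kelM = 2.77/day, 6 h
half-life) and distributed to a peripheral compartment (k12 = k21 = 2.4/day):

    dAbC/dt = In_C(t) - kaC*AbC            AbC(0) = 0
    dAC/dt  = kaC*AbC - kt*AC              AC(0)  = 0
    dAM/dt  = fM*kt*AC - (kelM+k12)*AM + k21*P
    dP/dt   = k12*AM - k21*P
    C_M     = AM / (fVM * W(t)),           fVM = 0.5 l/kg

A **simplified PK model** collapses absorption and transit into a single
daily IV bolus F^C * D_day with the same kelM and volume — appropriate
because CMZ acts on a time scale of hours while FT4 data are weeks apart.

**PD (Component II).** Total T4 follows a turnover model whose production is
inhibited by MMZ through a standard Imax term; oral LT4 (mcg -> nmol factor
1.29, bioavailability F^T4 = 0.6) enters through an absorption compartment:

    dAbT4/dt = In_T4(t) - kaT4*AbT4
    dT4/dt   = kaT4*AbT4 + kendoT4 * (1 - Imax*C_M/(IC50 + C_M)) - kelT4*T4
    T4(0)    = kendoT4 / kelT4            (pre-treatment equilibrium)
    FT4      = 0.3 * T4 / V_T4,  V_T4 = fVT4 * (W/WRef)^beta

**Population layer.** Individual parameters are log-normal around the
population values; the endogenous production rate carries covariate effects
of age at diagnosis and disease severity (graded from FT4 at diagnosis:
mild < 50, moderate 50–70, severe > 70 pmol/l):

    log kendo_i = log kendoT4 + beta_age * log(AGE/AGERef) + {0, beta_cat2, beta_cat1} + eta

Observations have proportional residual error. Estimation maximizes the
Laplace-approximated marginal likelihood with nested MAP (empirical-Bayes)
inner problems; standard errors come from the observed information matrix.

Because the original clinical dataset is not public, the package ships a
**synthetic-cohort generator** that emulates the study population (44
patients, severity mix 13/15/16, ~0.72 mg/kg/day CMZ tid, 39% switching to
block-and-replace at a median of day 75, ~11 FT4 observations over ~1.9
years) so the full simulate-and-refit loop is reproducible end to end.

## Worked example

```python
import numpy as np
import thyropmx as tx

pop = tx.PopulationParameters()          # packaged published estimates

# 1. What does a 30 mg/day tid CMZ regimen do to a 42.7 kg moderate patient?
regimen = [e for day in range(120) for e in tx.tid_doses(30.0, float(day))]
ft4 = tx.simulate_ft4(regimen, 42.7, pop.pd_pop, pop.pk_pop,
                      np.arange(0.0, 120.0, 1.0))
print(f"FT4 day 0: {ft4.values[0]:.1f} pmol/l -> day 119: {ft4.values[-1]:.1f} pmol/l")

# 2. How large are the covariate effects on T4 production?
print(f"severe vs mild: +{tx.covariate_effect_percent(pop.beta_cat1_severe):.1f}%")
print(f"moderate vs mild: +{tx.covariate_effect_percent(pop.beta_cat2_moderate):.1f}%")

# 3. Generate a virtual cohort and refit it
from thyropmx.cohort import CohortConfig, generate_cohort
from thyropmx.estimation import FitSettings, fit_population
cohort = generate_cohort(CohortConfig(n_patients=44), pop, rng_seed=1)
fit = fit_population(cohort, FitSettings(rng_seed=1))
print(fit.to_table().head(3).to_string(index=False))
```

Output:

```
FT4 day 0: 38.6 pmol/l -> day 119: 8.0 pmol/l
severe vs mild: +68.2%
moderate vs mild: +17.4%
parameter   estimate  rse_percent  fixed
  kendoT4 327.250533    16.582496  False
     IC50   0.021969    16.234244  False
     fVT4  24.204024    14.725491  False
```

The first line shows the untreated equilibrium (38.6 pmol/l at the reference
weight) suppressed by sustained blocking; the percentages are the clinical
reading of the severity coefficients: severe disease raises endogenous T4
production by more than 65% relative to mild disease, moderate by less than
20%. The fitted table shows this seed's maximum-likelihood estimates with
their relative standard errors; kendoT4 and fVT4 are each uncertain at the
~15% level (they form a likelihood ridge, being separately identified mainly
through the LT4-treated patients), while their ratio — which sets the FT4
level — is pinned much more tightly.

A command-line interface mirrors the library
(`thyropmx generate|simulate|fit|recover|gof|summarize`); see
`thyropmx --help`.

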
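"""Population layer: covariate model, inter-individual variability, residual error.

Individual endogenous T4 production follows the covariate model

    log(kendo_i) = log(kendo_pop) + beta_age * log(AGE/AGERef) + sev + eta,

where ``sev`` is 0 for mild disease, ``beta_cat2_moderate`` for moderate and
``beta_cat1_severe`` for severe, and eta ~ N(0, omega_kendo^2).  IC50, fVT4 and
the allometric exponent carry independent log-normal random effects.
Observations have proportional residual error y = f * (1 + sigma * eps).

Disease severity is graded from FT4 at diagnosis: mild < 50 pmol/l,
moderate 50-70 pmol/l (inclusive), severe > 70 pmol/l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .params import IndividualParameters, PopulationParameters
from .pd import FT4Profile, simulate_ft4

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import VirtualPatient


class Severity(str, Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class Sex(str, Enum):
    F = "F"
    M = "M"


class UnclassifiableSeverityError(ValueError):
    """Raised when severity cannot be graded (no FT4 at diagnosis)."""


def classify_severity(ft4_dx: float | None) -> Severity:
    """Grade disease severity from FT4 at diagnosis (pmol/l).

    Boundaries 50 and 70 belong to the moderate class.  A missing FT4 raises
    :class:`UnclassifiableSeverityError` (grading from TSH/T4 is not
    supported).
    """
    if ft4_dx is None or (isinstance(ft4_dx, float) and math.isnan(ft4_dx)):
        raise UnclassifiableSeverityError(
            "severity is unclassifiable without an FT4 value at diagnosis")
    if ft4_dx <= 0:
        raise ValueError(f"FT4 at diagnosis must be positive, got {ft4_dx}")
    if ft4_dx < 50.0:
        return Severity.MILD
    if ft4_dx <= 70.0:
        return Severity.MODERATE
    return Severity.SEVERE


@dataclass
class CovariateSet:
    """Per-patient covariates entering the model: age at diagnosis and severity."""

    age_dx: float
    sex: Sex
    severity: Severity
    ft4_dx: float | None = None

    def __post_init__(self) -> None:
        if self.age_dx <= 0:
            raise ValueError("age at diagnosis must be positive")
        self.sex = Sex(self.sex)
        self.severity = Severity(self.severity)
        if self.ft4_dx is not None and classify_severity(self.ft4_dx) != self.severity:
            raise ValueError(
                f"severity {self.severity.value!r} inconsistent with FT4 at "
                f"diagnosis {self.ft4_dx} pmol/l")


def severity_shift(pop: PopulationParameters, severity: Severity) -> float:
    """Additive log-scale severity effect on kendoT4 (mild is the reference)."""
    if severity is Severity.SEVERE:
        return pop.beta_cat1_severe
    if severity is Severity.MODERATE:
        return pop.beta_cat2_moderate
    return 0.0


def individual_endogenous_rate(pop: PopulationParameters, cov: CovariateSet,
                               eta_kendo: float = 0.0) -> float:
    """Covariate-adjusted individual endogenous T4 production rate (nmol/day)."""
    if cov.age_dx <= 0:
        raise ValueError("age at diagnosis must be positive")
    log_k = (math.log(pop.pd_pop.kendoT4)
             + pop.beta_age * math.log(cov.age_dx / pop.AGERef)
             + severity_shift(pop, cov.severity)
             + eta_kendo)
    return math.exp(log_k)


def covariate_effect_percent(beta: float) -> float:
    """Percent change implied by a log-scale covariate coefficient: (e^beta - 1)*100."""
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    return (math.exp(beta) - 1.0) * 100.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_individual_parameters(pop: PopulationParameters, cov: CovariateSet,
                                 rng_seed) -> IndividualParameters:
    """Draw one patient's parameters from the population model.

    Independent log-normal random effects on kendoT4 (after covariate
    adjustment), IC50, fVT4 and beta; reproducible given a seed or Generator.
    """
    rng = _as_rng(rng_seed)
    etas = {
        name: rng.normal(0.0, getattr(pop, name)) if getattr(pop, name) > 0 else 0.0
        for name in ("omega_kendo", "omega_ic50", "omega_fvt4", "omega_beta")
    }
    return IndividualParameters(
        kendo=individual_endogenous_rate(pop, cov, etas["omega_kendo"]),
        ic50=pop.pd_pop.IC50 * math.exp(etas["omega_ic50"]),
        fvt4=pop.pd_pop.fVT4 * math.exp(etas["omega_fvt4"]),
        beta=pop.pd_pop.beta * math.exp(etas["omega_beta"]),
        fixed=pop.pd_pop,
    )


def apply_residual_error(pred, sigma_prop: float, rng_seed):
    """Proportional residual error y = pred * (1 + sigma*eps), eps ~ N(0,1).

    Draws producing nonpositive values are redrawn (truncation), keeping
    observations inside the model's support; at sigma ~ 0.34 the redraw
    probability is ~0.2%.
    """
    if sigma_prop <= 0:
        raise ValueError("sigma_prop must be strictly positive")
    rng = _as_rng(rng_seed)
    pred_arr = np.atleast_1d(np.asarray(pred, dtype=float))
    if np.any(pred_arr <= 0):
        raise ValueError("proportional error is undefined for nonpositive predictions")
    out = pred_arr * (1.0 + sigma_prop * rng.standard_normal(pred_arr.shape))
    for _ in range(1000):
        bad = out <= 0
        if not np.any(bad):
            break
        out[bad] = pred_arr[bad] * (1.0 + sigma_prop * rng.standard_normal(int(bad.sum())))
    return float(out[0]) if np.isscalar(pred) else out


def simulate_population(cohort: "Sequence[VirtualPatient]",
                        pop: PopulationParameters, rng_seed,
                        with_noise: bool = True,
                        pk_mode: str = "simplified") -> list[FT4Profile]:
    """Simulate FT4 at each patient's visit times under the population model.

    Patients that already carry individual parameters (``truth`` set) are
    simulated with them; otherwise parameters are sampled from the population
    distribution.  Residual error is applied at the visit times when
    ``with_noise`` is set.  Deterministic per seed: one child RNG stream per
    patient for parameter sampling and one for residual noise, so toggling the
    noise does not change the sampled individuals.
    """
    rng = _as_rng(rng_seed)
    eta_rngs = rng.spawn(len(cohort))
    noise_rngs = rng.spawn(len(cohort))
    profiles: list[FT4Profile] = []
    for patient, eta_rng, noise_rng in zip(cohort, eta_rngs, noise_rngs):
        ind = patient.truth
        if ind is None:
            ind = sample_individual_parameters(pop, patient.covariates, eta_rng)
        times = np.asarray(patient.observation_times, dtype=float)
        kendo_mult = None
        if pop.use_treatment_covariate and patient.switch_day is not None:
            kendo_mult = (patient.switch_day, math.exp(pop.beta_treatment))
        prof = simulate_ft4(patient.regimen, patient.weight_fn(), ind.to_pd(),
                            pop.pk_pop, times, pk_mode=pk_mode,
                            kendo_multiplier_from=kendo_mult)
        if with_noise:
            prof = FT4Profile(times, apply_residual_error(
                prof.values, pop.sigma_prop, noise_rng))
        profiles.append(prof)
    return profiles
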
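"""Virtual-cohort generator emulating a pediatric Graves' disease population.

Generates patients whose covariate distributions, dosing behaviour and visit
structure match the retrospective cohort the model was developed on: 44
patients split 13/15/16 across mild/moderate/severe disease (graded by FT4 at
diagnosis), median age ~11 years, CMZ started at a median 0.72 mg/kg/day given
three times daily, ~39% switching to CMZ/LT4 block-and-replace therapy at a
median of day 75 with LT4 ~1.86 mcg/kg/day, and roughly 11 FT4 observations
per patient over a median 1.89 years of follow-up.

Dose titration in the source data followed unrecorded clinical judgement; the
generator uses a minimal synthetic controller (halve the CMZ dose when the
model-predicted FT4 falls below 12 pmol/l, increase it by 25% above 22 pmol/l)
that produces realistic dose histories but is not a clinical recommendation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .events import DoseEvent, Drug, tid_doses
from .params import IndividualParameters, PopulationParameters
from .population import (CovariateSet, Severity, Sex, classify_severity,
                         sample_individual_parameters)
from .pd import simulate_ft4

SEVERITY_ORDER = (Severity.MILD, Severity.MODERATE, Severity.SEVERE)


def interpolate_weight(measurements: Sequence[tuple[float, float]] | np.ndarray,
                       t: float | np.ndarray):
    """Piecewise-linear body weight between sparse measurements.

    Beyond the first/last measurement the weight is held constant (the nearest
    measured value).  ``measurements`` is a sequence of (time_days, kg) pairs.
    """
    arr = np.asarray(measurements, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one weight measurement is required")
    arr = arr.reshape(-1, 2)
    order = np.argsort(arr[:, 0])
    out = np.interp(np.asarray(t, dtype=float), arr[order, 0], arr[order, 1])
    return float(out) if np.isscalar(t) else out


@dataclass
class VirtualPatient:
    """One synthetic patient: covariates, weights, regimen and visit data."""

    id: int
    covariates: CovariateSet
    weight_times: np.ndarray
    weight_values: np.ndarray
    regimen: list[DoseEvent]
    observation_times: np.ndarray
    observations: np.ndarray | None = None
    truth: IndividualParameters | None = None
    switch_day: float | None = None
    followup_days: float | None = None

    def __post_init__(self) -> None:
        self.weight_times = np.asarray(self.weight_times, dtype=float)
        self.weight_values = np.asarray(self.weight_values, dtype=float)
        self.observation_times = np.asarray(self.observation_times, dtype=float)
        if self.observations is not None:
            self.observations = np.asarray(self.observations, dtype=float)
        if self.weight_times.size == 0:
            raise ValueError("a patient needs at least one weight measurement")
        if self.observation_times.size < 2:
            raise ValueError("a patient needs at least two follow-up visits")

    def weight_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        pairs = np.column_stack([self.weight_times, self.weight_values])
        return lambda t: interpolate_weight(pairs, t)

    @property
    def n_observations(self) -> int:
        return int(self.observation_times.size)


@dataclass
class CohortConfig:
    """Study-condition defaults of the emulated cohort (see module docstring)."""

    n_patients: int = 44
    severity_proportions: tuple[float, float, float] = (13 / 44, 15 / 44, 16 / 44)
    # per-severity (median, log-sd) calibrated to the reported medians/IQRs
    age_dist: dict = field(default_factory=lambda: {
        Severity.MILD: (12.0, 0.153),
        Severity.MODERATE: (10.8, 0.375),
        Severity.SEVERE: (8.9, 0.531)})
    ft4_dx_dist: dict = field(default_factory=lambda: {
        Severity.MILD: (38.9, 0.160, (15.0, 50.0)),
        Severity.MODERATE: (59.6, 0.115, (50.0, 70.0)),
        Severity.SEVERE: (84.8, 0.179, (70.0, 180.0))})
    weight_median: dict = field(default_factory=lambda: {
        Severity.MILD: 41.5, Severity.MODERATE: 30.5, Severity.SEVERE: 31.9})
    weight_log_sd: float = 0.2
    weight_growth_kg_per_year: float = 3.0
    p_female: float = 0.75
    cmz_start_per_kg: float = 0.72          # mg/kg/day, median
    cmz_start_log_sd: float = 0.222         # from the reported IQR (0.6, 0.81)
    cmz_per_kg_range: tuple[float, float] = (0.36, 1.40)
    tid_offsets: tuple[float, ...] = (0.0, 1 / 3, 2 / 3)
    daily_dose_range_mg: tuple[float, float] = (1.0, 60.0)
    # synthetic titration controller
    titration_low: float = 12.0             # pmol/l: below -> halve CMZ
    titration_high: float = 22.0            # pmol/l: above -> +25% CMZ
    p_switch: float = 17 / 44
    switch_day_median: float = 75.0
    switch_day_log_sd: float = 0.933        # from the reported IQR (52, 183)
    switch_day_range: tuple[float, float] = (28.0, 364.0)
    cmz_at_switch_per_kg: float = 0.42      # mg/kg/day
    lt4_start_per_kg: float = 1.86          # mcg/kg/day
    lt4_dose_range_mcg: tuple[float, float] = (12.5, 250.0)
    # visit schedule: weeks 0,2,4,6,8 then 12-weekly, +-4 day jitter
    early_visit_days: tuple[float, ...] = (0.0, 14.0, 28.0, 42.0, 56.0)
    late_visit_interval_days: float = 84.0
    visit_jitter_days: float = 4.0
    followup_years_median: float = 1.89
    followup_years_log_sd: float = 0.113    # from the reported IQR (1.69, 1.97)
    followup_years_range: tuple[float, float] = (126 / 365.25, 812 / 365.25)
    age_range: tuple[float, float] = (2.0, 17.9)

    def __post_init__(self) -> None:
        if abs(sum(self.severity_proportions) - 1.0) > 1e-9:
            raise ValueError("severity proportions must sum to 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name in ("cmz_start_per_kg", "lt4_start_per_kg", "cmz_at_switch_per_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _trunc_lognormal(rng: np.random.Generator, median: float, log_sd: float,
                     bounds: tuple[float, float]) -> float:
    """One draw from a log-normal with the given median, redrawn into bounds."""
    lo, hi = bounds
    for _ in range(1000):
        x = median * math.exp(rng.normal(0.0, log_sd))
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))  # pragma: no cover


def generate_covariates(config: CohortConfig, rng_seed) -> list[CovariateSet]:
    """Draw covariate sets with the cohort's severity mix and distributions.

    FT4 at diagnosis is drawn from a per-severity truncated log-normal, so
    every patient's FT4 classifies into its assigned severity stratum.
    """
    rng = _as_rng(rng_seed)
    out: list[CovariateSet] = []
    for _ in range(config.n_patients):
        severity = SEVERITY_ORDER[rng.choice(3, p=config.severity_proportions)]
        med, sd = config.age_dist[severity]
        age = _trunc_lognormal(rng, med, sd, config.age_range)
        med, sd, bounds = config.ft4_dx_dist[severity]
        ft4 = _trunc_lognormal(rng, med, sd, bounds)
        # keep strictly inside the open class boundaries
        if severity is Severity.MILD:
            ft4 = min(ft4, 50.0 - 1e-6)
        elif severity is Severity.SEVERE:
            ft4 = max(ft4, 70.0 + 1e-6)
        sex = Sex.F if rng.random() < config.p_female else Sex.M
        assert classify_severity(ft4) == severity
        out.append(CovariateSet(age_dx=age, sex=sex, severity=severity, ft4_dx=ft4))
    return out


def _visit_days(config: CohortConfig, followup_days: float,
                rng: np.random.Generator) -> np.ndarray:
    days = list(config.early_visit_days)
    t = days[-1] + config.late_visit_interval_days
    while t <= followup_days:
        days.append(t)
        t += config.late_visit_interval_days
    days = np.asarray(days, dtype=float)
    jitter = rng.uniform(-config.visit_jitter_days, config.visit_jitter_days,
                         size=days.size)
    jitter[0] = 0.0
    days = np.maximum.accumulate(np.maximum(days + jitter, 0.0))
    return np.unique(days[days <= followup_days])


def generate_regimen(cov: CovariateSet, weight_fn, config: CohortConfig,
                     rng_seed, visit_days: Sequence[float] | None = None,
                     followup_days: float | None = None,
                     ind_params: IndividualParameters | None = None,
                     pop: PopulationParameters | None = None,
                     with_noise: bool = True,
                     ) -> tuple[list[DoseEvent], float | None, np.ndarray]:
    """Build a dose history: tid CMZ start, titration at visits, optional switch.

    Returns ``(events, switch_day, ft4_observations)``.  The starting total
    daily dose is the drawn mg/kg/day times the weight at treatment start,
    split into three equal doses at 8-hour intervals.  At each visit the
    model-predicted FT4 for this patient is *measured* (residual error
    applied when ``with_noise``), recorded as that visit's observation, and
    fed to the synthetic titration controller, which adjusts the CMZ dose
    (or, after the block-and-replace switch, the LT4 dose) from the next day
    on.  Because dosing decisions depend only on the recorded measurements --
    exactly as a treating clinician's do -- the dose history stays
    non-informative about the latent random effects given the observed data,
    which keeps likelihood-based refitting of generated cohorts consistent.
    """
    from .population import apply_residual_error, individual_endogenous_rate

    rng = _as_rng(rng_seed)
    if pop is None:
        pop = PopulationParameters()
    if ind_params is None:
        ind_params = IndividualParameters(
            kendo=individual_endogenous_rate(pop, cov, 0.0),
            ic50=pop.pd_pop.IC50, fvt4=pop.pd_pop.fVT4,
            beta=pop.pd_pop.beta, fixed=pop.pd_pop)
    if followup_days is None:
        followup_days = 365.25 * config.followup_years_median
    if visit_days is None:
        visit_days = _visit_days(config, followup_days, rng)
    visit_days = np.asarray(visit_days, dtype=float)

    per_kg = _trunc_lognormal(rng, config.cmz_start_per_kg,
                              config.cmz_start_log_sd, config.cmz_per_kg_range)
    lo_mg, hi_mg = config.daily_dose_range_mg
    cmz_daily = float(np.clip(per_kg * weight_fn(np.array([0.0]))[0], lo_mg, hi_mg))

    switch_day: float | None = None
    if rng.random() < config.p_switch:
        switch_day = float(round(_trunc_lognormal(
            rng, config.switch_day_median, config.switch_day_log_sd,
            config.switch_day_range)))

    lt4_daily: float | None = None
    events: list[DoseEvent] = []
    visit_by_day = {int(round(v)): (i, float(v))
                    for i, v in enumerate(visit_days)}
    observations = np.full(visit_days.size, np.nan)
    n_days = int(math.ceil(float(max(followup_days, visit_days.max() + 1.0))))
    pd_ind = ind_params.to_pd()

    def measure_ft4(t_obs: float) -> float:
        prof = simulate_ft4(events, weight_fn, pd_ind, pop.pk_pop,
                            np.array([t_obs]), pk_mode="simplified")
        pred = float(prof.values[0])
        if with_noise:
            return float(apply_residual_error(pred, pop.sigma_prop, rng))
        return pred

    pending: str | None = None
    for day in range(n_days):
        # decisions from the previous visit take effect the following day
        if pending == "halve":
            cmz_daily = max(cmz_daily * 0.5, lo_mg)
        elif pending == "increase":
            cmz_daily = min(cmz_daily * 1.25, hi_mg)
        elif pending == "lt4_up":
            lt4_daily = min(lt4_daily * 1.25, config.lt4_dose_range_mcg[1])
        elif pending == "lt4_down":
            lt4_daily = max(lt4_daily * 0.75, config.lt4_dose_range_mcg[0])
        pending = None
        if switch_day is not None and day == int(switch_day):
            w = float(weight_fn(np.array([float(day)]))[0])
            cmz_daily = float(np.clip(config.cmz_at_switch_per_kg * w, lo_mg, hi_mg))
            lt4_daily = float(np.clip(config.lt4_start_per_kg * w,
                                      *config.lt4_dose_range_mcg))
        events.extend(tid_doses(cmz_daily, float(day), config.tid_offsets))
        if lt4_daily is not None:
            events.append(DoseEvent(Drug.LT4, lt4_daily, float(day)))
        if day in visit_by_day:
            i, t_obs = visit_by_day[day]
            ft4 = measure_ft4(t_obs)
            observations[i] = ft4
            if day > 0:
                if lt4_daily is None:
                    if ft4 < config.titration_low:
                        pending = "halve"
                    elif ft4 > config.titration_high:
                        pending = "increase"
                else:
                    if ft4 < config.titration_low:
                        pending = "lt4_up"
                    elif ft4 > config.titration_high:
                        pending = "lt4_down"
    if np.any(np.isnan(observations)):  # pragma: no cover - schedule invariant
        raise RuntimeError("some visits received no measurement")
    return events, switch_day, observations


def generate_cohort(config: CohortConfig, true_pop: PopulationParameters,
                    rng_seed, with_noise: bool = True) -> list[VirtualPatient]:
    """Generate a fit-ready cohort with simulated FT4 observations.

    Composes covariate generation, weight trajectories, regimen construction
    and population simulation with residual noise.  Identical seeds yield
    identical cohorts.
    """
    rng = _as_rng(rng_seed)
    covs = generate_covariates(config, rng)
    patients: list[VirtualPatient] = []
    for pid, cov in enumerate(covs, start=1):
        w0 = float(np.clip(
            config.weight_median[cov.severity] * math.exp(
                rng.normal(0.0, config.weight_log_sd)), 15.0, 90.0))
        followup = 365.25 * _trunc_lognormal(
            rng, config.followup_years_median, config.followup_years_log_sd,
            config.followup_years_range)
        growth = config.weight_growth_kg_per_year / 365.25

        def weight_fn(t, _w0=w0, _g=growth):
            return _w0 + _g * np.asarray(t, dtype=float)

        visit_days = _visit_days(config, followup, rng)
        truth = sample_individual_parameters(true_pop, cov, rng)
        regimen, switch_day, observations = generate_regimen(
            cov, weight_fn, config, rng, visit_days=visit_days,
            followup_days=followup, ind_params=truth, pop=true_pop,
            with_noise=with_noise)
        weight_times = visit_days.copy()
        patients.append(VirtualPatient(
            id=pid, covariates=cov,
            weight_times=weight_times, weight_values=weight_fn(weight_times),
            regimen=regimen, observation_times=visit_days,
            observations=observations,
            truth=truth, switch_day=switch_day, followup_days=followup))
    return patients


@dataclass
class CohortSummary:
    """Per-severity-group descriptive statistics (median and IQR)."""

    table: pd.DataFrame
    group_counts: dict[str, int]
    n_patients: int
    percent_female: float
    percent_monotherapy: float
    total_observations: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _med_iqr(x: np.ndarray) -> str:
    if len(x) == 0:
        return "-"
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return f"{q50:.2f} ({q25:.2f}, {q75:.2f})"


def summarize_cohort(cohort: Sequence[VirtualPatient]) -> CohortSummary:
    """Median/IQR descriptive summary per severity group and overall."""
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    for p in cohort:
        daily0 = sum(e.amount for e in p.regimen
                     if e.drug is Drug.CMZ and e.time < 1.0)
        rows.append({
            "severity": p.covariates.severity.value,
            "age": p.covariates.age_dx,
            "weight0": float(p.weight_values[0]),
            "ft4_dx": p.covariates.ft4_dx,
            "dose_per_kg": daily0 / float(p.weight_values[0]),
            "followup_years": (p.followup_days or p.observation_times[-1]) / 365.25,
            "female": p.covariates.sex is Sex.F,
            "monotherapy": p.switch_day is None,
            "n_obs": p.n_observations,
        })
    df = pd.DataFrame(rows)
    groups = {"all": df} | {
        sev.value: df[df.severity == sev.value] for sev in SEVERITY_ORDER}
    table = pd.DataFrame({
        name: {
            "patients_n": len(g),
            "female_pct": 100.0 * g.female.mean() if len(g) else float("nan"),
            "age_yrs": _med_iqr(g.age.to_numpy()),
            "weight_kg": _med_iqr(g.weight0.to_numpy()),
            "ft4_dx_pmol_l": _med_iqr(g.ft4_dx.dropna().to_numpy()),
            "cmz_start_mg_kg_day": _med_iqr(g.dose_per_kg.to_numpy()),
            "followup_yrs": _med_iqr(g.followup_years.to_numpy()),
            "monotherapy_pct": 100.0 * g.monotherapy.mean() if len(g) else float("nan"),
        }
        for name, g in groups.items()
    })
    counts = {sev.value: int((df.severity == sev.value).sum())
              for sev in SEVERITY_ORDER}
    return CohortSummary(
        table=table, group_counts=counts, n_patients=len(cohort),
        percent_female=100.0 * df.female.mean(),
        percent_monotherapy=100.0 * df.monotherapy.mean(),
        total_observations=int(df.n_obs.sum()))
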
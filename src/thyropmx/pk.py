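"""Pharmacokinetics of carbimazole (CMZ) and its active metabolite methimazole (MMZ).

Two model variants are provided:

* the **full model** — a linear multi-compartment system with first-order CMZ
  absorption (``kaC``), a metabolic transit step (``kt``) converting CMZ to MMZ
  with factor ``fM``, first-order MMZ elimination (``kelM``) and a peripheral
  distribution compartment (``k12``/``k21``); and
* the **simplified model** — a one-compartment IV-bolus model with one total
  dose per day, scaled by ``FC``, justified by the fast absorption and
  metabolism of CMZ relative to the weeks-to-months time scale of FT4 data.

Both report the MMZ concentration C(t) = A_M(t) / (fVM * W(t)) in mg/l.
Dose inputs are instantaneous boluses at the dose times; integration is exact
(matrix-exponential propagation between events).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import expm

from . import _engine
from .events import DoseEvent, Drug, aggregate_daily
from .params import PKParameters


class PKState(NamedTuple):
    """Amounts (mg) in the four PK compartments."""

    AbC: float  # CMZ in the absorption compartment
    AC: float   # CMZ in the central compartment
    AM: float   # MMZ in the central compartment
    P: float    # MMZ in the peripheral compartment


@dataclass
class ConcentrationProfile:
    """MMZ concentration (mg/l) on a strictly increasing time grid (days)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration values must be finite")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_days": self.times,
                      "conc_mg_per_l": self.values}).to_csv(path, index=False)


def pk_derivatives_full(state: PKState, params: PKParameters) -> PKState:
    """Right-hand sides of the full PK system (dose boluses excluded).

    dAbC = -kaC*AbC;  dAC = kaC*AbC - kt*AC;
    dAM = fM*kt*AC - kelM*AM - k12*AM + k21*P;  dP = k12*AM - k21*P.
    """
    arr = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("PK state must be finite")
    AbC, AC, AM, P = arr
    return PKState(
        AbC=-params.kaC * AbC,
        AC=params.kaC * AbC - params.kt * AC,
        AM=params.fM * params.kt * AC - params.kelM * AM - params.k12 * AM + params.k21 * P,
        P=params.k12 * AM - params.k21 * P,
    )


def mmz_concentration(AM: float, weight: float, fVM: float) -> float:
    """MMZ concentration (mg/l) from the central amount and body weight."""
    if weight <= 0:
        raise ValueError(f"body weight must be positive, got {weight}")
    return AM / (fVM * weight)


def _check_cmz_only(regimen: Sequence[DoseEvent]) -> list[DoseEvent]:
    for e in regimen:
        if e.drug is not Drug.CMZ:
            raise ValueError("PK simulation accepts CMZ dose events only")
    return sorted(regimen, key=lambda e: e.time)


def simulate_pk_full_amounts(regimen: Sequence[DoseEvent], params: PKParameters,
                             grid: np.ndarray) -> np.ndarray:
    """Amounts of the full model on the grid, with a 5th 'eliminated MMZ' column.

    The augmented state (AbC, AC, AM, P, E) with dE/dt = kelM*AM supports the
    mass-balance identity fM*(AbC+AC) + AM + P + E = fM * (total CMZ dosed).
    Propagation uses cached matrix exponentials, exact for this linear system.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and strictly increasing")
    if grid[0] < 0:
        raise ValueError("grid must start at or after t=0")
    doses = _check_cmz_only(regimen)

    A = np.zeros((5, 5))
    A[:4, :4] = _engine.full_pk_matrix(params)
    A[4, 2] = params.kelM

    dose_times = np.array([e.time for e in doses])
    dose_amounts = np.array([e.amount for e in doses])
    timeline = np.unique(np.concatenate([grid, dose_times, [0.0]]))

    cache: dict[float, np.ndarray] = {}

    def step(dt: float) -> np.ndarray:
        key = round(float(dt), 15)
        if key not in cache:
            cache[key] = expm(A * dt)
        return cache[key]

    state = np.zeros(5)
    out = np.empty((grid.size, 5))
    gi = 0
    prev_t = timeline[0]
    for t in timeline:
        if t > prev_t:
            state = step(t - prev_t) @ state
            prev_t = t
        # record pre-dose value if the grid point coincides with a dose? By the
        # bolus convention amounts jump at the dose time; report the post-dose
        # value so a dose at t=0 is visible on the profile.
        hits = dose_times == t
        if np.any(hits):
            state[0] += dose_amounts[hits].sum()
        while gi < grid.size and grid[gi] == t:
            out[gi] = state
            gi += 1
    return out


def simulate_pk_full(regimen: Sequence[DoseEvent], weight_fn, params: PKParameters,
                     grid: np.ndarray) -> ConcentrationProfile:
    """MMZ concentration profile of the full multi-compartment model.

    ``weight_fn`` is a constant weight in kg or a callable t(days) -> kg.
    """
    amounts = simulate_pk_full_amounts(regimen, params, grid)
    grid = np.asarray(grid, dtype=float)
    w = _engine.as_weight_fn(weight_fn)(grid)
    return ConcentrationProfile(grid, amounts[:, 2] / (params.fVM * w))


def simulate_pk_simplified(daily_doses: Sequence[DoseEvent], params: PKParameters,
                           grid: np.ndarray, weight_fn=None) -> ConcentrationProfile:
    """MMZ concentration of the simplified one-compartment daily-dose model.

    Each dose event contributes an IV bolus of FC * amount to the MMZ amount,
    which then decays mono-exponentially with kelM.  Events are aggregated to
    one total dose per dosing day.  ``weight_fn`` defaults to the reference
    body-weight-free value W = 1 kg if omitted (callers normally pass one).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and strictly increasing")
    doses = aggregate_daily(_check_cmz_only(daily_doses))
    dose_times = np.array([e.time for e in doses])
    dose_amounts = np.array([params.FC * e.amount for e in doses])

    timeline = np.unique(np.concatenate([grid, dose_times, [0.0]]))
    am = _engine.bolus_decay_amounts(timeline, params.kelM, dose_times, dose_amounts)
    am_on_grid = am[np.searchsorted(timeline, grid)]
    w = _engine.as_weight_fn(weight_fn if weight_fn is not None else 1.0)(grid)
    return ConcentrationProfile(grid, am_on_grid / (params.fVM * w))


def simplified_closed_form(dose: float, t_since_dose: float | np.ndarray,
                           weight: float, params: PKParameters) -> float | np.ndarray:
    """Analytic single-dose solution of the simplified model.

    C(t) = FC * dose / (fVM * weight) * exp(-kelM * t); serves as an
    independent oracle for :func:`simulate_pk_simplified`.
    """
    if weight <= 0:
        raise ValueError(f"body weight must be positive, got {weight}")
    t = np.asarray(t_since_dose, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since dose must be nonnegative")
    out = params.FC * dose / (params.fVM * weight) * np.exp(-params.kelM * t)
    return float(out) if np.isscalar(t_since_dose) else out


def peak_time(profile: ConcentrationProfile) -> float:
    """Grid time of the maximum concentration; ties broken by the earliest time."""
    if profile.times.size == 0:
        raise ValueError("profile is empty")
    return float(profile.times[int(np.argmax(profile.values))])


def daily_auc(profile: ConcentrationProfile, day_index: int) -> float:
    """Trapezoidal AUC (mg*day/l) of the profile over [day, day+1)."""
    lo, hi = float(day_index), float(day_index) + 1.0
    if profile.times[0] > lo or profile.times[-1] < hi:
        raise ValueError(f"profile does not cover day {day_index}")
    mask = (profile.times >= lo) & (profile.times <= hi)
    return float(np.trapezoid(profile.values[mask], profile.times[mask]))


def single_dose_grid(duration_days: float = 1.0,
                     spacing_days: float = 1.0 / 1440.0) -> np.ndarray:
    """A refined grid (default 1-minute spacing) for peak-time localization."""
    n = int(round(duration_days / spacing_days))
    return np.linspace(0.0, duration_days, n + 1)
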
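"""Structural and population parameter containers.

Default values are the published population estimates for the pediatric
Graves' disease cohort this model was developed on: fixed PK constants for
CMZ/MMZ taken from product labels and literature, and estimated PD, covariate
and variability parameters.  ``fix_flags`` mirrors which parameters were
estimated versus held fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class PKParameters:
    """Fixed structural constants of the CMZ/MMZ pharmacokinetic model.

    All rates are in 1/day.  ``fM`` is the CMZ->MMZ metabolic conversion
    factor, ``fVM`` (l/kg) relates body weight to the MMZ distribution volume,
    and ``FC`` is the dose scaling factor of the simplified one-compartment
    daily-dose model (defaults to ``fM``: the conversion factor moves into the
    input function when absorption and transit are collapsed).
    """

    kaC: float = 144.0       # CMZ absorption rate (1/day)
    kt: float = 28.8         # metabolic transit rate (1/day)
    fM: float = 0.61         # CMZ -> MMZ conversion factor (unitless)
    kelM: float = 2.77       # MMZ elimination rate (1/day), 6 h half-life
    k12: float = 2.4         # central -> peripheral distribution rate (1/day)
    k21: float = 2.4         # peripheral -> central distribution rate (1/day)
    fVM: float = 0.5         # weight -> MMZ volume proportionality (l/kg)
    FC: float = 0.61         # simplified-model dose scaling factor (unitless)

    def __post_init__(self) -> None:
        for name in ("kaC", "kt", "kelM", "k12", "k21", "fVM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.fM <= 1:
            raise ValueError("fM must lie in (0, 1]")
        if not 0 < self.FC <= 1:
            raise ValueError("FC must lie in (0, 1]")


@dataclass
class PDParameters:
    """Constants of the FT4 turnover model with Imax inhibition by MMZ.

    ``kendoT4`` (nmol/day) is the disease-elevated endogenous T4 production
    rate, inhibited by the MMZ concentration through a standard
    ``1 - Imax*C/(IC50 + C)`` term.  ``fVT4`` and ``beta`` give the allometric
    T4 distribution volume ``fVT4 * (W/WRef)**beta``.  ``FT4bio`` is the oral
    LT4 bioavailability; LT4 mcg doses are converted to nmol with
    ``lt4_factor``.
    """

    kaT4: float = 20.0       # LT4 absorption rate (1/day)
    kendoT4: float = 261.0   # endogenous T4 production rate (nmol/day)
    kelT4: float = 0.1       # T4 elimination rate (1/day)
    Imax: float = 0.9        # maximal inhibitory effect (unitless)
    IC50: float = 0.024      # MMZ conc. at half-maximal inhibition (mg/l)
    fVT4: float = 20.3       # T4 volume multiplicative factor (l)
    beta: float = 0.7        # allometric power exponent (unitless)
    FT4bio: float = 0.6      # LT4 bioavailability (unitless)
    WRef: float = 42.7       # reference body weight (kg)
    lt4_factor: float = 1.29  # mcg -> nmol conversion for LT4

    def __post_init__(self) -> None:
        for name in ("kaT4", "kendoT4", "kelT4", "IC50", "fVT4", "WRef", "lt4_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.Imax <= 1:
            raise ValueError("Imax must lie in (0, 1]")
        if not 0 < self.FT4bio <= 1:
            raise ValueError("FT4bio must lie in (0, 1]")


#: Parameters that were estimated (False) vs held fixed (True) in the
#: published analysis; everything not listed here is always fixed.
DEFAULT_FIX_FLAGS: dict[str, bool] = {
    "kendoT4": False,
    "IC50": False,
    "fVT4": False,
    "beta": False,
    "beta_age": False,
    "beta_cat1_severe": False,
    "beta_cat2_moderate": False,
    "omega_kendo": False,
    "omega_ic50": False,
    "sigma_prop": False,
    "omega_fvt4": True,
    "omega_beta": True,
}


@dataclass
class PopulationParameters:
    """Fixed effects, covariate coefficients, random-effect SDs and residual error.

    The covariate model acts on ``log kendoT4``: an age effect
    ``beta_age * log(age/AGERef)`` plus an additive severity shift (0 for mild,
    ``beta_cat2_moderate`` for moderate, ``beta_cat1_severe`` for severe).
    Inter-individual variability is log-normal with SDs ``omega_*``; the
    residual error is proportional with SD ``sigma_prop``.
    """

    pd_pop: PDParameters = field(default_factory=PDParameters)
    pk_pop: PKParameters = field(default_factory=PKParameters)
    beta_age: float = 0.464
    beta_cat1_severe: float = 0.52
    beta_cat2_moderate: float = 0.16
    AGERef: float = 8.98
    omega_kendo: float = 0.04
    omega_ic50: float = 0.77
    omega_fvt4: float = 0.1
    omega_beta: float = 0.25
    sigma_prop: float = 0.344
    # Optional exploratory on/off treatment-type effect on kendoT4 (applied on
    # the log scale from the block-and-replace switch onward); disabled by
    # default and never estimated.
    beta_treatment: float = 0.0
    use_treatment_covariate: bool = False
    fix_flags: dict[str, bool] = field(
        default_factory=lambda: dict(DEFAULT_FIX_FLAGS))

    def __post_init__(self) -> None:
        for name in ("omega_kendo", "omega_ic50", "omega_fvt4", "omega_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sigma_prop <= 0:
            raise ValueError("sigma_prop must be strictly positive")
        if self.AGERef <= 0:
            raise ValueError("AGERef must be strictly positive")

    def copy(self) -> "PopulationParameters":
        return dataclasses.replace(
            self,
            pd_pop=dataclasses.replace(self.pd_pop),
            pk_pop=dataclasses.replace(self.pk_pop),
            fix_flags=dict(self.fix_flags),
        )


@dataclass
class IndividualParameters:
    """One patient's realized structural parameters.

    ``kendo``, ``ic50``, ``fvt4`` and ``beta`` carry the individual (random
    effect + covariate) values; every other constant is inherited from
    ``fixed``.
    """

    kendo: float
    ic50: float
    fvt4: float
    beta: float
    fixed: PDParameters = field(default_factory=PDParameters)

    def __post_init__(self) -> None:
        for name in ("kendo", "ic50", "fvt4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_pd(self) -> PDParameters:
        """Materialize a complete PDParameters set for this individual."""
        return dataclasses.replace(
            self.fixed, kendoT4=self.kendo, IC50=self.ic50,
            fVT4=self.fvt4, beta=self.beta)

    @classmethod
    def typical(cls, pd_pop: PDParameters) -> "IndividualParameters":
        """The population-typical individual (all random effects zero)."""
        return cls(kendo=pd_pop.kendoT4, ic50=pd_pop.IC50,
                   fvt4=pd_pop.fVT4, beta=pd_pop.beta, fixed=pd_pop)
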
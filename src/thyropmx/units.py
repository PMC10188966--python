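"""Dose-unit conversions between carbimazole (CMZ), methimazole (MMZ) and levothyroxine (LT4).

CMZ is an oral prodrug that is rapidly and essentially completely converted to
its active metabolite MMZ; on a mass basis the conversion is the ratio of
molecular weights, MW_MMZ / MW_CMZ = 114.17 / 186.23 ~ 0.61.  LT4 doses are
prescribed in micrograms but enter the thyroid turnover model in nmol/day; the
mass-to-amount factor is 1000 / MW_T4 = 1000 / 776.9 ~ 1.29 nmol per mcg.
"""

from __future__ import annotations

import math

MW_CMZ = 186.23
"""Molecular weight of carbimazole (g/mol)."""

MW_MMZ = 114.17
"""Molecular weight of methimazole (g/mol)."""

MW_T4 = 776.9
"""Molecular weight of thyroxine (g/mol)."""

CMZ_TO_MMZ_FACTOR = MW_MMZ / MW_CMZ
"""Exact mass conversion factor CMZ -> MMZ (0.6131...; conventionally rounded to 0.61)."""

MMZ_PER_CMZ_REPORTED = 0.61
"""Rounded CMZ -> MMZ factor used for dose reporting and as the default f^M / F^C."""

LT4_MCG_TO_NMOL = 1.29
"""Conventional mcg -> nmol conversion factor for LT4 (1000/776.9 rounded to 2 decimals)."""


def cmz_to_mmz_dose(dose_cmz: float) -> float:
    """Convert a CMZ dose (mg) to the equivalent MMZ dose (mg).

    Uses the exact molecular-weight ratio; 1 mg CMZ corresponds to 0.61 mg MMZ
    at the conventional 2-decimal rounding.
    """
    if dose_cmz < 0:
        raise ValueError(f"CMZ dose must be nonnegative, got {dose_cmz}")
    return dose_cmz * CMZ_TO_MMZ_FACTOR


def mmz_to_cmz_dose(dose_mmz: float) -> float:
    """Convert an MMZ dose (mg) to the CMZ dose (mg) delivering it.

    Uses the rounded convention 1 mg CMZ = 0.61 mg MMZ, so 10 and 30 mg MMZ
    map to 16.4 and 49.2 mg CMZ (at 1-decimal reporting precision).
    """
    if dose_mmz < 0:
        raise ValueError(f"MMZ dose must be nonnegative, got {dose_mmz}")
    return dose_mmz / MMZ_PER_CMZ_REPORTED


def lt4_mcg_to_nmol(dose_mcg: float) -> float:
    """Convert an LT4 dose from mcg to nmol with the conventional factor 1.29."""
    if dose_mcg < 0:
        raise ValueError(f"LT4 dose must be nonnegative, got {dose_mcg}")
    return dose_mcg * LT4_MCG_TO_NMOL


def rate_from_half_life(t_half_days: float) -> float:
    """First-order rate constant (1/day) from a half-life in days.

    A 6 h (0.25 day) MMZ half-life gives ln(2)/0.25 = 2.77/day at 2-decimal
    rounding.
    """
    if t_half_days <= 0:
        raise ValueError(f"half-life must be positive, got {t_half_days}")
    return math.log(2.0) / t_half_days
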
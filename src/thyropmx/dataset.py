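"""Event-record dataset reader/writer.

The on-disk format is a NONMEM-inspired CSV with one row per event:

    ID,TIME,EVID,DV,AMT,DRUG,WT,AGE,SEX,SEVERITY

EVID 0 marks an FT4 observation (DV in pmol/l, AMT empty); EVID 1 marks a dose
(AMT in mg for CMZ or mcg for LT4, DV empty).  WT (kg) may be present on any
row whose time carries a body-weight measurement; covariates (AGE at
diagnosis, SEX, SEVERITY) are constant within a patient.  Times are days since
treatment start.  Patients with fewer than two observations are excluded with
a warning, mirroring the minimum follow-up inclusion criterion.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .cohort import VirtualPatient
from .events import DoseEvent, Drug
from .population import CovariateSet, Severity, Sex

logger = logging.getLogger(__name__)

COLUMNS = ["ID", "TIME", "EVID", "DV", "AMT", "DRUG", "WT", "AGE", "SEX", "SEVERITY"]


class DatasetError(ValueError):
    """Raised when an event dataset violates the format invariants."""


def write_dataset(cohort: Sequence[VirtualPatient], path) -> None:
    """Write a cohort as an event CSV.

    Row order is deterministic: by patient ID, then time, with doses preceding
    observations at equal times.  Numbers are rendered at full (repr)
    precision so a write/read round trip is lossless.
    """
    rows: list[dict] = []
    for p in sorted(cohort, key=lambda q: q.id):
        weight_map = {float(t): float(w)
                      for t, w in zip(p.weight_times, p.weight_values)}
        cov = p.covariates
        base = {"ID": p.id, "AGE": cov.age_dx, "SEX": cov.sex.value,
                "SEVERITY": cov.severity.value}
        event_times = {float(e.time) for e in p.regimen} | {
            float(t) for t in p.observation_times}
        stray = set(weight_map) - event_times
        if stray:
            raise DatasetError(
                f"patient {p.id}: weight measurements at {sorted(stray)[:5]} do "
                "not coincide with any dose or observation time")
        for e in p.regimen:
            rows.append(base | {"TIME": float(e.time), "EVID": 1, "DV": None,
                                "AMT": float(e.amount), "DRUG": e.drug.value,
                                "WT": weight_map.get(float(e.time))})
        obs_vals = (p.observations if p.observations is not None
                    else [None] * len(p.observation_times))
        for t, v in zip(p.observation_times, obs_vals):
            rows.append(base | {"TIME": float(t), "EVID": 0,
                                "DV": None if v is None else float(v),
                                "AMT": None, "DRUG": None,
                                "WT": weight_map.get(float(t))})
    df = pd.DataFrame(rows, columns=COLUMNS)
    if len(df):
        df = df.sort_values(["ID", "TIME", "EVID"],
                            ascending=[True, True, False], kind="stable")
    df.to_csv(path, index=False)


def read_dataset(path) -> list[VirtualPatient]:
    """Read an event CSV back into virtual patients.

    Validates the format invariants (duplicate events, unknown drugs, required
    empty cells) and drops patients with fewer than two observations, logging
    a warning for each exclusion.
    """
    df = pd.read_csv(path, dtype={"SEX": "string", "SEVERITY": "string",
                                  "DRUG": "string"},
                     float_precision="round_trip")
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(f"missing required columns: {sorted(missing)}")
    if len(df) == 0:
        return []
    if df["TIME"].min() < 0:
        raise DatasetError("negative TIME values are not allowed")
    if not df["EVID"].isin([0, 1]).all():
        bad = sorted(df.loc[~df["EVID"].isin([0, 1]), "EVID"].unique())
        raise DatasetError(f"EVID must be 0 (observation) or 1 (dose), got {bad}")

    dup_mask = df.duplicated(subset=["ID", "TIME", "EVID", "DRUG"], keep=False)
    # duplicate observations at the same time are ambiguous; duplicate dose
    # rows for the same drug at the same instant are almost certainly errors
    if dup_mask.any():
        offenders = df.loc[dup_mask, ["ID", "TIME", "EVID", "DRUG"]]
        raise DatasetError(
            "duplicate (ID, TIME, EVID, DRUG) rows:\n"
            + offenders.drop_duplicates().head(10).to_string(index=False))

    doses = df[df.EVID == 1]
    obs = df[df.EVID == 0]
    unknown = set(doses["DRUG"].dropna()) - {d.value for d in Drug}
    if unknown:
        raise DatasetError(f"unknown DRUG values: {sorted(unknown)}")
    if doses["DRUG"].isna().any():
        raise DatasetError("dose rows (EVID=1) must carry a DRUG label")
    if doses["AMT"].isna().any():
        raise DatasetError("dose rows (EVID=1) must carry an AMT")
    if doses["DV"].notna().any():
        raise DatasetError("dose rows (EVID=1) must leave DV empty")
    if obs["AMT"].notna().any() or obs["DRUG"].notna().any():
        raise DatasetError("observation rows (EVID=0) must leave AMT and DRUG empty")

    patients: list[VirtualPatient] = []
    for pid, g in df.groupby("ID", sort=True):
        for col in ("AGE", "SEX", "SEVERITY"):
            if g[col].isna().any() or g[col].nunique() != 1:
                raise DatasetError(
                    f"patient {pid}: covariate {col} must be present and "
                    "constant within the patient")
        g_obs = g[g.EVID == 0]
        if len(g_obs) < 2:
            logger.warning(
                "patient %s excluded: %d observation(s), need at least 2",
                pid, len(g_obs))
            continue
        g_dose = g[g.EVID == 1].sort_values("TIME", kind="stable")
        regimen = [DoseEvent(Drug(r.DRUG), float(r.AMT), float(r.TIME))
                   for r in g_dose.itertuples()]
        wt = g[g.WT.notna()].sort_values("TIME", kind="stable")
        wt = wt.drop_duplicates(subset="TIME")
        if len(wt) == 0:
            raise DatasetError(f"patient {pid}: no body-weight measurements")
        cov = CovariateSet(age_dx=float(g["AGE"].iloc[0]),
                           sex=Sex(str(g["SEX"].iloc[0])),
                           severity=Severity(str(g["SEVERITY"].iloc[0])))
        g_obs = g_obs.sort_values("TIME", kind="stable")
        observations = (g_obs["DV"].to_numpy(dtype=float)
                        if g_obs["DV"].notna().all() else None)
        patients.append(VirtualPatient(
            id=int(pid), covariates=cov,
            weight_times=wt["TIME"].to_numpy(dtype=float),
            weight_values=wt["WT"].to_numpy(dtype=float),
            regimen=regimen,
            observation_times=g_obs["TIME"].to_numpy(dtype=float),
            observations=observations,
            switch_day=_first_lt4_day(regimen)))
    return patients


def _first_lt4_day(regimen: Sequence[DoseEvent]) -> float | None:
    lt4 = [e.time for e in regimen if e.drug is Drug.LT4]
    return min(lt4) if lt4 else None
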
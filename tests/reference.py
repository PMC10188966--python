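"""Independent reference implementations used as numerical oracles.

Everything here integrates the model equations with scipy's adaptive ODE
solver (restarted at every dose event so bolus jumps are exact), deliberately
sharing no code with the package's semi-analytic engine.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from thyropmx.events import Drug, aggregate_daily
from thyropmx.params import PDParameters, PKParameters

_RTOL = 1e-10
_ATOL = 1e-12


def _weight_fn(weight):
    if callable(weight):
        return weight
    return lambda t: np.full_like(np.asarray(t, dtype=float), float(weight))


def _segmented_solve(rhs, boluses, y0, grid):
    """Integrate piecewise between events; record the solution on the grid.

    ``boluses`` is a list of (time, state_increment_vector).  Integration is
    restarted at every event time; a grid point coinciding with a bolus time
    reports the post-bolus state.
    """
    grid = np.asarray(grid, dtype=float)
    bolus_map: dict[float, np.ndarray] = {}
    for t_b, inc in boluses:
        key = float(t_b)
        bolus_map[key] = bolus_map.get(key, 0.0) + np.asarray(inc, dtype=float)
    checkpoints = np.unique(np.concatenate(
        [grid, np.array(sorted(bolus_map)), [0.0]]))
    y = np.array(y0, dtype=float)
    out = np.empty((grid.size, y.size))
    t_cur = checkpoints[0]
    if t_cur in bolus_map:
        y = y + bolus_map[t_cur]
    for gi in np.where(grid == t_cur)[0]:
        out[gi] = y
    for t_next in checkpoints[1:]:
        sol = solve_ivp(rhs, (t_cur, t_next), y, method="LSODA",
                        rtol=_RTOL, atol=_ATOL)
        y = sol.y[:, -1]
        if float(t_next) in bolus_map:
            y = y + bolus_map[float(t_next)]
        for gi in np.where(grid == t_next)[0]:
            out[gi] = y
        t_cur = t_next
    return out


def pk_full_amounts_ode(regimen, params: PKParameters, grid) -> np.ndarray:
    """Full PK amounts (AbC, AC, AM, P, eliminated) by adaptive ODE solving."""

    def rhs(t, s):
        AbC, AC, AM, P, E = s
        return [-params.kaC * AbC,
                params.kaC * AbC - params.kt * AC,
                params.fM * params.kt * AC - params.kelM * AM
                - params.k12 * AM + params.k21 * P,
                params.k12 * AM - params.k21 * P,
                params.kelM * AM]

    boluses = sorted(
        ((e.time, np.array([e.amount, 0.0, 0.0, 0.0, 0.0])) for e in regimen),
        key=lambda p: p[0])
    return _segmented_solve(rhs, boluses, np.zeros(5), grid)


def ft4_ode(regimen, weight, pd: PDParameters, pk: PKParameters, grid,
            pk_mode: str = "simplified") -> np.ndarray:
    """FT4 (pmol/l) on the grid by adaptive ODE solving of the joint system."""
    wfn = _weight_fn(weight)
    cmz = sorted((e for e in regimen if e.drug is Drug.CMZ), key=lambda e: e.time)
    lt4 = sorted((e for e in regimen if e.drug is Drug.LT4), key=lambda e: e.time)

    if pk_mode == "simplified":
        daily = aggregate_daily(cmz)
        boluses = [(e.time, np.array([pk.FC * e.amount, 0.0, 0.0]))
                   for e in daily]
        boluses += [(e.time,
                     np.array([0.0, pd.FT4bio * pd.lt4_factor * e.amount, 0.0]))
                    for e in lt4]
        y0 = np.array([0.0, 0.0, pd.kendoT4 / pd.kelT4])

        def rhs(t, s):
            AM, AbT4, T4 = s
            cm = AM / (pk.fVM * float(wfn(np.asarray(t))))
            prod = pd.kendoT4 * (1.0 - pd.Imax * cm / (pd.IC50 + cm))
            return [-pk.kelM * AM,
                    -pd.kaT4 * AbT4,
                    pd.kaT4 * AbT4 + prod - pd.kelT4 * T4]

        t4_col = 2
    elif pk_mode == "full":
        boluses = [(e.time, np.array([e.amount, 0, 0, 0, 0, 0.0]))
                   for e in cmz]
        boluses += [(e.time,
                     np.array([0, 0, 0, 0,
                               pd.FT4bio * pd.lt4_factor * e.amount, 0.0]))
                    for e in lt4]
        y0 = np.zeros(6)
        y0[5] = pd.kendoT4 / pd.kelT4

        def rhs(t, s):
            AbC, AC, AM, P, AbT4, T4 = s
            cm = AM / (pk.fVM * float(wfn(np.asarray(t))))
            prod = pd.kendoT4 * (1.0 - pd.Imax * cm / (pd.IC50 + cm))
            return [-pk.kaC * AbC,
                    pk.kaC * AbC - pk.kt * AC,
                    pk.fM * pk.kt * AC - pk.kelM * AM - pk.k12 * AM + pk.k21 * P,
                    pk.k12 * AM - pk.k21 * P,
                    -pd.kaT4 * AbT4,
                    pd.kaT4 * AbT4 + prod - pd.kelT4 * T4]

        t4_col = 5
    else:
        raise ValueError(pk_mode)

    boluses.sort(key=lambda p: p[0])
    grid = np.asarray(grid, dtype=float)
    states = _segmented_solve(rhs, boluses, y0, grid)
    t4 = states[:, t4_col]
    vol = pd.fVT4 * (np.asarray(wfn(grid), dtype=float) / pd.WRef) ** pd.beta
    return 0.3 * t4 / vol
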
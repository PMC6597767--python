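"""What-if analysis on the fitted FT4 formula.

The fitted closed form ties three quantities together through
``F(t, d, y) = y - y(t, d) = 0``: treatment time ``t`` (days), daily dose
``d`` (mg) and the FT4 level ``y`` (pmol/l). Given any two, the third is
solved for:

* unknown ``y`` — direct evaluation of the closed form;
* unknown ``d`` — a sign-change scan over ``[0, dose_cap]`` followed by
  bracketed root refinement (monotonicity in ``d`` is not assumed; the
  smallest root — the lowest effective dose — is returned);
* unknown ``t`` — closed-form inversion of the reciprocal identity,
  cross-checkable against bisection.

Infeasibility (a target below the steady state reachable at the cap, or
above the starting level) is part of the answer, not an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import DomainError
from .kinetics import ft4_asymptote, ft4_solution
from .params import ModelParams

__all__ = [
    "WhatIfQuery",
    "WhatIfAnswer",
    "solve_whatif",
    "predict_ft4",
    "solve_dose",
    "solve_time",
    "solve_time_bisect",
    "dose_grid",
    "target_grid",
    "trajectory",
]

#: residual tolerance scale for a solved answer
_RESID_RTOL = 1e-6


@dataclass(frozen=True)
class WhatIfAnswer:
    """Result of a three-way solve.

    ``status`` is ``"solved"``, ``"infeasible"`` or ``"at_bound"``;
    ``value`` is the solved quantity (also populated for ``at_bound``,
    where the unconstrained solution lies beyond the cap named in
    ``bound_hit``). Infeasible answers carry a ``reason`` and, for dose
    solves, the achievable FT4 range at the given time.
    """

    value: float | None
    residual: float
    status: str
    bound_hit: str | None = None
    reason: str | None = None
    achievable: tuple | None = None

    @property
    def ok(self) -> bool:
        return self.status == "solved"


@dataclass(frozen=True)
class WhatIfQuery:
    """A (t, d, y) triple with exactly one unknown (set it to None)."""

    params: ModelParams
    t: float | None = None
    d: float | None = None
    y: float | None = None
    dose_cap: float = 60.0
    time_cap: float = 730.0

    def __post_init__(self):
        unknowns = [name for name in ("t", "d", "y") if getattr(self, name) is None]
        if len(unknowns) != 1:
            raise DomainError(
                f"exactly one of t, d, y must be unknown; got {unknowns or 'none'}"
            )


def solve_whatif(q: WhatIfQuery) -> WhatIfAnswer:
    """Dispatch a query to the appropriate solver."""
    if q.y is None:
        return predict_ft4(q.params, q.t, q.d)
    if q.d is None:
        return solve_dose(q.params, q.t, q.y, dose_cap=q.dose_cap)
    return solve_time(q.params, q.d, q.y, time_cap=q.time_cap)


def predict_ft4(p: ModelParams, t: float, d: float) -> WhatIfAnswer:
    """Question (i): FT4 after ``t`` days on a constant daily dose ``d``."""
    y = float(ft4_solution(p, t, d))
    return WhatIfAnswer(value=y, residual=0.0, status="solved")


def solve_dose(
    p: ModelParams,
    t: float,
    y: float,
    dose_cap: float = 60.0,
    n_scan: int = 129,
) -> WhatIfAnswer:
    """Question (ii): daily dose reaching FT4 ``y`` after ``t`` days.

    Scans ``F(t, ., y)`` on a uniform grid over ``[0, dose_cap]`` (at least
    64 points) and refines the first sign change by bracketed root finding;
    the smallest root is the lowest effective dose. When the target lies
    outside the FT4 range achievable over the interval the answer is
    infeasible and reports that range.
    """
    if t <= 0:
        raise DomainError("solve_dose needs t > 0")
    if y <= 0:
        raise DomainError("target FT4 must be positive")
    n_scan = max(n_scan, 64)
    grid = np.linspace(0.0, dose_cap, n_scan)
    g = np.asarray(ft4_solution(p, t, grid)) - y

    exact = np.flatnonzero(np.abs(g) == 0.0)
    if exact.size:
        d_root = float(grid[exact[0]])
    else:
        sign_change = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)
        if sign_change.size == 0:
            lo, hi = float(np.min(g) + y), float(np.max(g) + y)
            return WhatIfAnswer(
                value=None,
                residual=float(np.min(np.abs(g))),
                status="infeasible",
                reason=(
                    f"target {y} pmol/l not achievable at t={t} d within "
                    f"0..{dose_cap} mg; achievable FT4 range is [{lo:.3g}, {hi:.3g}]"
                ),
                achievable=(lo, hi),
            )
        k = sign_change[0]
        d_root = float(
            brentq(
                lambda d: float(ft4_solution(p, t, d)) - y,
                grid[k],
                grid[k + 1],
                xtol=1e-6,
            )
        )
    resid = abs(float(ft4_solution(p, t, d_root)) - y)
    status = "solved"
    bound = None
    if dose_cap - d_root <= 1e-6:
        status, bound = "at_bound", "dose_cap"
    return WhatIfAnswer(value=d_root, residual=resid, status=status, bound_hit=bound)


def solve_time(
    p: ModelParams,
    d: float,
    y: float,
    time_cap: float = 730.0,
) -> WhatIfAnswer:
    """Question (iii): days of constant dosing at ``d`` to reach FT4 ``y``.

    Closed-form inversion of the reciprocal identity:

        t = -(ic50+d)/(a*ic50) * ln[ (1/y - c*(ic50+d)/(a*ic50)) / c1 ]

    Feasible exactly when the log argument lies in (0, 1]: targets at or
    below the steady state are never attained, and targets above the
    starting level are already passed at t = 0.
    """
    if d < 0:
        raise DomainError("dose must be nonnegative")
    if y <= 0:
        raise DomainError("target FT4 must be positive")
    ab = p.a_ic50 / (p.ic50 + d)
    inv_steady = p.c / ab
    arg = (1.0 / y - inv_steady) / p.c1
    y_start = float(ft4_solution(p, 0.0, d))
    if arg <= 0:
        return WhatIfAnswer(
            value=None, residual=np.inf, status="infeasible",
            reason=(
                f"target {y} pmol/l is at or below the steady state "
                f"{ft4_asymptote(p, d):.3g} pmol/l at dose {d} mg; never attained"
            ),
        )
    if arg > 1:
        return WhatIfAnswer(
            value=None, residual=np.inf, status="infeasible",
            reason=(
                f"target {y} pmol/l exceeds the starting level "
                f"{y_start:.3g} pmol/l; already below target at t = 0"
            ),
        )
    t = float(-np.log(arg) / ab)
    resid = abs(float(ft4_solution(p, t, d)) - y)
    if t > time_cap:
        return WhatIfAnswer(
            value=t, residual=resid, status="at_bound", bound_hit="time_cap",
            reason=f"required time {t:.1f} d exceeds the {time_cap} d horizon",
        )
    return WhatIfAnswer(value=t, residual=resid, status="solved")


def solve_time_bisect(
    p: ModelParams, d: float, y: float, time_cap: float = 730.0
) -> WhatIfAnswer:
    """Bisection counterpart of :func:`solve_time` (cross-validation route)."""
    f = lambda t: float(ft4_solution(p, t, d)) - y
    f0, fcap = f(0.0), f(time_cap)
    if f0 < 0:
        return WhatIfAnswer(None, np.inf, "infeasible",
                            reason="already below target at t = 0")
    if f0 == 0.0:
        return WhatIfAnswer(0.0, 0.0, "solved")
    if fcap > 0:
        return WhatIfAnswer(None, abs(fcap), "infeasible",
                            reason=f"target not reached within {time_cap} d")
    t = float(brentq(f, 0.0, time_cap, xtol=1e-8))
    return WhatIfAnswer(t, abs(f(t)), "solved")


# ---------------------------------------------------------------------------
# report tables and curves (rounding happens only here, at the table layer)
# ---------------------------------------------------------------------------

def dose_grid(p: ModelParams, times, doses) -> pd.DataFrame:
    """Predicted-FT4 table over a (dose x time) grid, FT4 rounded to 1 dp."""
    rows = [
        {
            "dose_mg": float(d),
            "time_days": float(t),
            "ft4_pmol_per_l": round(float(ft4_solution(p, t, d)), 1),
        }
        for d in doses
        for t in times
    ]
    if not rows:
        raise DomainError("dose_grid needs non-empty dose and time grids")
    return pd.DataFrame(rows)


def target_grid(p: ModelParams, targets, times, dose_cap: float = 60.0) -> pd.DataFrame:
    """Optimal-dose table over a (target-FT4 x time) grid, dose to 1 dp.

    Infeasible cells carry NaN dose and the answer status.
    """
    rows = []
    for y in targets:
        for t in times:
            ans = solve_dose(p, t, y, dose_cap=dose_cap)
            rows.append(
                {
                    "target_ft4_pmol_per_l": float(y),
                    "time_days": float(t),
                    "dose_mg": np.nan if ans.value is None else round(ans.value, 1),
                    "status": ans.status,
                }
            )
    if not rows:
        raise DomainError("target_grid needs non-empty target and time grids")
    return pd.DataFrame(rows)


def trajectory(p: ModelParams, d: float, horizon: float, step: float = 1.0) -> pd.DataFrame:
    """FT4 time course under a constant dose, sampled every ``step`` days."""
    if step <= 0:
        raise DomainError("step must be positive")
    t = np.arange(0.0, horizon + step / 2, step)
    t = t[t <= horizon]
    if t.size == 0 or t[-1] < horizon:
        t = np.append(t, horizon)
    return pd.DataFrame({"day": t, "ft4_pmol_per_l": ft4_solution(p, t, d)})


def plot_trajectories(p: ModelParams, doses, horizon: float, step: float = 1.0, ax=None):
    """Minimal static render of FT4 curves for several doses (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for d in doses:
        df = trajectory(p, d, horizon, step)
        ax.plot(df["day"], df["ft4_pmol_per_l"], label=f"{d} mg")
    ax.set_xlabel("days since initial review")
    ax.set_ylabel("FT4 (pmol/l)")
    ax.legend()
    return ax
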
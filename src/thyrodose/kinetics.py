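"""Closed-form FT4 kinetics under Hill-type dose inhibition.

The free-thyroxine concentration ``y(t)`` (pmol/l) under a constant daily
anti-thyroid-drug dose ``d`` (mg) follows the Bernoulli ODE

    dy/dt = A * B(d) * y - C * y**2,        B(d) = ic50 / (ic50 + d),

whose closed-form solution, written in the overflow-safe *reciprocal* form, is

    1 / y(t) = C * (ic50 + d) / (A * ic50) + C1 * exp(-A * ic50 * t / (ic50 + d)).

The direct exponential form of the solution overflows IEEE doubles for
clinically reasonable inputs (exponents of several hundred occur for real
follow-up intervals), so every evaluation in this module routes through the
reciprocal identity; only non-positive exponents ever reach ``exp``.

For ``c1 < 0`` the trajectory is strictly decreasing and approaches the
steady state ``A * ic50 / (C * (ic50 + d))`` from above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ValidityError
from .params import DEFAULT_MARGIN, ModelParams

__all__ = [
    "inhibition_factor",
    "ft4_solution",
    "ft4_direct_form",
    "ft4_asymptote",
    "ft4_derivative",
    "ft4_initial",
    "check_validity",
    "taylor_ft4",
    "ValidityReport",
    "TaylorResult",
]


def inhibition_factor(d, ic50):
    """Fraction of the FT4 synthesis rate surviving a daily dose ``d``.

    Implements the Hill-type factor ``B(d) = ic50 / (ic50 + d)``: 1 at zero
    dose, 1/2 at ``d == ic50``, tending to 0 as the dose grows. Strictly
    decreasing in ``d``. Accepts scalars or arrays in ``d``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be nonnegative")
    if not ic50 > 0:
        raise DomainError(f"ic50 must be positive, got {ic50}")
    out = ic50 / (ic50 + d)
    return out.item() if out.ndim == 0 else out


def _reciprocal(p: ModelParams, t, d):
    """1/y on the reciprocal route; vectorized over t and d."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    ab = p.a_ic50 / (p.ic50 + d)  # A * B(d)
    return p.c / ab + p.c1 * np.exp(-ab * t)


def ft4_solution(p: ModelParams, t, d):
    """FT4 concentration ``y(t, d)`` in pmol/l.

    Evaluates the closed-form solution through the reciprocal identity
    (see module docstring), which is algebraically identical to the direct
    exponential form but never overflows. ``t`` and ``d`` may be scalars or
    broadcastable arrays.

    Raises
    ------
    ValidityError
        If the reciprocal is non-positive at any requested point, i.e. the
        positivity conditions on the parameters fail there.
    """
    t_arr = np.asarray(t, dtype=float)
    d_arr = np.asarray(d, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be nonnegative")
    if np.any(d_arr < 0):
        raise DomainError("dose must be nonnegative")
    inv = _reciprocal(p, t_arr, d_arr)
    bad = inv <= 0
    if np.any(bad):
        pts = np.argwhere(np.atleast_1d(bad)).ravel().tolist()
        raise ValidityError(
            "positivity condition violated: C*exp(A*B*t) + A*B*C1 <= 0 "
            f"at point index(es) {pts}",
            points=pts,
        )
    y = 1.0 / inv
    return y.item() if y.ndim == 0 else y


def ft4_direct_form(p: ModelParams, t, d):
    """The solution in its direct exponential form (reference only).

    Overflows for large ``A*B(d)*t``; kept for cross-validation against the
    reciprocal route at safe exponents.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    ab = p.a_ic50 / (p.ic50 + d)
    e = np.exp(ab * t)
    y = ab * e / (p.c * e + ab * p.c1)
    return y.item() if y.ndim == 0 else y


def ft4_initial(p: ModelParams) -> float:
    """FT4 at ``t = 0`` (any dose cancels only at t=0 for d=0): a/(c + a*c1)."""
    return ft4_solution(p, 0.0, 0.0)


def ft4_asymptote(p: ModelParams, d):
    """Steady-state FT4 under a sustained daily dose ``d``.

    The large-time limit ``A * ic50 / (C * (ic50 + d))``; strictly
    decreasing in ``d``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be nonnegative")
    out = p.a_ic50 / (p.c * (p.ic50 + d))
    return out.item() if out.ndim == 0 else out


def ft4_derivative(p: ModelParams, t, d):
    """Rate of change dy/dt (pmol/l/day) at ``(t, d)``.

    Computed as the ODE right-hand side ``A*B(d)*y - C*y**2`` evaluated at the
    closed-form ``y(t, d)``. Negative for all ``t >= 0`` exactly when
    ``c1 < 0``.
    """
    y = np.asarray(ft4_solution(p, t, d), dtype=float)
    b = inhibition_factor(d, p.ic50)
    out = p.a * b * y - p.c * y**2
    return out.item() if out.ndim == 0 else out


@dataclass
class ValidityReport:
    """Outcome of the positivity checks for a parameter set over points."""

    ok: bool
    c1_negative: bool
    point_ok: list = field(default_factory=list)  # per (t, d) point
    reasons: list = field(default_factory=list)


def check_validity(
    p_or_fields,
    points=(),
    margin: float = DEFAULT_MARGIN,
) -> ValidityReport:
    """Check the solution's positivity conditions at a set of ``(t, d)`` points.

    Accepts either a :class:`ModelParams` or a plain ``(a, c, ic50, c1)``
    tuple (so candidate parameters that would fail construction can still be
    diagnosed). The per-point condition ``C*exp(A*B*t) + A*B*C1 > 0`` is
    evaluated in log form, ``log C + A*B*t > log(A*B*(-C1))``, so large
    exponents never overflow.
    """
    if isinstance(p_or_fields, ModelParams):
        a, c, ic50, c1 = p_or_fields.a, p_or_fields.c, p_or_fields.ic50, p_or_fields.c1
    else:
        a, c, ic50, c1 = map(float, p_or_fields)

    reasons = []
    c1_neg = c1 <= -margin
    if not c1_neg:
        reasons.append(f"c1 must be negative (<= -{margin:g}), got {c1}")
    if a <= 0 or c <= 0 or ic50 <= 0:
        reasons.append("a, c and ic50 must all be positive")
        return ValidityReport(False, c1_neg, [False] * len(list(points)), reasons)

    point_ok = []
    for t, d in points:
        ab = a * ic50 / (ic50 + d)
        if c1 >= 0:
            ok = True  # positive c1 keeps the denominator positive (but c1_neg fails)
        else:
            ok = np.log(c) + ab * t - np.log(ab * (-c1)) >= margin
        point_ok.append(bool(ok))
        if not ok:
            reasons.append(
                f"positivity fails at (t={t}, d={d}): "
                f"log C + A*B*t = {np.log(c) + ab * t:.6g} <= "
                f"log(A*B*(-C1)) = {np.log(ab * (-c1)):.6g}"
            )
    return ValidityReport(c1_neg and all(point_ok), c1_neg, point_ok, reasons)


@dataclass
class TaylorResult:
    """Second-order polynomial FT4 shortcut: value or a divergence flag."""

    value: float | None
    diverged: bool
    z: float  # the reciprocal quadratic; y = 1/z when z > 0


def taylor_ft4(p: ModelParams, t, d) -> TaylorResult:
    """Second-order Taylor shortcut for FT4, for by-hand estimation.

    Expands ``exp(-A*B*t)`` in the reciprocal identity to second order:

        z = c1 + c*(ic50+d)/(a*ic50) - a*c1*B*t + (1/2)*c1*(a*B)**2 * t**2

    and returns ``y = 1/z`` when ``z > 0``. For ``A*B*t`` beyond roughly 1
    the truncation can drive ``z`` non-positive; that is reported as a
    *divergence flag*, not an error. At ``t = 0`` the shortcut equals the
    exact solution.
    """
    t = float(t)
    d = float(d)
    b = inhibition_factor(d, p.ic50)
    ab = p.a * b
    z = p.c1 + p.c * (p.ic50 + d) / p.a_ic50 - p.c1 * ab * t + 0.5 * p.c1 * ab**2 * t**2
    if z <= 0:
        return TaylorResult(value=None, diverged=True, z=z)
    return TaylorResult(value=1.0 / z, diverged=False, z=z)
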
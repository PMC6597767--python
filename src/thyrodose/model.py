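"""Per-patient model fitting by constrained nonlinear least squares.

Given a patient's visit series ``(d_{i-1}, t_i, y_i)``, the four kinetic
constants are chosen to minimize the mean squared deviation between the
closed-form FT4 prediction at each follow-up visit and the measured value,

    minimize   (1/(m-1)) * sum_{i=2..m} (f(t_i, d_{i-1}) - y_i)^2

subject to the initial condition ``A - y_1 (C + A C_1) = 0``, positivity of
the solution at every data point, sign constraints on the parameters, and a
clinical upper bound ``IC50 <= 150`` mg.

The initial-condition equality is solved exactly for the integration
constant, ``C1 = 1/y_1 - C/A``, which removes one decision variable; the
remaining three are optimized in log space (so positivity is structural)
with a multistart SQP solver. A useful consequence of the exact elimination:
every per-visit positivity inequality then holds automatically, because
``1/y(t,d) >= C/A + C1 = 1/y_1 > 0`` for ``C1 < 0`` — the inequalities are
nevertheless re-checked post hoc on every returned fit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import InsufficientDataError
from .kinetics import check_validity, ft4_solution
from .params import DEFAULT_MARGIN, IC50_MAX, ModelParams
from .series import PatientSeries

__all__ = [
    "FitConfig",
    "FT4Model",
    "fit_patient",
    "predicted_series",
    "objective_value",
    "constraint_values",
    "tolerance_test",
]

#: statistics accepted for the tolerance test
_TOL_STATS = ("mean_abs", "max_abs", "rmse")


@dataclass(frozen=True)
class FitConfig:
    """Solver and acceptance settings for per-patient fitting.

    Attributes
    ----------
    tolerance : float
        Acceptance tolerance on the deviation statistic, pmol/l. A fit is
        *accepted* when the statistic over follow-up visits is <= tolerance
        (inclusive). Default 4.5.
    tolerance_statistic : str
        Which deviation statistic the tolerance applies to:
        ``mean_abs`` (default), ``max_abs`` or ``rmse``.
    ic50_max : float
        Clinical upper bound on ic50, mg.
    strict_margin : float
        Margin by which strict sign conditions are enforced.
    multistart_count : int
        Number of random starting points (two data-driven heuristic starts
        are always added).
    seed : int
        Seed for the deterministic multistart stream.
    ftol, maxiter : solver step tolerance and iteration cap.
    constraint_tol : float
        Post-hoc feasibility tolerance for the returned candidate.
    min_visits : int
        Minimum series length accepted by :func:`fit_patient`.
    """

    tolerance: float = 4.5
    tolerance_statistic: str = "mean_abs"
    ic50_max: float = IC50_MAX
    strict_margin: float = DEFAULT_MARGIN
    multistart_count: int = 16
    seed: int = 0
    ftol: float = 1e-12
    maxiter: int = 300
    constraint_tol: float = 1e-6
    min_visits: int = 3

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.ic50_max <= 0:
            raise ValueError("ic50_max must be positive")
        if self.multistart_count < 1:
            raise ValueError("multistart_count must be >= 1")
        if self.tolerance_statistic not in _TOL_STATS:
            raise ValueError(f"tolerance_statistic must be one of {_TOL_STATS}")


# ---------------------------------------------------------------------------
# spec-level free functions (also used by FT4Model methods)
# ---------------------------------------------------------------------------

def predicted_series(p: ModelParams, s: PatientSeries) -> np.ndarray:
    """Model FT4 at every visit of ``s`` under parameters ``p``.

    Element ``i`` plugs the cumulative time ``t_i`` and the dose prescribed
    at the preceding review ``d_{i-1}`` into the single-dose closed form;
    element 1 is the modelled initial value ``a / (c + a*c1)``. Dose changes
    between visits are *not* integrated piecewise — the latest dose and the
    total elapsed time enter the one-dose solution directly, reproducing the
    estimation convention this model family uses.
    """
    return np.asarray(ft4_solution(p, s.times, s.doses_prev))


def objective_value(p: ModelParams, s: PatientSeries) -> float:
    """Mean squared deviation over follow-up visits 2..m, (pmol/l)^2."""
    if s.m < 2:
        raise InsufficientDataError(
            f"patient {s.patient_id}: need >= 2 visits for the objective, got {s.m}"
        )
    pred = predicted_series(p, s)
    res = pred[1:] - s.ft4[1:]
    return float(np.mean(res**2))


def constraint_values(p: ModelParams, s: PatientSeries) -> dict:
    """All constraint diagnostics of the optimization model at ``p``.

    Returns the initial-condition equality residual ``A - y1 (C + A C1)``,
    the per-visit log-form positivity values
    ``(ic50+d)ln(A ic50 (-C1)) - t A ic50 - (ic50+d)ln(C (ic50+d))``
    (feasible when < 0), and the slacks of the sign/bound constraints.
    """
    y1 = s.initial_ft4
    eq = p.a - y1 * (p.c + p.a * p.c1)
    d = s.doses_prev
    t = s.times
    w = p.ic50 + d
    ineq = w * np.log(p.a_ic50 * (-p.c1)) - t * p.a_ic50 - w * np.log(p.c * w)
    return {
        "equality_residual": float(eq),
        "inequality_values": ineq,  # feasible: strictly negative
        "bound_slacks": {
            "a": p.a,
            "c": p.c,
            "ic50_lower": p.ic50,
            "ic50_upper": IC50_MAX - p.ic50,
            "neg_c1": -p.c1,
        },
    }


def _deviation_stat(pred: np.ndarray, actual: np.ndarray, statistic: str) -> float:
    dev = np.abs(pred[1:] - actual[1:])
    if statistic == "mean_abs":
        return float(np.mean(dev))
    if statistic == "max_abs":
        return float(np.max(dev))
    return float(np.sqrt(np.mean(dev**2)))


def tolerance_test(fit_result, cfg: FitConfig | None = None) -> bool:
    """Acceptance test: deviation statistic over follow-up visits <= tolerance.

    Inclusive at the boundary. ``fit_result`` is an :class:`FT4Results`; the
    config defaults to the one the fit was run with.
    """
    cfg = cfg or fit_result.config
    if not fit_result.converged:
        return False
    stat = _deviation_stat(
        fit_result.predicted, fit_result.actual, cfg.tolerance_statistic
    )
    return stat <= cfg.tolerance


# ---------------------------------------------------------------------------
# the Model object
# ---------------------------------------------------------------------------

class FT4Model:
    """FT4 dose-response model for one patient's visit series.

    Statsmodels-style entry point: construct from the data, then call
    :meth:`fit` to obtain an :class:`~thyrodose.results.FT4Results`.

    Parameters
    ----------
    series : PatientSeries
        The ordered visit series (see :mod:`thyrodose.series`).

    Examples
    --------
    >>> from thyrodose import FT4Model, PatientSeries
    >>> s = PatientSeries.from_arrays("16", [0, 15, 17.5], [0, 90, 78],
    ...                              [14, 13, 10])
    >>> res = FT4Model(s).fit()
    >>> res.accepted
    True
    """

    def __init__(self, series: PatientSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, patient_id: str | None = None) -> "FT4Model":
        """Build from a visit-table frame (one patient; columns as in io)."""
        ids = df["patient_id"].unique() if "patient_id" in df else [patient_id or "?"]
        if patient_id is None:
            if len(ids) != 1:
                raise ValueError(
                    f"frame contains {len(ids)} patients; pass patient_id"
                )
            patient_id = str(ids[0])
        else:
            df = df[df["patient_id"].astype(str) == str(patient_id)]
        return cls(PatientSeries.from_dataframe(patient_id, df))

    # -- evaluation at given parameters -------------------------------------

    def predict(self, params: ModelParams) -> np.ndarray:
        return predicted_series(params, self.series)

    def objective(self, params: ModelParams) -> float:
        return objective_value(params, self.series)

    def constraints(self, params: ModelParams) -> dict:
        return constraint_values(params, self.series)

    # -- fitting -------------------------------------------------------------

    def _pack_objective(self, theta: np.ndarray) -> float:
        """Objective over theta = (log a, log c, log ic50); c1 eliminated."""
        a, c, ic50 = np.exp(theta)
        s = self.series
        y1 = s.initial_ft4
        c1 = 1.0 / y1 - c / a
        ab = a * ic50 / (ic50 + s.doses_prev[1:])
        inv = c / ab + c1 * np.exp(-ab * s.times[1:])
        # inv >= 1/y1 > 0 whenever c1 < 0; guard anyway for boundary starts
        if np.any(inv <= 0):
            return 1e12
        res = 1.0 / inv - s.ft4[1:]
        return float(np.mean(res**2))

    def _starts(self, cfg: FitConfig) -> list[np.ndarray]:
        """Deterministic multistart points in log space, c1 < 0 guaranteed."""
        s = self.series
        y1 = s.initial_ft4
        rng = np.random.default_rng(cfg.seed)
        starts: list[np.ndarray] = []
        # data-driven heuristics: untreated steady state just below the
        # smallest observed FT4; slow and fast equilibration regimes
        steady = 0.9 * float(np.min(s.ft4))
        for a0, ic0 in ((0.05, 50.0), (4.0, 60.0)):
            starts.append(np.log([a0, a0 / steady, ic0]))
        tries = 0
        while len(starts) < cfg.multistart_count + 2 and tries < 100 * cfg.multistart_count:
            tries += 1
            a0 = 10.0 ** rng.uniform(-3, 2)
            c0 = 10.0 ** rng.uniform(-4, 1)
            ic0 = rng.uniform(1.0, cfg.ic50_max)
            if c0 / a0 > 1.0 / y1 + cfg.strict_margin:  # pinned c1 negative
                starts.append(np.log([a0, c0, ic0]))
        return starts

    def fit(self, config: FitConfig | None = None, **overrides):
        """Estimate the four constants by multistart constrained SQP.

        Returns
        -------
        FT4Results
            Never raises on non-convergence: ``converged`` / ``accepted``
            flags carry the outcome. Raises :class:`InsufficientDataError`
            when the series is shorter than ``config.min_visits``.
        """
        from .results import FT4Results  # local import to avoid a cycle

        cfg = config or FitConfig()
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        s = self.series
        if s.m < cfg.min_visits:
            raise InsufficientDataError(
                f"patient {s.patient_id}: {s.m} visits < min_visits={cfg.min_visits}"
            )
        y1 = s.initial_ft4

        bounds = [
            (np.log(1e-6), np.log(1e4)),
            (np.log(1e-7), np.log(1e3)),
            (np.log(1e-3), np.log(cfg.ic50_max)),
        ]
        # c1 <= -margin  <=>  log c - log a >= log(1/y1 + margin): linear in theta
        rhs = np.log(1.0 / y1 + cfg.strict_margin)
        cons = [{"type": "ineq", "fun": lambda th: th[1] - th[0] - rhs}]

        candidates = []
        n_converged = 0
        for theta0 in self._starts(cfg):
            try:
                opt = minimize(
                    self._pack_objective,
                    theta0,
                    method="SLSQP",
                    bounds=bounds,
                    constraints=cons,
                    options={"ftol": cfg.ftol, "maxiter": cfg.maxiter},
                )
            except (ValueError, FloatingPointError):  # pathological start
                continue
            if not (opt.success and np.isfinite(opt.fun)):
                continue
            a, c, ic50 = np.exp(opt.x)
            c1 = 1.0 / y1 - c / a
            if not c1 <= -cfg.strict_margin:
                continue
            rep = check_validity((a, c, ic50, c1),
                                 zip(s.times, s.doses_prev),
                                 margin=-cfg.constraint_tol)
            if not rep.ok:
                continue
            n_converged += 1
            candidates.append((float(opt.fun), a, c, ic50, c1))

        warnings = []
        if np.count_nonzero(np.unique(s.doses_prev[s.doses_prev > 0])) < 2:
            warnings.append(
                "fewer than 2 distinct nonzero doses: a and ic50 are weakly "
                "identified (only a*ic50/(ic50+d) is constrained per dose level)"
            )
        if s.m - 1 < 3:
            warnings.append(
                f"under-determined: {s.m - 1} follow-up residual(s) for 3 free "
                "parameters after the initial-condition elimination"
            )

        if not candidates:
            return FT4Results(
                model=self, params=None, objective=np.inf, converged=False,
                accepted=False, n_starts_converged=0, config=cfg,
                warnings=warnings,
            )

        candidates.sort(key=lambda c: c[0])
        obj, a, c, ic50, c1 = candidates[0]
        params = ModelParams(
            a=a, c=c, ic50=ic50, c1=c1,
            meta={"patient_id": s.patient_id, "objective": obj},
        )
        result = FT4Results(
            model=self, params=params, objective=obj, converged=True,
            accepted=False, n_starts_converged=n_converged, config=cfg,
            warnings=warnings,
        )
        result.accepted = tolerance_test(result, cfg)
        return result


def fit_patient(series: PatientSeries, config: FitConfig | None = None):
    """Functional wrapper: ``FT4Model(series).fit(config)``."""
    return FT4Model(series).fit(config)
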
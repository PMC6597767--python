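"""Fit results: estimates, diagnostics, summary and what-if entry points."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams


@dataclass
class FT4Results:
    """Outcome of :meth:`thyrodose.model.FT4Model.fit`.

    Attributes
    ----------
    model : FT4Model
        The model (and hence the series) the fit was run on.
    params : ModelParams or None
        Estimated constants; ``None`` when no start converged.
    objective : float
        Mean squared deviation over follow-up visits, (pmol/l)^2.
    converged, accepted : bool
        Solver success and the clinical tolerance test (``accepted``
        implies ``converged``).
    n_starts_converged : int
        How many multistart candidates passed the feasibility re-check.
    warnings : list of str
        Identifiability and data-sufficiency notes.
    """

    model: object
    params: ModelParams | None
    objective: float
    converged: bool
    accepted: bool
    n_starts_converged: int
    config: object
    warnings: list = field(default_factory=list)

    # -- per-visit diagnostics ----------------------------------------------

    @property
    def actual(self) -> np.ndarray:
        return self.model.series.ft4

    @property
    def predicted(self) -> np.ndarray:
        if self.params is None:
            return np.full(self.model.series.m, np.nan)
        return self.model.predict(self.params)

    @property
    def deviations(self) -> np.ndarray:
        """Follow-up-visit deviations, predicted - actual (visit 1 excluded)."""
        return self.predicted[1:] - self.actual[1:]

    @property
    def mean_abs_deviation(self) -> float:
        return float(np.mean(np.abs(self.deviations)))

    def per_visit(self) -> pd.DataFrame:
        """Per-visit table of actual vs predicted FT4 and the deviation."""
        s = self.model.series
        return pd.DataFrame(
            {
                "visit": [r.visit_index for r in s.visits],
                "dose_prev_mg": s.doses_prev,
                "interval_days": s.intervals,
                "actual_ft4": self.actual,
                "predicted_ft4": self.predicted,
                "deviation": self.predicted - self.actual,
            }
        )

    # -- what-if entry points (delegate to the whatif module) ----------------

    def predict_ft4(self, t: float, d: float):
        from . import whatif

        return whatif.predict_ft4(self.params, t, d)

    def solve_dose(self, t: float, y: float, dose_cap: float = 60.0):
        from . import whatif

        return whatif.solve_dose(self.params, t, y, dose_cap=dose_cap)

    def solve_time(self, d: float, y: float, time_cap: float = 730.0):
        from . import whatif

        return whatif.solve_time(self.params, d, y, time_cap=time_cap)

    def trajectory(self, d: float, horizon: float, step: float = 1.0):
        from . import whatif

        return whatif.trajectory(self.params, d, horizon, step)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text fit report in the style of statistical model summaries."""
        s = self.model.series
        lines = [
            "FT4 dose-response model fit",
            "=" * 46,
            f"patient id:            {s.patient_id}",
            f"visits (m):            {s.m}",
            f"converged:             {self.converged}"
            f"   (starts converged: {self.n_starts_converged})",
            f"objective (MSD):       {self.objective:.6g} (pmol/l)^2",
        ]
        if self.params is not None:
            p = self.params
            lines += [
                "-" * 46,
                f"a      (synthesis, 1/day):        {p.a:.6g}",
                f"c      (decay, l/pmol/day):       {p.c:.6g}",
                f"ic50   (half-inhibition, mg):     {p.ic50:.6g}",
                f"c1     (integration const):       {p.c1:.6g}",
                f"a*ic50:                           {p.a_ic50:.6g}",
                f"a*ic50*c1:                        {p.a_ic50_c1:.6g}",
                "-" * 46,
                f"mean |deviation| (pmol/l):        {self.mean_abs_deviation:.3f}",
                f"accepted (tol {self.config.tolerance} pmol/l):"
                f"           {self.accepted}",
            ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.model.series.patient_id,
            "params": None if self.params is None else self.params.to_dict(),
            "objective": self.objective,
            "converged": self.converged,
            "accepted": self.accepted,
            "n_starts_converged": self.n_starts_converged,
            "warnings": list(self.warnings),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text
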
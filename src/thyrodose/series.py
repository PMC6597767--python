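"""Patient thyroid-function-test series.

A patient's record is an ordered sequence of review visits. Visit ``i``
carries the daily dose prescribed at the *preceding* review (taken during the
interval that ends at this visit), the interval length in days, and the FT4
measured at this visit. Visit 1 is the initial review: zero dose, zero
interval. Cumulative time since the initial review is derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass(frozen=True)
class VisitRecord:
    """One thyroid-function-test observation.

    Attributes
    ----------
    visit_index : int
        1-based ordinal of the review.
    dose_prev : float
        Daily ATD dose (mg) prescribed at the preceding review; 0 at visit 1.
    interval_days : float
        Days since the previous visit; 0 at visit 1.
    cumulative_days : float
        Days since the initial review (prefix sum of intervals).
    ft4 : float
        Measured free thyroxine, pmol/l.
    """

    visit_index: int
    dose_prev: float
    interval_days: float
    cumulative_days: float
    ft4: float


@dataclass(frozen=True)
class PatientSeries:
    """An ordered, validated sequence of :class:`VisitRecord` for one patient."""

    patient_id: str
    visits: tuple[VisitRecord, ...]

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        v = self.visits
        if not v:
            raise ValidationError(f"patient {self.patient_id}: empty series")
        if [r.visit_index for r in v] != list(range(1, len(v) + 1)):
            raise ValidationError(
                f"patient {self.patient_id}: visit indices must be contiguous from 1"
            )
        first = v[0]
        if first.dose_prev != 0 or first.interval_days != 0 or first.cumulative_days != 0:
            raise ValidationError(
                f"patient {self.patient_id}: visit 1 must have zero dose_prev, "
                "interval and cumulative time"
            )
        cum = 0.0
        for r in v:
            if r.ft4 <= 0:
                raise ValidationError(
                    f"patient {self.patient_id} visit {r.visit_index}: ft4 must be positive"
                )
            if r.dose_prev < 0:
                raise ValidationError(
                    f"patient {self.patient_id} visit {r.visit_index}: negative dose"
                )
            if r.visit_index >= 2 and r.interval_days <= 0:
                raise ValidationError(
                    f"patient {self.patient_id} visit {r.visit_index}: "
                    "interval_days must be positive after visit 1"
                )
            cum += r.interval_days
            if abs(r.cumulative_days - cum) > 1e-9:
                raise ValidationError(
                    f"patient {self.patient_id} visit {r.visit_index}: cumulative_days "
                    f"{r.cumulative_days} != prefix sum of intervals {cum}"
                )

    # -- construction --------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        patient_id: str,
        doses_prev: Sequence[float],
        intervals: Sequence[float],
        ft4: Sequence[float],
    ) -> "PatientSeries":
        """Build from parallel per-visit arrays; cumulative time is derived."""
        if not (len(doses_prev) == len(intervals) == len(ft4)):
            raise ValidationError("doses_prev, intervals and ft4 must have equal length")
        cum = np.cumsum(np.asarray(intervals, dtype=float))
        visits = tuple(
            VisitRecord(i + 1, float(doses_prev[i]), float(intervals[i]),
                        float(cum[i]), float(ft4[i]))
            for i in range(len(ft4))
        )
        return cls(patient_id=str(patient_id), visits=visits)

    @classmethod
    def from_dataframe(cls, patient_id: str, df: pd.DataFrame) -> "PatientSeries":
        """Build from a per-patient frame with the visit-table columns."""
        df = df.sort_values("visit")
        return cls.from_arrays(
            patient_id,
            df["dose_prev_mg"].to_numpy(float),
            df["interval_days"].to_numpy(float),
            df["ft4_pmol_per_l"].to_numpy(float),
        )

    # -- views ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.visits)

    def __iter__(self) -> Iterator[VisitRecord]:
        return iter(self.visits)

    @property
    def m(self) -> int:
        """Number of visits (the series length)."""
        return len(self.visits)

    @property
    def doses_prev(self) -> np.ndarray:
        return np.array([r.dose_prev for r in self.visits])

    @property
    def times(self) -> np.ndarray:
        """Cumulative days since the initial review, one per visit."""
        return np.array([r.cumulative_days for r in self.visits])

    @property
    def intervals(self) -> np.ndarray:
        return np.array([r.interval_days for r in self.visits])

    @property
    def ft4(self) -> np.ndarray:
        return np.array([r.ft4 for r in self.visits])

    @property
    def initial_ft4(self) -> float:
        return self.visits[0].ft4

    def truncate(self, n: int) -> "PatientSeries":
        """First ``min(n, m)`` visits as a new series (cumulative time unchanged)."""
        return PatientSeries(self.patient_id, self.visits[: max(1, n)])

    def to_dataframe(self) -> pd.DataFrame:
        """Visit-table representation (cumulative time derived, not stored)."""
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "visit": [r.visit_index for r in self.visits],
                "dose_prev_mg": self.doses_prev,
                "interval_days": self.intervals,
                "ft4_pmol_per_l": self.ft4,
            }
        )
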
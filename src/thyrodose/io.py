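"""Visit-table, parameter-document and config readers/writers.

The visit table is a UTF-8 CSV (or spreadsheet) with header columns

    patient_id, visit, dose_prev_mg, interval_days, ft4_pmol_per_l

one row per review, grouped by patient and sorted by visit. Cumulative time
is always derived from the intervals, never stored. Parameter documents are
flat JSON (see :class:`thyrodose.params.ModelParams`); solver settings load
from YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ValidationError
from .model import FitConfig
from .series import PatientSeries

logger = logging.getLogger("thyrodose")

REQUIRED_COLUMNS = (
    "patient_id",
    "visit",
    "dose_prev_mg",
    "interval_days",
    "ft4_pmol_per_l",
)

_SPREADSHEET_SUFFIXES = {".xlsx", ".xlsm", ".xls", ".ods"}


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in _SPREADSHEET_SUFFIXES:
        return pd.read_excel(path)
    return pd.read_csv(path, float_precision="round_trip")


def read_visits(path) -> list[PatientSeries]:
    """Read a visit table into validated per-patient series.

    Raises :class:`ValidationError` naming the file, patient and rule on any
    malformed row or violated series invariant. An empty table yields an
    empty list with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    try:
        df = _read_table(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty visit table", path)
        return []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty visit table", path)
        return []
    for col in ("visit", "dose_prev_mg", "interval_days", "ft4_pmol_per_l"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(df.index[df[col].isna() | bad][0]) + 2  # header is line 1
            raise ValidationError(f"{path} line {row}: malformed value in {col!r}")
        df[col] = pd.to_numeric(df[col])

    out = []
    for pid, group in df.groupby("patient_id", sort=False):
        try:
            out.append(PatientSeries.from_dataframe(str(pid), group))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return out


def write_visits(dataset: list[PatientSeries], path) -> None:
    """Write per-patient series back to the visit-table CSV dialect."""
    frames = [s.to_dataframe() for s in dataset]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=REQUIRED_COLUMNS)
    )
    df.to_csv(path, index=False)


def load_config(path=None, **overrides) -> FitConfig:
    """Load a :class:`FitConfig` from a YAML file, with keyword overrides."""
    settings: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            settings = yaml.safe_load(fh) or {}
        unknown = set(settings) - {f.name for f in dataclasses.fields(FitConfig)}
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    settings.update(overrides)
    return FitConfig(**settings)
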
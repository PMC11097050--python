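"""Reading, validating and normalizing the five longitudinal EHR tables.

The pipeline consumes five delimited tables per patient population:

* ``registry``       -- patient_id, birth_year, diagnosis_date, practice_id
* ``prescriptions``  -- patient_id, date, atc_code [, description]
* ``consultations``  -- patient_id, date, ctg_code
* ``measurements``   -- patient_id, date, nhg_code [, description], value
* ``comorbidities``  -- patient_id, icpc_code [, description], start_date,
                        end_date, duration_class

On load, clinical codes gain a human-readable description from the bundled
code dictionaries, dates are normalized to a single calendar type, rows with
unparseable dates are dropped (and counted), and exact duplicate rows are
de-duplicated (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .codes import CodeMap, default_codemaps

TABLE_NAMES = ("registry", "prescriptions", "consultations", "measurements", "comorbidities")

DURATION_CLASSES = ("4 weeks", "8 weeks", "16 weeks", "long-lasting", "chronic")
_TEMPORARY_CLASSES = frozenset({"4 weeks", "8 weeks", "16 weeks"})
_CHRONIC_CLASSES = frozenset({"long-lasting", "chronic"})

_REQUIRED_COLUMNS = {
    "registry": ("patient_id", "birth_year", "diagnosis_date", "practice_id"),
    "prescriptions": ("patient_id", "date", "atc_code"),
    "consultations": ("patient_id", "date", "ctg_code"),
    "measurements": ("patient_id", "date", "nhg_code", "value"),
    "comorbidities": ("patient_id", "icpc_code", "start_date", "end_date", "duration_class"),
}

_DATE_COLUMNS = {
    "registry": ("diagnosis_date",),
    "prescriptions": ("date",),
    "consultations": ("date",),
    "measurements": ("date",),
    "comorbidities": ("start_date",),  # end_date may legitimately be open
}


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class ReferentialIntegrityError(ValueError):
    """An event references a patient absent from the registry."""


@dataclass
class EventTables:
    """The five ingested longitudinal tables, keyed by patient id."""

    registry: pd.DataFrame
    prescriptions: pd.DataFrame
    consultations: pd.DataFrame
    measurements: pd.DataFrame
    comorbidities: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        for name in TABLE_NAMES:
            yield name, getattr(self, name)

    def validate(self) -> "EventTables":
        for name, frame in self:
            missing = [c for c in _REQUIRED_COLUMNS[name] if c not in frame.columns]
            if missing:
                raise SchemaError(f"table {name!r} is missing columns {missing}")
        known = set(self.registry["patient_id"])
        for name, frame in self:
            if name == "registry":
                continue
            orphans = set(frame["patient_id"]) - known
            if orphans:
                raise ReferentialIntegrityError(
                    f"table {name!r} references unknown patients: {sorted(orphans)[:5]}"
                )
        bad = set(self.comorbidities["duration_class"].dropna()) - set(DURATION_CLASSES)
        if bad:
            raise SchemaError(f"unknown comorbidity duration classes: {sorted(bad)}")
        return self


def classify_comorbidity_duration(duration_class: str) -> str:
    """Collapse the five episode duration classes into temporary vs chronic.

    The 4/8/16-week episode classes are temporary; long-lasting and chronic
    episodes are both treated as chronic.
    """
    if duration_class in _TEMPORARY_CLASSES:
        return "temporary"
    if duration_class in _CHRONIC_CLASSES:
        return "chronic"
    raise ValueError(f"unknown duration class {duration_class!r}")


def _normalize_dates(frame: pd.DataFrame, columns: tuple[str, ...]) -> tuple[pd.DataFrame, int]:
    dropped = 0
    for col in columns:
        parsed = pd.to_datetime(frame[col], errors="coerce", format="mixed")
        bad = parsed.isna() & frame[col].notna()
        dropped += int(bad.sum())
        frame = frame.loc[~bad].copy()
        frame[col] = parsed.loc[~bad]
    return frame, dropped


def _attach_descriptions(
    tables: dict[str, pd.DataFrame], codemaps: Mapping[str, CodeMap]
) -> list[str]:
    unmapped: list[str] = []
    spec = [
        ("prescriptions", "atc_code", "ATC"),
        ("measurements", "nhg_code", "NHG"),
        ("comorbidities", "icpc_code", "ICPC"),
    ]
    for name, code_col, system in spec:
        frame = tables[name]
        cmap = codemaps[system]
        if len(frame):
            frame["description"] = frame[code_col].map(cmap.describe)
            unmapped.extend(
                f"{system}:{c}" for c in sorted(set(frame[code_col].astype(str))) if c not in cmap
            )
        elif "description" not in frame.columns:
            frame["description"] = pd.Series(dtype=str)
    return unmapped


def load_tables(
    paths: Mapping[str, Path | str] | Path | str,
    codemaps: Mapping[str, CodeMap] | None = None,
) -> EventTables:
    """Read the five CSV tables, normalize dates, and map codes to descriptions.

    ``paths`` is either a directory containing ``<table>.csv`` files or a
    mapping from table name to file path.  Rows with unparseable dates are
    dropped and counted in ``EventTables.meta['dropped_bad_dates']``; exact
    duplicate rows are removed and counted in ``meta['deduplicated']``;
    unmapped codes are listed in ``meta['unmapped_codes']``.
    """
    if codemaps is None:
        codemaps = default_codemaps()
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / f"{name}.csv" for name in TABLE_NAMES}

    tables: dict[str, pd.DataFrame] = {}
    meta: dict = {"dropped_bad_dates": {}, "deduplicated": {}}
    for name in TABLE_NAMES:
        frame = pd.read_csv(paths[name], dtype={"patient_id": str})
        missing = [c for c in _REQUIRED_COLUMNS[name] if c not in frame.columns]
        if missing:
            raise SchemaError(f"table {name!r} is missing columns {missing}")
        n0 = len(frame)
        frame = frame.drop_duplicates(ignore_index=True)
        meta["deduplicated"][name] = n0 - len(frame)
        frame, dropped = _normalize_dates(frame, _DATE_COLUMNS[name])
        if name == "comorbidities":
            frame["end_date"] = pd.to_datetime(frame["end_date"], errors="coerce", format="mixed")
        meta["dropped_bad_dates"][name] = dropped
        tables[name] = frame.reset_index(drop=True)

    meta["unmapped_codes"] = _attach_descriptions(tables, codemaps)
    out = EventTables(**tables, meta=meta)
    return out.validate()


def write_tables(tables: EventTables, out_dir: Path | str) -> dict[str, Path]:
    """Write the five tables as UTF-8 CSV with ISO-8601 dates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in tables:
        frame = frame.copy()
        for col in frame.columns:
            if pd.api.types.is_datetime64_any_dtype(frame[col]):
                frame[col] = frame[col].dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path
    return written
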
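"""Extraction of treatment decision points (DPs) from longitudinal records.

A decision point is a dated disease-uncontrolled test (HbA1c > 7 % or fasting
glucose > 7 mmol/L) after the diagnosis date that has at least one follow-up
test of the same variable 90-365 days later.  Each DP carries:

* the index test (date and value) and the earliest qualifying follow-up test,
  whose value determines the outcome label (controlled iff value <= threshold);
* the active treatment regimen in force at the index date and the new
  regimen taken in the observation period (``"no change"`` if identical);
* guideline flags (age > 70 y, disease duration > 10 y, BMI < 25 kg/m^2) and
  mobility / mental impairment flags derived from comorbidity episodes;
* a baseline snapshot (most recent value of each clinical measurement before
  the index date) and event counts from diagnosis to index.

Conventions the source data leave open, fixed here: multiple same-day tests
are collapsed to their maximum for index/outcome decisions and to their mean
for baseline features; a medication is active at a date if its most recent
prescription falls within ``active_window_days`` (default 180) before it;
lifestyle advice, having no end date, persists once given; a value exactly at
the threshold counts as controlled; a missing BMI yields a false BMI flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import (
    HEALTHY_LIFESTYLE,
    LIFESTYLE_ADVICE_DESCRIPTIONS,
    MENTAL_ICPC,
    MOBILITY_ICPC,
    MOBILITY_NHG,
    NUMERIC_MEASUREMENTS,
    T2DM_MEDICATIONS,
)
from .ingest import EventTables, classify_comorbidity_duration
from .labels import NO_CHANGE, render_label, transition_label

_TEMP_WEEKS = {"4 weeks": 4, "8 weeks": 8, "16 weeks": 16}
_DAY = np.timedelta64(1, "D")


@dataclass(frozen=True)
class OutcomeSpec:
    """Target outcome variable, control threshold and follow-up window."""

    variable: str  # "HbA1c" or "fasting glucose"
    threshold: float
    window_min_days: int = 90
    window_max_days: int = 365

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not self.window_min_days < self.window_max_days:
            raise ValueError("window_min_days must be < window_max_days")


HBA1C = OutcomeSpec(variable="HbA1c", threshold=7.0)
FASTING_GLUCOSE = OutcomeSpec(variable="fasting glucose", threshold=7.0)
OUTCOME_SPECS = {"hba1c": HBA1C, "glucose": FASTING_GLUCOSE}

FLAG_NAMES = (
    "age_above_70y",
    "disease_duration_above_10y",
    "bmi_below_25",
    "mobility_impaired",
    "mental_impaired",
)


@dataclass(frozen=True)
class GuidelineFlags:
    age_above_70y: bool
    disease_duration_above_10y: bool
    bmi_below_25: bool
    mobility_impaired: bool
    mental_impaired: bool

    def true_flags(self) -> list[str]:
        return [name for name in FLAG_NAMES if getattr(self, name)]


@dataclass
class DecisionPoint:
    patient_id: str
    index_date: pd.Timestamp
    index_value: float
    outcome_variable: str
    active_treatment: str
    new_treatment: str  # regimen label, or "no change"
    transition: str  # "NEW_new+OLD_stop" or "No change"
    outcome_label: str  # "controlled" | "uncontrolled"
    outcome_date: pd.Timestamp
    guideline_flags: GuidelineFlags
    has_chronic_comorbidity: bool
    baseline: dict[str, float] = field(default_factory=dict)
    history_counts: tuple[int, int, int, int] = (0, 0, 0, 0)


class _PatientArrays:
    """One patient's events as sorted numpy arrays (the extraction hot path)."""

    def __init__(
        self,
        registry_row: pd.Series,
        meas: pd.DataFrame | None,
        rx: pd.DataFrame | None,
        consult: pd.DataFrame | None,
        comorb: pd.DataFrame | None,
    ):
        self.birth_year = int(registry_row["birth_year"])
        self.diagnosis = np.datetime64(registry_row["diagnosis_date"], "ns")

        if meas is not None and len(meas):
            order = np.argsort(meas["date"].to_numpy(), kind="stable")
            self.m_dates = meas["date"].to_numpy("datetime64[ns]")[order]
            self.m_desc = meas["description"].to_numpy(object)[order]
            self.m_values = pd.to_numeric(meas["value"], errors="coerce").to_numpy(float)[order]
            self.m_nhg = meas["nhg_code"].astype(str).to_numpy(object)[order]
        else:
            self.m_dates = np.empty(0, "datetime64[ns]")
            self.m_desc = np.empty(0, object)
            self.m_values = np.empty(0, float)
            self.m_nhg = np.empty(0, object)
        self.advice_dates = np.sort(
            self.m_dates[np.isin(self.m_desc, LIFESTYLE_ADVICE_DESCRIPTIONS)]
        )
        self.amputation_dates = np.sort(self.m_dates[np.isin(self.m_nhg, MOBILITY_NHG)])
        self._per_desc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for desc in NUMERIC_MEASUREMENTS:
            sel = self.m_desc == desc
            self._per_desc[desc] = (self.m_dates[sel], self.m_values[sel])

        if rx is not None and len(rx):
            order = np.argsort(rx["date"].to_numpy(), kind="stable")
            dates = rx["date"].to_numpy("datetime64[ns]")[order]
            desc = rx["description"].to_numpy(object)[order]
            keep = np.fromiter((d in T2DM_MEDICATIONS for d in desc), bool, len(desc))
            self.rx_all_dates = dates
            self.rx_dates = dates[keep]
            self.rx_desc = desc[keep]
        else:
            self.rx_all_dates = np.empty(0, "datetime64[ns]")
            self.rx_dates = np.empty(0, "datetime64[ns]")
            self.rx_desc = np.empty(0, object)

        self.consult_dates = (
            np.sort(consult["date"].to_numpy("datetime64[ns]"))
            if consult is not None and len(consult)
            else np.empty(0, "datetime64[ns]")
        )

        if comorb is not None and len(comorb):
            self.co_start = comorb["start_date"].to_numpy("datetime64[ns]")
            self.co_end = comorb["end_date"].to_numpy("datetime64[ns]")
            self.co_code = comorb["icpc_code"].astype(str).to_numpy(object)
            klass = comorb["duration_class"].to_numpy(object)
            self.co_chronic = np.fromiter(
                (classify_comorbidity_duration(c) == "chronic" for c in klass), bool, len(klass)
            )
            # implied end for temporary episodes missing an end date
            implied = np.array(
                [
                    s + np.timedelta64(_TEMP_WEEKS.get(c, 0) * 7, "D").astype("timedelta64[ns]")
                    if not ch
                    else np.datetime64("NaT", "ns")
                    for s, c, ch in zip(self.co_start, klass, self.co_chronic)
                ],
                "datetime64[ns]",
            )
            self.co_end = np.where(np.isnat(self.co_end), implied, self.co_end)
            self.co_mobility = np.fromiter(
                (c in MOBILITY_ICPC for c in self.co_code), bool, len(self.co_code)
            )
            self.co_mental = np.fromiter(
                (c in MENTAL_ICPC for c in self.co_code), bool, len(self.co_code)
            )
        else:
            self.co_start = np.empty(0, "datetime64[ns]")
            self.co_end = np.empty(0, "datetime64[ns]")
            self.co_code = np.empty(0, object)
            self.co_chronic = np.empty(0, bool)
            self.co_mobility = np.empty(0, bool)
            self.co_mental = np.empty(0, bool)

    # -- treatment status -------------------------------------------------
    def active_medications(self, at: np.datetime64, window_days: int) -> set[str]:
        lo = at - np.timedelta64(window_days, "D")
        mask = (self.rx_dates <= at) & (self.rx_dates >= lo)
        return set(self.rx_desc[mask])

    def medications_between(self, after: np.datetime64, upto: np.datetime64) -> set[str]:
        mask = (self.rx_dates > after) & (self.rx_dates <= upto)
        return set(self.rx_desc[mask])

    def lifestyle_at(self, at: np.datetime64) -> bool:
        return bool(len(self.advice_dates)) and self.advice_dates[0] <= at

    # -- condition --------------------------------------------------------
    def latest_value(self, desc: str, before: np.datetime64) -> float:
        """Mean of the most recent same-day values strictly before ``before``."""
        dates, values = self._per_desc[desc]
        i = np.searchsorted(dates, before, side="left")
        if i == 0:
            return np.nan
        day = dates[i - 1]
        j = i - 1
        while j > 0 and dates[j - 1] == day:
            j -= 1
        return float(np.nanmean(values[j:i]))

    def episodes_active(self, mask: np.ndarray, at: np.datetime64) -> bool:
        if not mask.any():
            return False
        start_ok = ~np.isnat(self.co_start[mask]) & (self.co_start[mask] <= at)
        chronic = self.co_chronic[mask]
        end = self.co_end[mask]
        within_end = np.isnat(end) | (end >= at)
        return bool(np.any(start_ok & (chronic | within_end)))

    def flags(self, at: np.datetime64) -> tuple[GuidelineFlags, bool]:
        at_ts = pd.Timestamp(at)
        age = at_ts.year - self.birth_year
        duration_years = float((at - self.diagnosis) / _DAY) / 365.25
        bmi = self.latest_value("BMI", at + _DAY)  # most recent up to and incl. at
        mobility = self.episodes_active(self.co_mobility, at) or bool(
            len(self.amputation_dates) and self.amputation_dates[0] <= at
        )
        mental = self.episodes_active(self.co_mental, at)
        has_chronic = bool(
            np.any(self.co_chronic & ~np.isnat(self.co_start) & (self.co_start <= at))
        )
        flags = GuidelineFlags(
            age_above_70y=age > 70,
            disease_duration_above_10y=duration_years > 10.0,
            bmi_below_25=not np.isnan(bmi) and bmi < 25.0,
            mobility_impaired=mobility,
            mental_impaired=mental,
        )
        return flags, has_chronic

    def baseline(self, at: np.datetime64) -> dict[str, float]:
        return {f"baseline_{d}": self.latest_value(d, at) for d in NUMERIC_MEASUREMENTS}

    def history_counts(self, at: np.datetime64) -> tuple[int, int, int, int]:
        def count(dates: np.ndarray) -> int:
            return int(
                np.searchsorted(dates, at, side="right")
                - np.searchsorted(dates, self.diagnosis, side="left")
            )

        n_co = int(np.sum(~np.isnat(self.co_start) & (self.co_start >= self.diagnosis) & (self.co_start <= at)))
        return (count(self.rx_all_dates), count(self.m_dates), count(self.consult_dates), n_co)

    def daily_series(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-day (dates, max value) for one variable's tests."""
        dates, values = self._per_desc[variable]
        if not len(dates):
            return dates, values
        days, inverse = np.unique(dates, return_inverse=True)
        day_max = np.full(len(days), -np.inf)
        np.maximum.at(day_max, inverse, values)
        return days, day_max


def _patient_arrays(tables: EventTables, patient_id: str) -> _PatientArrays:
    reg = tables.registry
    row = reg.loc[reg["patient_id"] == patient_id]
    if not len(row):
        raise KeyError(f"patient {patient_id!r} not in registry")

    def sel(frame: pd.DataFrame) -> pd.DataFrame:
        return frame[frame["patient_id"] == patient_id]

    return _PatientArrays(
        row.iloc[0],
        sel(tables.measurements),
        sel(tables.prescriptions),
        sel(tables.consultations),
        sel(tables.comorbidities),
    )


def assign_treatments(
    tables: EventTables | _PatientArrays,
    patient_id: str,
    index_date,
    outcome_date,
    active_window_days: int = 180,
) -> tuple[str, str]:
    """Active and new treatment regimen labels for one decision point.

    The active regimen combines medications recently prescribed before the
    index date with the persistent "healthy lifestyle" component (the three
    registered advice forms collapse into it).  The new regimen is read from
    the observation period: medications prescribed after the index date up
    to the outcome date, plus lifestyle status at the outcome date.  An
    unchanged regimen is the sentinel ``"no change"``.
    """
    pa = tables if isinstance(tables, _PatientArrays) else _patient_arrays(tables, patient_id)
    index64 = np.datetime64(pd.Timestamp(index_date), "ns")
    outcome64 = np.datetime64(pd.Timestamp(outcome_date), "ns")

    active = pa.active_medications(index64, active_window_days)
    if pa.lifestyle_at(index64):
        active.add(HEALTHY_LIFESTYLE)
    new = pa.medications_between(index64, outcome64)
    if pa.lifestyle_at(outcome64):
        new.add(HEALTHY_LIFESTYLE)

    active_label = render_label(active)
    new_label = render_label(new)
    if new_label == active_label:
        new_label = NO_CHANGE
    return active_label, new_label


def compute_guideline_flags(
    tables: EventTables | _PatientArrays, patient_id: str, index_date
) -> tuple[GuidelineFlags, bool]:
    """Guideline and impairment flags at the index date, plus the
    has-chronic-comorbidity bit.

    Age and disease duration are computed at the index date; the BMI flag
    uses the most recent BMI on or before it (false when none exists).
    Mobility/mental impairment is true iff a matching comorbidity episode is
    active: chronic episodes from their start onward, temporary episodes
    only within [start, end] (end imputed from the episode class when
    absent).  Recorded foot amputations also count as mobility impairment.
    """
    pa = tables if isinstance(tables, _PatientArrays) else _patient_arrays(tables, patient_id)
    return pa.flags(np.datetime64(pd.Timestamp(index_date), "ns"))


def extract_decision_points(
    tables: EventTables,
    spec: OutcomeSpec,
    active_window_days: int = 180,
) -> list[DecisionPoint]:
    """All decision points for one outcome variable across the population."""
    if spec.variable not in NUMERIC_MEASUREMENTS:
        raise ValueError(f"unknown outcome variable {spec.variable!r}")
    dps: list[DecisionPoint] = []
    registry = tables.registry.set_index("patient_id", drop=False)

    def groups(frame: pd.DataFrame) -> dict:
        return dict(iter(frame.groupby("patient_id"))) if len(frame) else {}

    meas_by = groups(tables.measurements)
    rx_by = groups(tables.prescriptions)
    consult_by = groups(tables.consultations)
    comorb_by = groups(tables.comorbidities)

    for pid, meas in meas_by.items():
        pa = _PatientArrays(
            registry.loc[pid], meas, rx_by.get(pid), consult_by.get(pid), comorb_by.get(pid)
        )
        days, day_max = pa.daily_series(spec.variable)
        if not len(days):
            continue
        gaps_min = np.timedelta64(spec.window_min_days, "D")
        gaps_max = np.timedelta64(spec.window_max_days, "D")

        for i, (d, v) in enumerate(zip(days, day_max)):
            if d <= pa.diagnosis or v <= spec.threshold:
                continue
            lo = np.searchsorted(days, d + gaps_min, side="left")
            hi = np.searchsorted(days, d + gaps_max, side="right")
            if lo >= hi:
                continue
            outcome_day = days[lo]  # earliest qualifying follow-up test
            controlled = day_max[lo] <= spec.threshold

            active_label, new_label = assign_treatments(
                pa, pid, pd.Timestamp(d), pd.Timestamp(outcome_day), active_window_days
            )
            flags, has_chronic = pa.flags(d)
            dps.append(
                DecisionPoint(
                    patient_id=pid,
                    index_date=pd.Timestamp(d),
                    index_value=float(v),
                    outcome_variable=spec.variable,
                    active_treatment=active_label,
                    new_treatment=new_label,
                    transition=transition_label(new_label, active_label),
                    outcome_label="controlled" if controlled else "uncontrolled",
                    outcome_date=pd.Timestamp(outcome_day),
                    guideline_flags=flags,
                    has_chronic_comorbidity=has_chronic,
                    baseline=pa.baseline(d),
                    history_counts=pa.history_counts(d),
                )
            )
    return dps


def dps_to_frame(dps: list[DecisionPoint]) -> pd.DataFrame:
    """One row per DP: labels, flags, baseline features and history counts."""
    rows = []
    for k, dp in enumerate(dps):
        row = {
            "dp_id": k,
            "patient_id": dp.patient_id,
            "index_date": dp.index_date,
            "index_value": dp.index_value,
            "outcome_variable": dp.outcome_variable,
            "active_treatment": dp.active_treatment,
            "new_treatment": dp.new_treatment,
            "transition": dp.transition,
            "outcome": dp.outcome_label,
            "outcome_date": dp.outcome_date,
            "has_chronic_comorbidity": dp.has_chronic_comorbidity,
            "n_prescriptions": dp.history_counts[0],
            "n_measurements": dp.history_counts[1],
            "n_consultations": dp.history_counts[2],
            "n_comorbidities": dp.history_counts[3],
        }
        for name in FLAG_NAMES:
            row[name] = getattr(dp.guideline_flags, name)
        row.update(dp.baseline)
        rows.append(row)
    return pd.DataFrame(rows)
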
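"""Synthetic longitudinal EHR generator with known ground truth.

Emulates the five-table primary-care extract the pipeline ingests: a patient
registry plus prescriptions, consultations, clinical measurements and
comorbidity episodes for a population of type 2 diabetes patients diagnosed
2012-2014 with at least six months of prior history and up to five years of
follow-up.

The generator closes the loop with the decision-point extractor: treatment
changes are placed shortly after uncontrolled HbA1c tests, and the outcome of
each decision is attached to the *next* same-variable test (scheduled so that
it falls inside the 90-365 day follow-up window).  That next test is drawn
controlled with a configurable per-treatment probability, optionally shifted
by patient-level confounders, so downstream percent-controlled estimates can
be checked against the generating probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import (
    HEALTHY_LIFESTYLE,
    LIFESTYLE_ADVICE_DESCRIPTIONS,
    MENTAL_ICPC,
    MOBILITY_ICPC,
    default_codemaps,
)
from .ingest import EventTables, TABLE_NAMES
from .labels import render_label

_PRIOR_HISTORY_DAYS = 183
_REFILL_DAYS = 90


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class FixtureError(ValueError):
    """Malformed event passed to the toy-patient builder."""


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    ``control_prob`` maps a *new-treatment* regimen label (or the sentinel
    ``"no change"``) to the probability that the follow-up test after that
    decision is controlled, before confounder adjustment.
    """

    n_patients: int
    seed: int = 0
    years_followup: float = 5.0
    treatment_menu: tuple[str, ...] = (HEALTHY_LIFESTYLE, "metformin", "gliclazide")
    control_prob: dict[str, float] = field(
        default_factory=lambda: {
            "no change": 0.45,
            "metformin": 0.55,
            HEALTHY_LIFESTYLE: 0.52,
            f"{HEALTHY_LIFESTYLE}_metformin": 0.62,
            "gliclazide_metformin": 0.50,
        }
    )
    default_control_prob: float = 0.45
    confounder_strength: float = 1.0
    measurement_rate: float = 2.5  # tests per patient-year, each variable
    missing_frac: dict[str, float] = field(
        default_factory=lambda: {
            "BMI": 0.10,
            "systolic BP": 0.10,
            "diastolic BP": 0.10,
            "LDL cholesterol": 0.30,
        }
    )
    guideline_frac: float = 0.25  # fraction with age>70; likewise BMI<25
    p_mobility: float = 0.20
    p_mental: float = 0.12
    p_change: float = 0.5  # chance an uncontrolled test triggers a change
    base_uncontrolled: float = 0.55

    def validate(self) -> "SimConfig":
        if self.n_patients < 0:
            raise ConfigError("n_patients must be nonnegative")
        if self.years_followup <= 0:
            raise ConfigError("years_followup must be positive")
        if self.measurement_rate < 0:
            raise ConfigError("measurement_rate must be nonnegative")
        probs = list(self.control_prob.values()) + [
            self.default_control_prob,
            self.guideline_frac,
            self.p_mobility,
            self.p_mental,
            self.p_change,
            self.base_uncontrolled,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if any(not (0.0 <= f < 1.0) for f in self.missing_frac.values()):
            raise ConfigError("missing fractions must lie in [0, 1)")
        if self.confounder_strength < 0:
            raise ConfigError("confounder_strength must be nonnegative")
        return self


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    decisions: pd.DataFrame  # one row per treatment decision (DP-generating)
    patients: pd.DataFrame  # latent severity and confounder score per patient


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _adjust(p: float, shift: float) -> float:
    return _sigmoid(_logit(p) + shift)


_EMPTY_COLUMNS = {
    "registry": ["patient_id", "birth_year", "diagnosis_date", "practice_id"],
    "prescriptions": ["patient_id", "date", "atc_code", "description"],
    "consultations": ["patient_id", "date", "ctg_code"],
    "measurements": ["patient_id", "date", "nhg_code", "description", "value"],
    "comorbidities": [
        "patient_id",
        "icpc_code",
        "description",
        "start_date",
        "end_date",
        "duration_class",
    ],
}


def _empty_tables() -> dict[str, list]:
    return {name: [] for name in TABLE_NAMES}


def _reverse_codes() -> dict[str, dict[str, str]]:
    maps = default_codemaps()
    return {
        system: {desc: code for code, desc in maps[system].entries.items()}
        for system in ("NHG", "ATC", "ICPC")
    }


def _test_times(rng: np.random.Generator, rate: float, horizon_days: float) -> list[float]:
    """Test days after diagnosis, spaced so gaps land in the outcome window."""
    if rate <= 0:
        return []
    mean_gap = 365.0 / rate
    lo, hi = max(95.0, 0.6 * mean_gap), min(350.0, max(96.0, 1.4 * mean_gap))
    times = []
    t = rng.uniform(30.0, 120.0)
    while t <= horizon_days:
        times.append(t)
        t += rng.uniform(lo, hi)
    return times


def simulate_population(config: SimConfig) -> tuple[EventTables, GroundTruth]:
    """Generate the five EHR tables plus the generating ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rev = _reverse_codes()
    nhg_of = rev["NHG"]
    atc_of = rev["ATC"]
    icpc_of = rev["ICPC"]
    gamma = config.confounder_strength

    rows = _empty_tables()
    decisions: list[dict] = []
    patients: list[dict] = []
    horizon = config.years_followup * 365.0

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        practice = f"G{int(rng.integers(1, 21)):02d}"
        dx = pd.Timestamp("2012-01-01") + pd.Timedelta(days=int(rng.integers(0, 1096)))
        age_dx = rng.uniform(71, 88) if rng.random() < config.guideline_frac else rng.uniform(42, 70)
        birth_year = dx.year - int(age_dx)
        bmi0 = rng.uniform(20.0, 24.5) if rng.random() < config.guideline_frac else rng.uniform(25.5, 38.0)
        severity = rng.normal()
        conf = 0.6 * severity + 0.5 * (age_dx - 60.0) / 12.0 + 0.4 * (bmi0 - 28.0) / 5.0
        rows["registry"].append(
            {
                "patient_id": pid,
                "birth_year": birth_year,
                "diagnosis_date": dx,
                "practice_id": practice,
            }
        )
        patients.append({"patient_id": pid, "severity": severity, "confounder": conf})

        def record_measurement(day: float, desc: str, value: float) -> None:
            if rng.random() < config.missing_frac.get(desc, 0.0):
                return
            rows["measurements"].append(
                {
                    "patient_id": pid,
                    "date": dx + pd.Timedelta(days=int(day)),
                    "nhg_code": nhg_of.get(desc, desc),
                    "description": desc,
                    "value": round(float(value), 2),
                }
            )

        # Pre-diagnosis glycemia tests (the measurements the diagnosis rests
        # on); they also give every later DP a same-variable baseline value.
        record_measurement(-int(rng.integers(10, 61)), "HbA1c", rng.uniform(6.8, 9.5))
        record_measurement(-int(rng.integers(10, 61)), "fasting glucose", rng.uniform(6.5, 12.0))

        # Baseline clinical measurements at diagnosis, refreshed yearly.
        for year in range(int(config.years_followup) + 1):
            day = year * 365.0
            if day > horizon:
                break
            if year == 0 or rng.random() < 0.7:
                record_measurement(day, "BMI", bmi0 + rng.normal(0, 0.8))
                record_measurement(day, "systolic BP", rng.normal(135, 15))
                record_measurement(day, "diastolic BP", rng.normal(82, 10))
                record_measurement(day, "LDL cholesterol", rng.normal(3.2, 0.8))

        # Consultations (incl. some prior history, required to exist).
        n_consult = 2 + rng.poisson(3.5 * config.years_followup)
        consult_days = np.concatenate(
            [
                rng.uniform(-_PRIOR_HISTORY_DAYS, -10, size=2),
                rng.uniform(0, horizon, size=n_consult - 2),
            ]
        )
        for day in np.sort(consult_days):
            rows["consultations"].append(
                {
                    "patient_id": pid,
                    "date": dx + pd.Timedelta(days=int(day)),
                    "ctg_code": str(rng.choice(["12000", "12000", "12001", "12004"])),
                }
            )

        # Comorbidity episodes (mobility, mental, neutral).
        def episode(code: str, kind: str) -> None:
            start = dx + pd.Timedelta(days=int(rng.uniform(-100, horizon * 0.8)))
            if kind == "chronic":
                klass = str(rng.choice(["chronic", "long-lasting"]))
                end = pd.NaT
            else:
                klass = str(rng.choice(["4 weeks", "8 weeks", "16 weeks"]))
                end = start + pd.Timedelta(weeks=int(klass.split()[0]))
            rows["comorbidities"].append(
                {
                    "patient_id": pid,
                    "icpc_code": code,
                    "description": code,  # replaced by the ICPC map after the loop
                    "start_date": start,
                    "end_date": end,
                    "duration_class": klass,
                }
            )

        if rng.random() < config.p_mobility:
            code = str(rng.choice(list(MOBILITY_ICPC)))
            episode(code, MOBILITY_ICPC[code])
        if rng.random() < config.p_mental:
            code = str(rng.choice(list(MENTAL_ICPC)))
            episode(code, MENTAL_ICPC[code])
        if rng.random() < 0.30:
            episode("K86", "chronic")

        # Initial treatment regimen.
        u = rng.random()
        if u < 0.30:
            active: set[str] = set()
        elif u < 0.70:
            active = {"metformin"}
        elif u < 0.85:
            active = {HEALTHY_LIFESTYLE}
        else:
            active = {HEALTHY_LIFESTYLE, "metformin"}
        med_starts: dict[str, float] = {m: 0.0 for m in active if m != HEALTHY_LIFESTYLE}
        if HEALTHY_LIFESTYLE in active:
            record_advice_day = 0.0
            desc = str(rng.choice(LIFESTYLE_ADVICE_DESCRIPTIONS))
            rows["measurements"].append(
                {
                    "patient_id": pid,
                    "date": dx + pd.Timedelta(days=int(record_advice_day)),
                    "nhg_code": nhg_of.get(desc, desc),
                    "description": desc,
                    "value": 1.0,
                }
            )

        # HbA1c stream drives treatment decisions; glucose stream is passive.
        pending: tuple[float, float] | None = None
        for t in _test_times(rng, config.measurement_rate, horizon):
            if pending is not None and 90.0 <= t - pending[0] <= 365.0:
                p_controlled = pending[1]
            else:
                p_controlled = _adjust(1.0 - config.base_uncontrolled, -0.5 * gamma * conf)
            pending = None
            controlled = rng.random() < p_controlled
            value = rng.uniform(5.6, 6.9) if controlled else rng.uniform(7.1, 11.0)
            record_measurement(t, "HbA1c", value)
            if controlled:
                continue
            # Index event: decide on a treatment change.
            candidates = [m for m in config.treatment_menu if m not in active]
            changed = bool(candidates) and rng.random() < _adjust(config.p_change, gamma * conf)
            if changed:
                weights = np.array(
                    [
                        math.exp(0.5 * gamma * conf) if c == HEALTHY_LIFESTYLE else 1.0
                        for c in candidates
                    ]
                )
                new_component = candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))]
                change_day = t + rng.uniform(3, 25)
                if change_day <= horizon:
                    if new_component == HEALTHY_LIFESTYLE:
                        desc = str(rng.choice(LIFESTYLE_ADVICE_DESCRIPTIONS))
                        rows["measurements"].append(
                            {
                                "patient_id": pid,
                                "date": dx + pd.Timedelta(days=int(change_day)),
                                "nhg_code": nhg_of.get(desc, desc),
                                "description": desc,
                                "value": 1.0,
                            }
                        )
                    else:
                        med_starts[new_component] = change_day
                    active = active | {new_component}
                    option = render_label(active)
                else:
                    changed = False
                    option = "no change"
            else:
                option = "no change"
            p_next = config.control_prob.get(option, config.default_control_prob)
            p_next = _adjust(p_next, 0.4 * gamma * conf)
            pending = (t, p_next)
            decisions.append(
                {
                    "patient_id": pid,
                    "index_day": int(t),
                    "index_date": dx + pd.Timedelta(days=int(t)),
                    "option": option,
                    "changed": changed,
                    "intended_control_prob": p_next,
                }
            )

        # Passive fasting-glucose stream, correlated with severity.
        for t in _test_times(rng, config.measurement_rate, horizon):
            p_controlled = _adjust(0.35, -0.5 * severity - 0.3 * gamma * conf)
            controlled = rng.random() < p_controlled
            value = rng.uniform(4.5, 6.9) if controlled else rng.uniform(7.1, 14.0)
            record_measurement(t, "fasting glucose", value)

        # Repeat prescriptions every ~90 days while a medication is active.
        for med, start in med_starts.items():
            day = start
            while day <= horizon:
                rows["prescriptions"].append(
                    {
                        "patient_id": pid,
                        "date": dx + pd.Timedelta(days=int(day)),
                        "atc_code": atc_of.get(med, med),
                        "description": med,
                    }
                )
                day += _REFILL_DAYS

    frames = {
        name: pd.DataFrame(rows[name], columns=_EMPTY_COLUMNS[name]) for name in TABLE_NAMES
    }
    icpc_map = default_codemaps()["ICPC"]
    if len(frames["comorbidities"]):
        frames["comorbidities"]["description"] = frames["comorbidities"]["icpc_code"].map(
            icpc_map.describe
        )
    for name, date_cols in (
        ("registry", ["diagnosis_date"]),
        ("prescriptions", ["date"]),
        ("consultations", ["date"]),
        ("measurements", ["date"]),
        ("comorbidities", ["start_date", "end_date"]),
    ):
        for col in date_cols:
            frames[name][col] = pd.to_datetime(frames[name][col])
    for name in ("prescriptions", "consultations", "measurements"):
        frames[name] = frames[name].sort_values(["patient_id", "date"], kind="stable").reset_index(
            drop=True
        )

    tables = EventTables(**frames, meta={"config": asdict(config)})
    truth = GroundTruth(
        decisions=pd.DataFrame(
            decisions,
            columns=[
                "patient_id",
                "index_day",
                "index_date",
                "option",
                "changed",
                "intended_control_prob",
            ],
        ),
        patients=pd.DataFrame(patients, columns=["patient_id", "severity", "confounder"]),
    )
    if config.n_patients:
        tables.validate()
    return tables, truth


def make_toy_patient(
    events: list[dict],
    patient_id: str = "P00000",
    birth_year: int = 1950,
    diagnosis_date: str = "2013-01-01",
    practice_id: str = "G01",
) -> EventTables:
    """Build single-patient EventTables from a hand-written event list.

    Each event is a dict with a ``table`` key ("prescriptions",
    "consultations", "measurements" or "comorbidities") plus that table's
    columns (``patient_id`` is filled in automatically).  Dates may be given
    as ISO strings or day offsets are not supported -- use explicit dates.
    """
    rows = _empty_tables()
    rows["registry"].append(
        {
            "patient_id": patient_id,
            "birth_year": birth_year,
            "diagnosis_date": pd.Timestamp(diagnosis_date),
            "practice_id": practice_id,
        }
    )
    for event in events:
        if not isinstance(event, dict) or "table" not in event:
            raise FixtureError(f"event must be a dict with a 'table' key: {event!r}")
        table = event["table"]
        if table not in TABLE_NAMES or table == "registry":
            raise FixtureError(f"unknown event table {table!r}")
        row = {k: v for k, v in event.items() if k != "table"}
        row.setdefault("patient_id", patient_id)
        missing = [
            c
            for c in _EMPTY_COLUMNS[table]
            if c not in row and c not in ("description", "end_date", "value")
        ]
        if missing:
            raise FixtureError(f"event for {table!r} is missing fields {missing}")
        for col in ("date", "start_date", "end_date"):
            if col in row and row[col] is not None:
                row[col] = pd.Timestamp(row[col])
        rows[table].append(row)
    frames = {name: pd.DataFrame(rows[name], columns=_EMPTY_COLUMNS[name]) for name in TABLE_NAMES}
    for name, cols in (
        ("registry", ["diagnosis_date"]),
        ("prescriptions", ["date"]),
        ("consultations", ["date"]),
        ("measurements", ["date"]),
        ("comorbidities", ["start_date", "end_date"]),
    ):
        for col in cols:
            frames[name][col] = pd.to_datetime(frames[name][col])
    return EventTables(**frames).validate()


def write_ground_truth(truth: GroundTruth, out_dir: Path | str) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "decisions": out_dir / "ground_truth_decisions.csv",
        "patients": out_dir / "ground_truth_patients.csv",
    }
    truth.decisions.to_csv(paths["decisions"], index=False)
    truth.patients.to_csv(paths["patients"], index=False)
    return paths
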
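"""Clinical code dictionaries and canonical vocabularies.

Small bundled subsets of the Dutch primary-care coding systems, sufficient
for the diabetes workflow:

* NHG  -- clinical measurement codes (HbA1c, fasting glucose, BMI, ...),
* ATC  -- prescription codes for the glucose-lowering medications considered,
* ICPC -- comorbidity / episode codes (mobility and mental-state sets),
* CTG  -- consultation tariff codes.

The full official dictionaries contain thousands of entries; only the codes
the pipeline interprets are bundled.  Unmapped codes pass through with the
raw code used as its own description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

CODE_SYSTEMS = ("NHG", "ATC", "ICPC", "CTG")


@dataclass(frozen=True)
class CodeMap:
    """A code -> human-readable description dictionary for one code system."""

    system: str
    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.system not in CODE_SYSTEMS:
            raise ValueError(f"unknown code system {self.system!r}")

    def describe(self, code: object) -> str:
        """Description for ``code``; falls back to the raw code if unmapped."""
        key = str(code)
        return self.entries.get(key, key)

    def __contains__(self, code: object) -> bool:
        return str(code) in self.entries


def _load_bundled(system: str, filename: str) -> CodeMap:
    with resources.files("precohort.data").joinpath(filename).open("rb") as fh:
        frame = pd.read_csv(fh, dtype=str)
    return CodeMap(system=system, entries=dict(zip(frame["code"], frame["description"])))


def default_codemaps() -> dict[str, CodeMap]:
    """The bundled NHG/ATC/ICPC/CTG dictionaries keyed by system name."""
    return {
        "NHG": _load_bundled("NHG", "nhg.csv"),
        "ATC": _load_bundled("ATC", "atc.csv"),
        "ICPC": _load_bundled("ICPC", "icpc.csv"),
        "CTG": _load_bundled("CTG", "ctg.csv"),
    }


# Glucose-lowering medications considered as pharmacologic treatment
# components (canonical lower-case names, as rendered in treatment labels).
T2DM_MEDICATIONS = frozenset(
    {
        "metformin",
        "sitagliptin",
        "insulin aspart",
        "insulin degludec",
        "insulin detemir",
        "insulin glargine",
        "insulin (human)",
        "repaglinide",
        "glimepiride",
        "tolbutamide",
        "gliclazide",
    }
)

# The three registered forms of lifestyle advice, collapsed downstream into
# the single nonpharmacological treatment component "healthy lifestyle".
LIFESTYLE_ADVICE_DESCRIPTIONS = (
    "follow dietary advice",
    "advice healthy food given",
    "advice physical activity given",
)
HEALTHY_LIFESTYLE = "healthy lifestyle"

# ICPC comorbidity codes indicating a possible mobility impairment, with the
# duration kind typically carried by their illness episodes.
MOBILITY_ICPC = {
    "L15": "temporary",
    "L95": "chronic",
    "L90": "chronic",
    "N17": "chronic",
    "L14": "chronic",
    "K90": "chronic",
    "L73": "temporary",
    "L03": "chronic",
    "L89": "chronic",
    "L76": "temporary",
    "R96": "chronic",
    "L79": "temporary",
    "L74": "temporary",
    "L16": "chronic",
    "L97": "chronic",
    "N18": "chronic",
    "L84": "chronic",
    "L77": "temporary",
    "L75": "temporary",
    "L70": "temporary",
    "L78": "temporary",
}

# NHG measurement codes also counted as (chronic) mobility impairments.
MOBILITY_NHG = ("K93", "K94")

# ICPC comorbidity codes indicating an altered emotional / mental state.
MENTAL_ICPC = {
    "P01": "temporary",
    "P02": "temporary",
    "P20": "chronic",
    "P74": "chronic",
    "Z18": "temporary",
    "Z19": "chronic",
    "P06": "temporary",
    "Z15": "temporary",
    "A80": "temporary",
    "P03": "temporary",
    "P99": "chronic",
    "P72": "chronic",
    "P76": "chronic",
    "P73": "chronic",
    "Z25": "temporary",
    "P04": "temporary",
    "P77": "chronic",
    "P98": "chronic",
    "P70": "chronic",
}

# Measurement descriptions treated as numeric baseline features.
NUMERIC_MEASUREMENTS = (
    "HbA1c",
    "fasting glucose",
    "BMI",
    "systolic BP",
    "diastolic BP",
    "LDL cholesterol",
)
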
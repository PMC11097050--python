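"""Published count/percentage pairs used as a recomputation fixture.

Each entry is (numerator, denominator, printed_percentage_string): the
percentage as printed in the study's cohort tables, alongside the counts it
was computed from.  Recomputing numerator/denominator must reproduce every
printed value at its printed precision (half-up rounding).
"""

# Cohort-level percentages of patients with/without measurements (n = 11,490).
PATIENT_COVERAGE = [
    (10375, 11490, "90.3"),
    (1115, 11490, "9.7"),
    (10824, 11490, "94.2"),
    (666, 11490, "5.8"),
]

# Outcome-class proportions quoted in the running text.
TEXT_RATIOS = [
    (9704, 17328, "56"),  # uncontrolled share, HbA1c scenario
    (7624, 17328, "44"),  # controlled share, HbA1c scenario
    (32401, 41014, "79"),  # uncontrolled share, fasting-glucose scenario
    (8613, 41014, "21"),  # controlled share, fasting-glucose scenario
    (16480, 28709, "57.4"),  # "no change" share quoted in the text
    (213, 370, "57.57"),
    (63, 98, "64.29"),
    (210, 324, "64.8"),
    (605, 1324, "45.69"),
    (719, 1324, "54.31"),
]

# Global treatment-option table, HbA1c scenario (n = 12,129 scoring DPs):
# (option, n, printed frequency %, n_controlled, printed controlled %).
GLOBAL_OPTIONS_HBA1C = [
    ("No change", 5747, "47.38", 2541, "44.21"),
    ("Metformin_new+healthy lifestyle_metformin_stop", 1324, "10.92", 605, "45.69"),
    ("Healthy lifestyle_new+healthy lifestyle_metformin_stop", 402, "3.31", 170, "42.29"),
    ("Metformin_new+no treatment_stop", 370, "3.05", 213, "57.57"),
    ("Healthy lifestyle_metformin_new+metformin_stop", 324, "2.67", 210, "64.81"),
    ("Healthy lifestyle_metformin_new+healthy lifestyle_stop", 246, "2.03", 165, "67.07"),
    ("Healthy lifestyle_metformin_new+no treatment_stop", 222, "1.83", 138, "62.16"),
    ("Gliclazide_healthy lifestyle_new+healthy lifestyle_metformin_stop", 217, "1.79", 86, "39.63"),
    ("Metformin_new+healthy lifestyle_stop", 169, "1.39", 91, "53.85"),
    ("Gliclazide_new+healthy lifestyle_metformin_stop", 151, "1.24", 65, "43.05"),
    ("Gliclazide_new+metformin_stop", 148, "1.22", 80, "54.05"),
    (
        "Gliclazide_metformin_new+gliclazide_healthy lifestyle_metformin_stop",
        147,
        "1.21",
        38,
        "25.85",
    ),
    ("Gliclazide_new+gliclazide_healthy lifestyle_stop", 123, "1.01", 41, "33.33"),
    ("Healthy lifestyle_new+no treatment_stop", 98, "0.81", 63, "64.29"),
    (
        "Gliclazide_healthy lifestyle_metformin_new+healthy lifestyle_metformin_stop",
        68,
        "0.56",
        32,
        "47.06",
    ),
    ("Gliclazide_metformin_new+metformin_stop", 59, "0.49", 30, "50.85"),
    ("Metformin_new+gliclazide_healthy lifestyle_stop", 59, "0.49", 16, "27.12"),
    (
        "Gliclazide_healthy lifestyle_new+gliclazide_healthy lifestyle_metformin_stop",
        58,
        "0.48",
        17,
        "29.31",
    ),
    ("Healthy lifestyle_metformin_new+gliclazide_healthy lifestyle_stop", 58, "0.48", 12, "20.69"),
    (
        "Healthy lifestyle_metformin_new+gliclazide_healthy lifestyle_metformin_stop",
        57,
        "0.47",
        21,
        "36.84",
    ),
]
GLOBAL_TOTAL_HBA1C = 12129

# Global treatment-option table, fasting-glucose scenario (n = 28,710).
GLOBAL_OPTIONS_GLUCOSE = [
    ("No change", 16480, "57.4", 3839, "23.29"),
    ("Metformin_new+healthy lifestyle_metformin_stop", 3130, "10.9", 586, "18.72"),
    ("Healthy lifestyle_new+healthy lifestyle_metformin_stop", 1011, "3.52", 201, "19.88"),
    ("Metformin_new+no treatment_stop", 639, "2.23", 110, "17.21"),
    ("Healthy lifestyle_new+no treatment_stop", 638, "2.22", 203, "31.82"),
    ("Healthy lifestyle_metformin_new+metformin_stop", 612, "2.13", 59, "9.64"),
    ("Healthy lifestyle_metformin_new+healthy lifestyle_stop", 429, "1.49", 157, "36.6"),
    ("Healthy lifestyle_metformin_new+no treatment_stop", 399, "1.39", 69, "17.29"),
    (
        "Gliclazide_metformin_new+gliclazide_healthy lifestyle_metformin_stop",
        284,
        "0.99",
        28,
        "9.86",
    ),
    ("Metformin_new+healthy lifestyle_stop", 265, "0.92", 97, "36.6"),
    ("Gliclazide_healthy lifestyle_new+healthy lifestyle_metformin_stop", 259, "0.9", 32, "12.36"),
    ("Gliclazide_new+gliclazide_healthy lifestyle_stop", 223, "0.78", 39, "17.49"),
    ("Gliclazide_new+healthy lifestyle_metformin_stop", 204, "0.71", 54, "26.47"),
    ("Gliclazide_new+metformin_stop", 165, "0.57", 22, "13.33"),
    (
        "Gliclazide_healthy lifestyle_metformin_new+healthy lifestyle_metformin_stop",
        105,
        "0.37",
        5,
        "4.76",
    ),
    ("Healthy lifestyle_new+metformin_stop", 102, "0.36", 15, "14.71"),
    ("Metformin_new+gliclazide_healthy lifestyle_stop", 102, "0.36", 13, "12.75"),
    ("Gliclazide_metformin_new+gliclazide_healthy lifestyle_stop", 98, "0.34", 8, "8.16"),
    ("Healthy lifestyle_metformin_new+gliclazide_healthy lifestyle_stop", 93, "0.32", 6, "6.45"),
    (
        "Metformin_tolbutamide_new+healthy lifestyle_metformin_tolbutamide_stop",
        91,
        "0.32",
        2,
        "2.2",
    ),
]
GLOBAL_TOTAL_GLUCOSE = 28710


def decimals_of(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def all_ratio_entries():
    """Flatten every (numerator, denominator, printed) triple."""
    entries = list(PATIENT_COVERAGE) + list(TEXT_RATIOS)
    for rows, total in (
        (GLOBAL_OPTIONS_HBA1C, GLOBAL_TOTAL_HBA1C),
        (GLOBAL_OPTIONS_GLUCOSE, GLOBAL_TOTAL_GLUCOSE),
    ):
        for _option, n, freq, n_ctrl, pct in rows:
            entries.append((n, total, freq))
            entries.append((n_ctrl, n, pct))
    return entries
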
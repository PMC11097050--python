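"""Treatment-option outcome statistics with multiplicity control.

DPs (of a precision cohort, or of the whole scoring set for the global view)
are grouped by their treatment decision, rendered as a transition label
(``Metformin_new+no treatment_stop``) with ``No change`` as the baseline
option.  Per option the module reports the DP count, percent controlled,
the difference versus the baseline in percentage points, and a chi-square
test of the 2x2 controlled/uncontrolled table against the baseline with a
Bonferroni-corrected significance threshold.  Options covering less than
1 % of the cohort's DPs (minimum 10) are excluded from testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .labels import NO_CHANGE_OPTION


class BaselineMissingError(ValueError):
    """No baseline ("No change") group to compare against.

    The per-option summaries, computed without deltas or p-values, are
    attached as the ``summaries`` attribute.
    """

    def __init__(self, message: str, summaries=None):
        super().__init__(message)
        self.summaries = summaries or []


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("empty group")
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class TreatmentOptionSummary:
    option: str
    n: int
    n_controlled: int
    pct_of_total: float
    pct_controlled: float
    delta_vs_nochange: float | None
    p_raw: float | None
    significant: bool
    included: bool

    @property
    def n_uncontrolled(self) -> int:
        return self.n - self.n_controlled


def chi_square_vs_baseline(
    controlled: int, uncontrolled: int, base_controlled: int, base_uncontrolled: int
) -> float:
    """p-value of the 2x2 chi-square test (no continuity correction)."""
    table = np.array([[controlled, uncontrolled], [base_controlled, base_uncontrolled]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(chi2_contingency(table, correction=False)[1])


def summarize_options(
    dps: pd.DataFrame,
    min_frac: float = 0.01,
    min_count: int = 10,
    alpha: float = 0.05,
) -> list[TreatmentOptionSummary]:
    """Per-treatment-option outcome table for one set of DPs.

    Options with fewer than max(min_count, ceil(min_frac * total)) DPs are
    retained for reporting but excluded from the significance family.  Each
    included non-baseline option is tested against "No change" at the
    Bonferroni-corrected level alpha / m.
    """
    total = len(dps)
    threshold = max(min_count, math.ceil(min_frac * total))
    grouped = dps.groupby("transition")["outcome"]
    stats = {
        option: (int(len(g)), int((g == "controlled").sum())) for option, g in grouped
    }
    baseline = stats.get(NO_CHANGE_OPTION)
    included = {o for o, (n, _) in stats.items() if n >= threshold}
    m = len(included - {NO_CHANGE_OPTION})

    summaries = []
    for option, (n, n_ctrl) in stats.items():
        pct_ctrl = percent(n_ctrl, n)
        delta = p_raw = None
        significant = False
        if baseline is not None and option != NO_CHANGE_OPTION:
            base_n, base_ctrl = baseline
            delta = round(pct_ctrl - percent(base_ctrl, base_n), 2)
            if option in included and m > 0:
                p_raw = chi_square_vs_baseline(
                    n_ctrl, n - n_ctrl, base_ctrl, base_n - base_ctrl
                )
                significant = p_raw < alpha / m
        summaries.append(
            TreatmentOptionSummary(
                option=option,
                n=n,
                n_controlled=n_ctrl,
                pct_of_total=percent(n, total),
                pct_controlled=pct_ctrl,
                delta_vs_nochange=delta,
                p_raw=p_raw,
                significant=significant,
                included=option in included,
            )
        )
    summaries.sort(key=lambda s: (-s.n, s.option))
    if baseline is None and summaries:
        raise BaselineMissingError(
            "no 'No change' baseline group; summaries have no deltas or p-values",
            summaries=summaries,
        )
    return summaries


def summaries_to_frame(summaries: list[TreatmentOptionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "option": s.option,
                "n": s.n,
                "pct_of_total": s.pct_of_total,
                "n_controlled": s.n_controlled,
                "pct_controlled": s.pct_controlled,
                "delta_vs_nochange": s.delta_vs_nochange,
                "p_raw": s.p_raw,
                "significant": s.significant,
                "included": s.included,
            }
            for s in summaries
        ]
    )


def global_analysis(
    scoring_dps: pd.DataFrame,
    min_frac: float = 0.01,
    min_count: int = 10,
    alpha: float = 0.05,
    top_k: int | None = 20,
) -> pd.DataFrame:
    """Option table across all filter cohorts, largest options first."""
    summaries = summarize_options(scoring_dps, min_frac=min_frac, min_count=min_count, alpha=alpha)
    frame = summaries_to_frame(summaries)
    if top_k is not None:
        frame = frame.head(top_k)
    return frame.reset_index(drop=True)


def sankey_export(summaries: list[TreatmentOptionSummary], cohort_label: str = "cohort") -> dict:
    """Node/link data for a treatment-pathway Sankey diagram.

    One link per included option from the cohort node, split into controlled
    (green) and uncontrolled (red) terminal nodes; link width equals the DP
    count.  Option color encodes the comparison with the baseline: green if
    more often controlled, red if less, gray for "No change"; dark shades
    mark Bonferroni-significant options.
    """
    nodes = [
        {"id": 0, "label": cohort_label, "color": "black"},
        {"id": 1, "label": "controlled", "color": "green"},
        {"id": 2, "label": "uncontrolled", "color": "red"},
    ]
    links = []
    for s in summaries:
        if not s.included:
            continue
        if s.option == NO_CHANGE_OPTION:
            color = "gray"
        elif s.delta_vs_nochange is not None and s.delta_vs_nochange > 0:
            color = "darkgreen" if s.significant else "green"
        else:
            color = "darkred" if s.significant else "red"
        node_id = len(nodes)
        nodes.append({"id": node_id, "label": s.option, "color": color})
        links.append(
            {
                "source": 0,
                "target": node_id,
                "value": s.n,
                "label": f"{s.option} ({s.pct_controlled}%)",
                "color": color,
            }
        )
        links.append({"source": node_id, "target": 1, "value": s.n_controlled, "color": "green"})
        links.append(
            {"source": node_id, "target": 2, "value": s.n_uncontrolled, "color": "red"}
        )
    return {"nodes": nodes, "links": links}
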
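"""Filter cohorts, similarity ranking and covariate balance.

Cohort selection is a two-step procedure.  First, decision points are
grouped by a *filter key* -- the true guideline/impairment flags plus the
active treatment (e.g. ``age_above_70y+metformin``); only cohorts with more
than 200 DPs are considered representative enough for precision cohorts.
Second, the members of the query's filter cohort are ranked by the learned
weighted distance to the query DP; distances are normalized relative to the
closest match ((d - d_min) / SD of raw distances, i.e. "spreads above the
minimum") and members below a normalized-distance cutoff (default 2) form
the precision cohort.

Covariate balance between the treatment-change and no-change groups is the
standardized mean difference (difference of means over the SD of the
treatment-change group); values near 0 indicate balanced confounders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decision_points import FLAG_NAMES
from .labels import NO_CHANGE_OPTION, NO_TREATMENT
from .similarity import SimilarityModel

ALL_FALSE_KEY = "all_guidelines_variables_false"


class BalanceError(ValueError):
    """Covariate balance is undefined (an empty comparison group)."""


class CohortContractError(ValueError):
    """Query and cohort are inconsistent (features or filter key)."""


def filter_key(flags: dict | pd.Series, active_treatment: str) -> str:
    """Render the filter variable for one DP.

    The true guideline/impairment flags (sorted) and the active-treatment
    label are joined with '+'; a DP with no true flag and no treatment
    renders as the catch-all key ``all_guidelines_variables_false``.
    """
    parts = sorted(name for name in FLAG_NAMES if bool(flags[name]))
    if active_treatment != NO_TREATMENT:
        parts.append(active_treatment)
    return "+".join(parts) if parts else ALL_FALSE_KEY


def attach_filter_keys(dps: pd.DataFrame) -> pd.Series:
    keys = dps.apply(lambda row: filter_key(row, row["active_treatment"]), axis=1)
    keys.name = "filter_key"
    return keys


@dataclass
class FilterCohorts:
    """DPs grouped by filter key, with eligibility per the >200-DP rule."""

    members: dict[str, np.ndarray]  # key -> row labels of the DP frame
    min_size: int
    chart: pd.DataFrame  # key, size, eligible, cumulative coverage (%)

    def eligible(self, key: str) -> bool:
        return key in self.members and len(self.members[key]) > self.min_size


def build_filter_cohorts(dps: pd.DataFrame, min_size: int = 200) -> FilterCohorts:
    """Group scoring-set DPs by filter key; flag cohorts of size <= min_size.

    Also emits ranked bar-chart data (size per cohort plus cumulative
    percent coverage of all DPs).
    """
    keys = dps["filter_key"] if "filter_key" in dps.columns else attach_filter_keys(dps)
    members = {key: idx.to_numpy() for key, idx in dps.groupby(keys).groups.items()}
    sizes = sorted(((k, len(v)) for k, v in members.items()), key=lambda kv: (-kv[1], kv[0]))
    total = sum(n for _, n in sizes) or 1
    chart = pd.DataFrame(
        {
            "filter_key": [k for k, _ in sizes],
            "size": [n for _, n in sizes],
            "eligible": [n > min_size for _, n in sizes],
        }
    )
    chart["cumulative_coverage_pct"] = 100.0 * chart["size"].cumsum() / total
    return FilterCohorts(members=members, min_size=min_size, chart=chart)


@dataclass
class PrecisionCohort:
    """Similarity-ranked members of the query's filter cohort."""

    query_id: object
    filter_key: str
    members: pd.DataFrame  # dp_id, raw_distance, normalized_distance (ascending)
    cutoff: float | None = None
    balance_profile: pd.DataFrame | None = None
    status: str = "ok"  # "ok" | "insufficient data"
    notes: list[str] = field(default_factory=list)


def score_cohort(
    model: SimilarityModel,
    cohort_features: pd.DataFrame,
    query_vector: pd.Series | np.ndarray,
    query_id: object = None,
    key: str = "",
) -> PrecisionCohort:
    """Raw and normalized distances from every cohort member to the query.

    ``cohort_features`` holds the model's features (standardized) indexed by
    DP id; the query vector is on the same scale.  The normalized distance
    is (d - d_min) / SD(d): 0 for the closest member, and the cutoff value
    reads as "spreads of raw distance above the closest match".  The query's
    own DP (when ``query_id`` indexes the cohort) is excluded from the
    members: a patient's own outcome is not part of their evidence pool.
    """
    if query_id is not None and query_id in cohort_features.index:
        cohort_features = cohort_features.drop(index=query_id)
    X = cohort_features[model.features].to_numpy(float)
    q = np.asarray(
        query_vector[model.features] if isinstance(query_vector, pd.Series) else query_vector,
        float,
    )
    if q.shape != (len(model.features),):
        raise CohortContractError("query vector does not match the model's features")
    if np.isnan(X).any() or np.isnan(q).any():
        raise CohortContractError("features must be imputed before similarity scoring")
    diff = model.transform(X) - model.transform(q[None, :])
    raw = np.sqrt((diff * diff).sum(axis=1))
    spread = float(np.std(raw, ddof=1)) if len(raw) > 1 else 0.0
    normalized = (raw - raw.min()) / spread if spread > 0 else np.zeros_like(raw)
    members = pd.DataFrame(
        {
            "dp_id": cohort_features.index.to_numpy(),
            "raw_distance": raw,
            "normalized_distance": normalized,
        }
    ).sort_values(["raw_distance", "dp_id"], kind="stable", ignore_index=True)
    return PrecisionCohort(query_id=query_id, filter_key=key, members=members)


def covariate_balance(
    members: pd.DataFrame,
    change_mask: pd.Series | np.ndarray,
    covariates: list[str],
    sd_reference: pd.Series | None = None,
) -> tuple[pd.Series, float]:
    """Standardized mean difference per covariate, and the max-|SMD| summary.

    Balance = (mean in the treatment-change group - mean in the no-change
    group) / sample SD of the treatment-change ("treated") group.  Covariates
    with zero SD in the change group are skipped with a warning.

    When balance is tracked across nested subsets (the distance-cutoff
    profile), pass ``sd_reference`` -- per-covariate SDs from the full
    cohort's change group -- so the denominator stays fixed and the SMDs of
    differently sized subsets are comparable; a shrinking within-subset SD
    would otherwise inflate the ratio mechanically.
    """
    mask = np.asarray(change_mask, bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise BalanceError("both a change and a no-change group are required")
    change = members.loc[mask, covariates]
    nochange = members.loc[~mask, covariates]
    values = {}
    for cov in covariates:
        if sd_reference is not None and cov in sd_reference.index:
            sd = float(sd_reference[cov])
        else:
            sd = float(change[cov].std(ddof=1)) if len(change) > 1 else 0.0
        scale = max(float(np.abs(change[cov]).max()), float(np.abs(nochange[cov]).max()), 1.0)
        if np.isnan(sd) or sd <= 1e-8 * scale:
            warnings.warn(f"covariate {cov!r} has zero SD in the change group; skipped")
            continue
        values[cov] = (float(change[cov].mean()) - float(nochange[cov].mean())) / sd
    series = pd.Series(values, dtype=float)
    summary = float(series.abs().max()) if len(series) else 0.0
    return series, summary


def change_group_sd(
    members: pd.DataFrame, change_mask: pd.Series | np.ndarray, covariates: list[str]
) -> pd.Series:
    """Per-covariate sample SD of the treatment-change group (reference SDs)."""
    mask = np.asarray(change_mask, bool)
    return members.loc[mask, covariates].std(ddof=1)


def _balance_profile(
    cohort: PrecisionCohort,
    dp_frame: pd.DataFrame,
    covariates: list[str],
    n_bins: int = 20,
) -> pd.DataFrame:
    """Cumulative balance by normalized-distance bin (balance-vs-size curve)."""
    nd = cohort.members["normalized_distance"].to_numpy()
    edges = np.linspace(0.0, max(float(nd.max()), 1e-9), n_bins + 1)[1:]
    all_change = dp_frame["transition"] != NO_CHANGE_OPTION
    sd_ref = change_group_sd(dp_frame, all_change, covariates) if all_change.any() else None
    rows = []
    for edge in edges:
        ids = cohort.members.loc[nd <= edge, "dp_id"]
        sub = dp_frame.loc[ids]
        change = sub["transition"] != NO_CHANGE_OPTION
        if change.sum() == 0 or (~change).sum() == 0:
            continue
        try:
            _, summary = covariate_balance(sub, change, covariates, sd_reference=sd_ref)
        except BalanceError:
            continue
        rows.append({"normalized_distance": float(edge), "n": len(sub), "balance": summary})
    return pd.DataFrame(rows, columns=["normalized_distance", "n", "balance"])


def apply_cutoff(
    cohort: PrecisionCohort,
    cutoff: float = 2.0,
    dp_frame: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
) -> PrecisionCohort:
    """Retain members with normalized distance strictly below the cutoff.

    When the DP frame and covariate list are given, the cumulative
    balance-by-distance profile is recomputed on the retained members.
    """
    kept = cohort.members[cohort.members["normalized_distance"] < cutoff].reset_index(drop=True)
    out = replace(cohort, members=kept, cutoff=cutoff)
    if not len(kept):
        warnings.warn("no members survive the normalized-distance cutoff")
    elif dp_frame is not None and covariates is not None:
        out.balance_profile = _balance_profile(out, dp_frame, covariates)
    return out


def insufficient_cohort(query_id: object, key: str, size: int, min_size: int) -> PrecisionCohort:
    """Structured result for a query whose filter cohort is too small."""
    return PrecisionCohort(
        query_id=query_id,
        filter_key=key,
        members=pd.DataFrame(columns=["dp_id", "raw_distance", "normalized_distance"]),
        status="insufficient data",
        notes=[f"filter cohort has {size} DPs (needs > {min_size})"],
    )
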
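import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from precohort.labels import new_regimen_of, render_label, transition_label
from precohort.outcomes import (
    BaselineMissingError,
    chi_square_vs_baseline,
    global_analysis,
    percent,
    sankey_export,
    summarize_options,
)


def _dps(option_counts):
    """DP frame from {option: (n_controlled, n_uncontrolled)}."""
    rows = []
    for option, (ctrl, unctrl) in option_counts.items():
        rows += [{"transition": option, "outcome": "controlled"}] * ctrl
        rows += [{"transition": option, "outcome": "uncontrolled"}] * unctrl
    return pd.DataFrame(rows)


class TestLabels:
    def test_regimen_rendering_sorted_and_joined(self):
        assert render_label({"metformin", "healthy lifestyle"}) == "healthy lifestyle_metformin"
        assert render_label(set()) == "no treatment"

    def test_transition_label_capitalized(self):
        label = transition_label("metformin", "no treatment")
        assert label == "Metformin_new+no treatment_stop"

    def test_no_change_sentinel(self):
        assert transition_label("no change", "metformin") == "No change"
        assert transition_label("metformin", "metformin") == "No change"

    def test_new_regimen_recovered_from_label(self):
        assert new_regimen_of("Healthy lifestyle_metformin_new+metformin_stop") == (
            "healthy lifestyle_metformin"
        )
        assert new_regimen_of("No change") == "no change"


class TestPercent:
    @pytest.mark.parametrize(
        ("num", "den", "expected"),
        [(2541, 5747, 44.21), (3839, 16480, 23.29), (605, 1324, 45.69), (1, 3, 33.33)],
    )
    def test_half_up_two_decimals(self, num, den, expected):
        assert percent(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestSummarizeOptions:
    def test_inclusion_threshold_scales_with_cohort_size(self):
        # 2000 DPs -> options need at least 20 DPs
        counts = {"No change": (900, 1065), "A_new+no treatment_stop": (20, 15)}
        frame = _dps(counts)
        assert len(frame) == 2000
        summaries = {s.option: s for s in summarize_options(frame)}
        assert summaries["A_new+no treatment_stop"].included

        counts["A_new+no treatment_stop"] = (10, 9)  # 19 DPs < 20
        summaries = {s.option: s for s in summarize_options(_dps(counts))}
        assert not summaries["A_new+no treatment_stop"].included

    def test_minimum_of_ten_applies_to_small_cohorts(self):
        counts = {"No change": (30, 30), "A_new+no treatment_stop": (6, 4)}
        summaries = {s.option: s for s in summarize_options(_dps(counts))}
        assert summaries["A_new+no treatment_stop"].included  # 10 >= max(10, ceil(1))

    def test_identical_proportions_give_zero_delta_not_significant(self):
        counts = {"No change": (50, 50), "A_new+no treatment_stop": (25, 25)}
        summaries = {s.option: s for s in summarize_options(_dps(counts))}
        s = summaries["A_new+no treatment_stop"]
        assert s.delta_vs_nochange == 0.0
        assert s.p_raw == pytest.approx(1.0)
        assert not s.significant

    def test_all_no_change_single_row_full_frequency(self):
        summaries = summarize_options(_dps({"No change": (10, 10)}))
        assert len(summaries) == 1
        assert summaries[0].pct_of_total == 100.0

    def test_missing_baseline_raises_with_summaries_attached(self):
        with pytest.raises(BaselineMissingError) as exc:
            summarize_options(_dps({"A_new+no treatment_stop": (5, 5)}))
        assert len(exc.value.summaries) == 1
        assert exc.value.summaries[0].delta_vs_nochange is None

    def test_counts_conserved_across_options(self):
        counts = {
            "No change": (30, 42),
            "A_new+no treatment_stop": (12, 8),
            "B_new+no treatment_stop": (3, 5),
        }
        frame = _dps(counts)
        summaries = summarize_options(frame)
        assert sum(s.n for s in summaries) == len(frame)
        for s in summaries:
            assert s.n_controlled + s.n_uncontrolled == s.n


class TestChiSquare:
    def test_matches_textbook_formula_on_published_counts(self):
        # 2x2 test of (210 controlled / 114 uncontrolled) vs (2541 / 3206)
        a, b, c, d = 210, 114, 2541, 3206
        n = a + b + c + d
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        expected_p = float(chi2_dist.sf(stat, df=1))
        got_p = chi_square_vs_baseline(a, b, c, d)
        assert got_p == pytest.approx(expected_p, abs=1e-10)
        # significant even against a Bonferroni family of 19 comparisons
        assert got_p < 0.05 / 19

    def test_degenerate_margin_returns_one(self):
        assert chi_square_vs_baseline(0, 0, 10, 10) == 1.0


class TestGlobalAnalysis:
    def test_hand_enumerated_counts_reproduced(self):
        counts = {
            "No change": (8, 12),
            "A_new+no treatment_stop": (5, 1),
            "B_new+no treatment_stop": (1, 3),
        }
        table = global_analysis(_dps(counts), top_k=None)
        assert list(table["option"])[0] == "No change"
        row = table.set_index("option").loc["A_new+no treatment_stop"]
        assert row["n"] == 6
        assert row["pct_controlled"] == percent(5, 6)

    def test_sorted_by_size_and_truncated(self):
        counts = {f"O{i}_new+no treatment_stop": (i, i) for i in range(1, 6)}
        counts["No change"] = (50, 50)
        table = global_analysis(_dps(counts), top_k=3)
        assert len(table) == 3
        assert list(table["n"]) == sorted(table["n"], reverse=True)


class TestSankey:
    def test_two_terminal_links_for_single_option(self):
        summaries = summarize_options(_dps({"No change": (10, 10)}))
        diagram = sankey_export(summaries, cohort_label="metformin")
        widths = [link["value"] for link in diagram["links"] if link["source"] != 0]
        assert widths == [10, 10]

    def test_no_change_link_label_carries_percentage(self):
        summaries = summarize_options(_dps({"No change": (605, 719)}))
        diagram = sankey_export(summaries)
        label = [l for l in diagram["links"] if l["source"] == 0][0]["label"]
        assert "45.69" in label
        assert [l for l in diagram["links"] if l["source"] == 0][0]["color"] == "gray"

    def test_terminal_inflow_conserves_included_dps(self):
        counts = {
            "No change": (30, 42),
            "A_new+no treatment_stop": (12, 8),
        }
        summaries = summarize_options(_dps(counts))
        diagram = sankey_export(summaries)
        into_terminals = sum(l["value"] for l in diagram["links"] if l["target"] in (1, 2))
        assert into_terminals == sum(s.n for s in summaries if s.included)

    def test_significant_better_option_colored_dark_green(self):
        counts = {"No change": (300, 700), "A_new+no treatment_stop": (200, 100)}
        summaries = summarize_options(_dps(counts))
        diagram = sankey_export(summaries)
        node = [n for n in diagram["nodes"] if n["label"] == "A_new+no treatment_stop"][0]
        assert node["color"] == "darkgreen"

    def test_empty_summaries_give_empty_diagram(self):
        diagram = sankey_export([])
        assert diagram["links"] == []


class TestBonferroniFamilyError:
    def test_familywise_error_controlled_under_null(self):
        """With every option at the same control probability, the corrected
        procedure should flag anything in at most ~alpha of replicates."""
        rng = np.random.default_rng(123)
        n_reps, any_sig = 500, 0
        for _ in range(n_reps):
            frame_parts = []
            for name, n in [("No change", 1000)] + [
                (f"O{i}_new+no treatment_stop", 300) for i in range(5)
            ]:
                ctrl = int(rng.binomial(n, 0.45))
                frame_parts.append(
                    pd.DataFrame(
                        {
                            "transition": [name] * n,
                            "outcome": ["controlled"] * ctrl + ["uncontrolled"] * (n - ctrl),
                        }
                    )
                )
            summaries = summarize_options(pd.concat(frame_parts, ignore_index=True))
            any_sig += any(s.significant for s in summaries)
        rate = any_sig / n_reps
        # 99% binomial envelope around alpha = 0.05 at 500 replicates
        assert rate <= 0.05 + 2.58 * math.sqrt(0.05 * 0.95 / n_reps)
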
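"""Group-level analysis pipeline on synthetic trial tables."""

import numpy as np
import pandas as pd
import pytest

from chronopop.analysis import (
    analyze_trials,
    count_stronger_effect,
    exclusion_reanalysis,
    load_trials,
    one_sample_t_test,
    paired_t_test,
    pearson_correlation,
    summarize_conditions,
)
from chronopop.synthetic import (
    default_population_spec,
    sample_population,
    simulate_trials,
)


@pytest.fixture(scope="module")
def small_trials():
    """Six synthetic participants at the default group statistics."""
    spec = default_population_spec(n_participants=6)
    return simulate_trials(sample_population(spec, seed=31), seed=32)


@pytest.fixture(scope="module")
def contaminated_trials():
    """Ten participants with the three planted baseline-600 overestimators."""
    spec = default_population_spec(n_participants=10, n_outliers=3)
    return simulate_trials(sample_population(spec, seed=41), seed=42)


class TestLoadTrials:
    def test_canonical_roundtrip(self, tmp_path, small_trials):
        path = tmp_path / "trials.csv"
        small_trials.to_csv(path, index=False)
        loaded = load_trials(path)
        pd.testing.assert_frame_equal(
            loaded.reset_index(drop=True), small_trials, check_dtype=False
        )

    def test_ms_valued_comparisons_are_converted(self, tmp_path):
        path = tmp_path / "ms.csv"
        pd.DataFrame(
            {
                "participant": ["P1"] * 2,
                "condition": ["baseline"] * 2,
                "standard_ms": [600, 600],
                "comparison_pct": [400.0, 1000.0],  # actually milliseconds
                "response": [0, 1],
                "rep": [0, 0],
            }
        ).to_csv(path, index=False)
        loaded = load_trials(path)
        np.testing.assert_allclose(
            sorted(loaded["comparison_pct"]), [-33.3333, 66.6667], atol=1e-3
        )

    def test_column_map_adapts_foreign_layout(self, tmp_path):
        path = tmp_path / "foreign.csv"
        pd.DataFrame(
            {
                "subj": ["a", "a"],
                "cond": ["baseline", "adaptation"],
                "std": [600, 600],
                "cmp": [-33.33, 16.67],
                "resp": [0, 1],
            }
        ).to_csv(path, index=False)
        loaded = load_trials(
            path,
            column_map={
                "subj": "participant",
                "cond": "condition",
                "std": "standard_ms",
                "cmp": "comparison_pct",
                "resp": "response",
            },
        )
        assert list(loaded.columns) == [
            "participant", "condition", "standard_ms", "comparison_pct",
            "response", "rep",
        ]

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("participant,condition,standard_ms,comparison_pct,response,rep\n")
        with pytest.raises(ValueError, match="no trial rows"):
            load_trials(path)

    def test_bad_rows_reported_with_line_numbers(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant,condition,standard_ms,comparison_pct,response,rep\n"
            "P1,baseline,600,0,1,0\n"
            "P1,warmup,600,0,1,1\n"
            "P1,baseline,600,0,2,2\n"
        )
        with pytest.raises(ValueError) as err:
            load_trials(path)
        assert "line 3" in str(err.value) and "warmup" in str(err.value)
        assert "line 4" in str(err.value)


class TestSummaries:
    def test_self_consistency_of_effects(self, small_trials):
        res = summarize_conditions(small_trials)
        for std in (600.0, 1200.0):
            mean_diff = (
                res.summaries[("adaptation", std)].mean_pse
                - res.summaries[("baseline", std)].mean_pse
            )
            assert res.effects[f"effect_{std:g}"].mean() == pytest.approx(mean_diff)

    def test_sem_formula(self, small_trials):
        s = summarize_conditions(small_trials).summaries[("baseline", 600.0)]
        assert s.sem_pse == pytest.approx(np.std(s.pses, ddof=1) / np.sqrt(s.n))

    def test_duplicated_participant_data_gives_zero_sem(self, small_trials):
        one = small_trials[small_trials.participant == "P01"]
        twin = one.assign(participant="P99")
        res = summarize_conditions(pd.concat([one, twin], ignore_index=True))
        assert res.summaries[("baseline", 600.0)].sem_pse == pytest.approx(0.0)

    def test_compression_is_negative_effect(self, small_trials):
        """Adaptation PSEs sit below baseline: effects come out negative."""
        res = summarize_conditions(small_trials)
        assert res.effects["effect_600"].mean() < 0


class TestStatistics:
    def test_paired_t_identical_vectors(self):
        assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[0] == 0.0

    def test_paired_t_hand_computed(self):
        t, df, p = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2
        assert 0 < p < 1

    def test_paired_t_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_one_sample_t(self):
        t, df, p = one_sample_t_test([1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2

    def test_pearson_perfect_lines(self):
        x = np.arange(5.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_pearson_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestExclusionReanalysis:
    def test_planted_outliers_are_the_ones_excluded(self, contaminated_trials):
        _, excluded = exclusion_reanalysis(contaminated_trials, k=3)
        # the three planted extreme overestimators are ranked on top
        assert set(excluded["participant"]) == {"P01", "P02", "P03"}

    def test_exclusion_lowers_baseline_mean(self, contaminated_trials):
        full = summarize_conditions(contaminated_trials)
        reduced, _ = exclusion_reanalysis(contaminated_trials, k=3)
        assert (
            reduced.summaries[("baseline", 600.0)].mean_pse
            < full.summaries[("baseline", 600.0)].mean_pse
        )

    def test_k_zero_is_identity(self, small_trials):
        full = summarize_conditions(small_trials)
        same, excluded = exclusion_reanalysis(small_trials, k=0)
        assert excluded.empty
        pd.testing.assert_frame_equal(same.effects, full.effects)

    def test_tie_at_boundary_is_refused(self, small_trials):
        # duplicate the highest-PSE participant so ranks 1 and 2 tie exactly
        base600 = summarize_conditions(small_trials).summaries[("baseline", 600.0)]
        top = base600.participants[int(np.argmax(base600.pses))]
        twin = small_trials[small_trials.participant == top].assign(participant="TWIN")
        tied = pd.concat([small_trials, twin], ignore_index=True)
        with pytest.raises(ValueError, match="tie"):
            exclusion_reanalysis(tied, k=1)


class TestCountStrongerEffect:
    def test_toy_table(self):
        eff = pd.DataFrame(
            {"effect_600": [-10.0, -1.0], "effect_1200": [-5.0, -4.0]}
        )
        assert count_stronger_effect(eff) == (1, 2)

    def test_equal_effects_count_zero(self):
        eff = pd.DataFrame({"effect_600": [-5.0] * 4, "effect_1200": [-5.0] * 4})
        assert count_stronger_effect(eff) == (0, 4)

    def test_missing_cells_skipped(self):
        eff = pd.DataFrame(
            {"effect_600": [-10.0, np.nan], "effect_1200": [-5.0, -4.0]}
        )
        assert count_stronger_effect(eff) == (1, 1)


class TestFullBattery:
    def test_analyze_trials_reports_everything(self, small_trials):
        out = analyze_trials(small_trials, exclusion_k=2)
        assert {"result", "paired_t_effects", "stronger_at_600",
                "baseline_600_vs_zero", "baseline_600_pse_jnd_r",
                "exclusion"} <= set(out)
        assert out["paired_t_effects"]["df"] == 5
        assert 0 <= out["stronger_at_600"]["count"] <= 6

    def test_pipeline_deterministic(self, small_trials):
        a = analyze_trials(small_trials)["result"].summary_frame()
        b = analyze_trials(small_trials)["result"].summary_frame()
        pd.testing.assert_frame_equal(a, b)
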
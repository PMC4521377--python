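"""Trace statistics: QC, feature formulas, classification, summaries, quadrants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skars.synth import CohortSpec, generate_cohort, simulate_cohort_traces, spec_with
from skars.traces import (
    InsufficientDataError,
    QCConfig,
    basal_level,
    classify,
    classify_table,
    compute_features,
    derive_threshold,
    marker_quadrants,
    population_summary,
    qc_filter,
    response_features,
    sort_for_heatmap,
)


def _tidy(cell_id, times, ratios, **extra):
    return pd.DataFrame({"cell_id": cell_id, "time_min": times, "ratio": ratios, **extra})


class TestQCFilter:
    def test_constant_feature_trace_kept(self):
        df = _tidy(0, range(10), np.full(10, 3.0), nucleus_area=50, cell_area=300,
                   full_length=True)
        kept, log = qc_filter(df, QCConfig())
        assert kept.cell_id.nunique() == 1 and log.empty

    def test_partial_track_rejected_with_reason(self):
        df = _tidy(0, range(10), np.full(10, 3.0), full_length=False)
        kept, log = qc_filter(df, QCConfig())
        assert kept.empty
        assert log.reason.iloc[0] == "not full length"

    def test_high_area_variability_rejected(self):
        areas = np.where(np.arange(10) % 2 == 0, 20, 80)  # CV ~ 0.6
        df = _tidy(0, range(10), np.full(10, 3.0), nucleus_area=areas, full_length=True)
        kept, log = qc_filter(df, QCConfig(max_cv_nucleus_area=0.2))
        assert kept.empty
        assert log.reason.iloc[0] == "nucleus area variability"
        assert log.cv.iloc[0] == pytest.approx(np.std(areas) / np.mean(areas))


class TestFeatureFormulas:
    def test_basal_level_is_mean_of_first_three(self):
        assert basal_level([3.0, 3.2, 3.1, 2.0, 1.0]) == pytest.approx(3.1)
        assert basal_level([1.0, 1.0, 1.0]) == 1.0
        with pytest.raises(InsufficientDataError):
            basal_level([3.0, 3.1])

    def test_final_response_from_last_three_normalized_points(self):
        # basal 1.0; last three normalized points 0.6 -> FR 0.4
        ratios = [1.0, 1.0, 1.0, 0.8, 0.6, 0.6, 0.6]
        times = [0, 1, 2, 3, 4, 5, 6]
        _, fr = response_features(times, ratios, stim_time=0.0)
        assert fr == pytest.approx(0.4)

    def test_flat_trace_has_zero_responses(self):
        times = np.arange(10.0)
        ir, fr = response_features(times, np.full(10, 2.5), stim_time=2.0)
        assert ir == pytest.approx(0.0) and fr == pytest.approx(0.0)

    def test_initial_response_window_points(self):
        # normalized points at 3, 4, 5 min post-stimulus average 0.8 -> IR 0.2
        times = [-2.0, -1.0, 0.0, 3.0, 4.0, 5.0, 8.0]
        ratios = [1.0, 1.0, 1.0, 0.9, 0.8, 0.7, 0.1]
        ir, _ = response_features(times, ratios, stim_time=0.0)
        assert ir == pytest.approx(0.2)

    def test_missing_window_points_error_names_window(self):
        with pytest.raises(InsufficientDataError, match="initial-response"):
            response_features([0.0, 1.0, 2.0, 3.0], [1, 1, 1, 1], stim_time=3.0)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_features_invariant_to_common_intensity_scaling(self, scale):
        """Scaling nuclear and cytoplasmic intensities together leaves
        the ratio, normalized trace, IR, FR and class unchanged."""
        times = np.arange(12.0)
        ratios = np.array([3, 3, 3, 2.5, 2.2, 2, 1.9, 1.8, 1.8, 1.8, 1.8, 1.8])
        nuc, cyt = ratios * 7.0, np.full(12, 7.0)
        base = response_features(times, nuc / cyt, stim_time=2.0)
        scaled = response_features(times, (nuc * scale) / (cyt * scale), stim_time=2.0)
        assert scaled[0] == pytest.approx(base[0], rel=1e-9)
        assert scaled[1] == pytest.approx(base[1], rel=1e-9)
        assert classify(*scaled, theta=0.2) == classify(*base, theta=0.2)


class TestThreshold:
    def test_gaussian_control_matches_quantile_oracle(self):
        rng = np.random.default_rng(42)
        fr = rng.normal(0.0, 0.05, size=1000)
        theta = derive_threshold(fr, q=95)
        assert theta == pytest.approx(1.645 * 0.05, abs=0.01)

    def test_all_zero_controls_give_zero_threshold(self):
        assert derive_threshold(np.zeros(50)) == 0.0

    def test_too_few_controls_recommend_fixed_mode(self):
        with pytest.raises(InsufficientDataError, match="fixed-threshold"):
            derive_threshold(np.zeros(10))


class TestClassify:
    @pytest.mark.parametrize(
        "ir,fr,expected",
        [
            (0.3, 0.35, "responding"),  # 0.35 <= 1.5 * 0.3
            (0.1, 0.3, "slow"),  # 0.3 > 0.15
            (0.4, 0.1, "non_responding"),
            (0.2, 0.2, "responding"),  # FR == theta boundary
            (0.2, 0.3, "responding"),  # FR == 1.5 * IR boundary exactly
            (-0.1, 0.25, "slow"),  # negative IR: late response
        ],
    )
    def test_rule_evaluation(self, ir, fr, expected):
        assert classify(ir, fr, theta=0.2) == expected

    def test_rejects_non_finite_features(self):
        with pytest.raises(ValueError):
            classify(np.nan, 0.3, 0.2)


class TestPopulationSummary:
    def test_identical_traces_collapse_to_one_curve(self):
        df = pd.concat([_tidy(i, range(5), np.full(5, 2.0)) for i in range(4)])
        out = population_summary(df)
        assert np.allclose(out["median"], 2.0)
        assert np.allclose(out.p25, 2.0) and np.allclose(out.p75, 2.0)

    def test_constant_traces_match_order_statistic_oracle(self):
        df = pd.concat(
            [_tidy(i, range(4), np.full(4, v)) for i, v in enumerate((1.0, 2.0, 3.0))]
        )
        out = population_summary(df)
        assert np.allclose(out["median"], 2.0)
        assert np.allclose(out.p25, 1.5) and np.allclose(out.p75, 2.5)

    def test_quartiles_bracket_median(self):
        rng = np.random.default_rng(3)
        df = pd.concat(
            [_tidy(i, range(6), rng.uniform(1, 4, size=6)) for i in range(9)]
        )
        out = population_summary(df)
        assert (out.p25 <= out["median"] + 1e-12).all()
        assert (out["median"] <= out.p75 + 1e-12).all()

    def test_misaligned_time_grids_raise(self):
        df = pd.concat([_tidy(0, [0, 1, 2], [1, 1, 1]), _tidy(1, [0, 1, 3], [1, 1, 1])])
        with pytest.raises(ValueError, match="time grid"):
            population_summary(df)


class TestSortForHeatmap:
    def _features(self, rows):
        df = pd.DataFrame(rows, columns=["cell_id", "initial_response", "final_response"])
        df["basal"] = 3.0
        df["marker_enrichment"] = np.nan
        return df

    def test_descending_final_response_within_class(self):
        feats = classify_table(
            self._features([(0, 0.4, 0.5), (1, 0.1, 0.1), (2, 0.25, 0.3)]), theta=0.2
        )
        ordered, _ = sort_for_heatmap(feats)
        assert ordered.cell_id.tolist() == [0, 2, 1]

    def test_equal_final_responses_stable_by_id(self):
        feats = classify_table(
            self._features([(5, 0.3, 0.4), (2, 0.3, 0.4), (9, 0.3, 0.4)]), theta=0.2
        )
        ordered, _ = sort_for_heatmap(feats)
        assert ordered.cell_id.tolist() == [2, 5, 9]

    def test_class_blocks_group_non_responders_last(self):
        feats = classify_table(
            self._features(
                [(0, 0.1, 0.05), (1, 0.4, 0.5), (2, 0.05, 0.3), (3, 0.3, 0.35)]
            ),
            theta=0.2,
        )
        ordered, offsets = sort_for_heatmap(feats)
        assert ordered.cls.tolist() == ["responding", "responding", "slow", "non_responding"]
        assert offsets == {"responding": 0, "slow": 2, "non_responding": 3}


class TestMarkerQuadrants:
    def _features(self):
        return pd.DataFrame(
            {
                "cell_id": [0, 1, 2, 3],
                "basal": 3.0,
                "initial_response": [0.3, 0.3, 0.0, 0.0],
                "final_response": [0.4, 0.4, 0.05, 0.05],
                "marker_enrichment": [200.0, -5.0, 200.0, 0.0],
            }
        )

    def test_enrichment_sign_sets_marker_state(self):
        feats, counts, _ = marker_quadrants(self._features(), theta=0.2, tau_m=0.0)
        assert feats.marker_state.tolist() == ["nuclear", "cytoplasmic", "nuclear", "cytoplasmic"]
        assert feats.quadrant.tolist() == [
            "marker+/responding",
            "marker-/responding",
            "marker+/non_responding",
            "marker-/non_responding",  # E == tau_m is marker-negative (strict >)
        ]
        assert counts.n_cells.sum() == 4

    def test_otsu_threshold_recovers_planted_marker_states(self, params):
        spec = spec_with(CohortSpec(), n_cells=120, seed=31)
        truth = generate_cohort(spec)
        traces = simulate_cohort_traces(truth, params)
        feats = compute_features(traces, stim_time=spec.stim_time)
        feats = classify_table(feats, theta=0.2)
        quads, _, _ = marker_quadrants(feats, theta=0.2, tau_m="otsu")
        merged = quads.merge(truth.cells[["cell_id", "marker_nuclear"]], on="cell_id")
        agree = (merged.marker_state == "nuclear") == merged.marker_nuclear
        assert agree.mean() >= 0.95

    def test_missing_marker_errors(self):
        feats = self._features().assign(marker_enrichment=np.nan)
        with pytest.raises(ValueError, match="marker"):
            marker_quadrants(feats, theta=0.2)


class TestClassificationRecovery:
    def test_default_cohort_recovers_planted_fractions(self, params):
        spec = spec_with(CohortSpec(), n_cells=300, seed=1)
        truth = generate_cohort(spec)
        traces = simulate_cohort_traces(truth, params)
        feats = classify_table(compute_features(traces, spec.stim_time), theta=0.2)
        merged = feats.merge(truth.cells[["cell_id", "cls"]], on="cell_id",
                             suffixes=("", "_planted"))
        assert (merged.cls == merged.cls_planted).mean() >= 0.97
        for cls, frac in spec.class_fractions.items():
            n = (feats.cls == cls).sum()
            sigma = np.sqrt(300 * frac * (1 - frac))
            assert abs(n - 300 * frac) <= 3 * sigma + 1
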
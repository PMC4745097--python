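import numpy as np
import pytest
from scipy import stats as sps

from widecal import (
    AnalysisParams,
    SimParams,
    TrialTable,
    align_trials,
    classify_all,
    classify_modulation,
    latency_to_peak,
    make_ground_truth,
    render_traces,
    summarize_population,
    window_auc,
)
from widecal.synth import kernel_peak_time, transient_kernel
from widecal.taskstats import paired_t_pvalue
from widecal.traces import normalize_traces

FS = 20.0


def trials_at(onsets):
    return TrialTable(np.asarray(onsets, float),
                      np.array(["correct"] * len(onsets), dtype=object))


class TestAlignTrials:
    def test_constant_trace_gives_constant_matrix(self):
        trace = np.full(400, 3.0)
        m, idx = align_trials(trace, trials_at([5.0, 10.0]), (-2, 2), FS)
        assert m.shape == (2, 80)
        np.testing.assert_array_equal(m, 3.0)
        assert idx.tolist() == [0, 1]

    def test_delta_lands_in_expected_column(self):
        trace = np.zeros(600)
        onsets = [5.0, 12.0, 20.0]
        for tone in onsets:
            trace[int((tone + 1.0) * FS)] = 7.0
        m, _ = align_trials(trace, trials_at(onsets), (-2, 2), FS)
        col = int((1.0 - (-2.0)) * FS)
        assert np.all(m[:, col] == 7.0)
        m[:, col] = 0
        assert not m.any()

    def test_matches_index_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 1, 500)
        onsets = [4.0, 11.3, 19.75]
        m, _ = align_trials(trace, trials_at(onsets), (-1, 3), FS)
        for row, tone in zip(m, onsets):
            start = int(np.floor((tone - 1.0) * FS + 1e-9))
            np.testing.assert_array_equal(row, trace[start : start + 80])

    def test_truncated_trial_excluded_with_warning(self):
        trace = np.zeros(100)  # 5 s of trace
        with pytest.warns(UserWarning, match="truncated"):
            m, idx = align_trials(trace, trials_at([2.0, 4.5]), (-2, 2), FS)
        assert m.shape[0] == 1
        assert idx.tolist() == [0]


class TestWindowAuc:
    def test_constant_one_over_two_seconds(self):
        row = np.ones(80)  # [-2, 2) at 20 Hz
        assert window_auc(row, (0, 2), (-2, 2), FS) == pytest.approx(2.0)

    def test_zeros(self):
        assert window_auc(np.zeros(80), (-2, 0), (-2, 2), FS) == 0.0

    def test_close_to_trapezoid_on_smooth_input(self):
        t = np.arange(-2, 2, 1 / FS)
        row = np.sin(t) + 2
        rect = window_auc(row, (0, 2), (-2, 2), FS)
        trapz = np.trapezoid(row[40:], dx=1 / FS)
        assert abs(rect - trapz) <= np.abs(row).max() / FS


class TestClassifyModulation:
    def test_hand_computed_t_statistic(self):
        # baseline AUCs [1,2,3] vs task [3,5,4]: diffs mean 2, SD 1, n 3
        aligned = np.zeros((3, 80))
        for i, (b, t) in enumerate(zip([1, 2, 3], [3, 5, 4])):
            aligned[i, :40] = b / 2.0  # constant level over the 2 s window
            aligned[i, 40:] = t / 2.0
        res = classify_modulation(aligned, [0, 1, 2], AnalysisParams(), FS, (-2, 2))
        assert res.t_stat == pytest.approx(3.464, abs=1e-3)
        assert res.p_value == pytest.approx(0.0742, abs=2e-3)
        assert res.label == "none"  # p > 0.05 with only 3 trials

    def test_identical_windows_give_none(self):
        rng = np.random.default_rng(1)
        aligned = np.tile(rng.normal(0, 1, 40), (4, 2))
        res = classify_modulation(aligned, [0, 1, 2, 3], AnalysisParams(), FS, (-2, 2))
        assert res.label == "none"
        assert res.p_value == 1.0

    def test_matches_scipy_reference_to_1e10(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.integers(3, 12)
            b = rng.normal(0, 1, n)
            t = rng.normal(0.3, 1, n)
            t_stat, p, _ = paired_t_pvalue(t - b)
            ref = sps.ttest_rel(t, b)
            assert t_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_label_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(3)
        aligned = rng.normal(0, 1, (10, 80))
        aligned[:, 40:] += 1.0
        a = classify_modulation(aligned, range(10), AnalysisParams(), FS, (-2, 2))
        b = classify_modulation(aligned * 37.0, range(10), AnalysisParams(), FS, (-2, 2))
        assert a.label == b.label == "positive"
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_zero_variance_nonzero_difference_flagged_significant(self):
        aligned = np.zeros((3, 80))
        aligned[:, 40:] = 1.0  # identical nonzero difference on every trial
        res = classify_modulation(aligned, [0, 1, 2], AnalysisParams(), FS, (-2, 2))
        assert res.exact_difference
        assert res.label == "positive"


class TestLatencyToPeak:
    def test_single_peak_location(self):
        aligned = np.zeros((3, 200))  # [-2, 8) at 20 Hz
        aligned[:, 40 + 24] = 1.0  # +1.2 s
        res = latency_to_peak(aligned, [0, 1, 2], AnalysisParams(), FS, (-2, 8))
        assert res.latency_s == pytest.approx(1.2)

    def test_tie_takes_first_occurrence(self):
        aligned = np.zeros((2, 200))
        aligned[:, 40 + 10] = 5.0  # +0.5 s
        aligned[:, 40 + 60] = 5.0  # +3.0 s
        res = latency_to_peak(aligned, [0, 1], AnalysisParams(), FS, (-2, 8))
        assert res.latency_s == pytest.approx(0.5)

    def test_planted_kernel_latency_matches_argmax(self):
        t = np.arange(-2, 8, 1 / FS)
        onset = 0.1
        row = transient_kernel(t - onset, 0.045, 0.40)
        aligned = np.tile(row, (5, 1))
        res = latency_to_peak(aligned, range(5), AnalysisParams(), FS, (-2, 8))
        expected = onset + kernel_peak_time(0.045, 0.40)
        assert 0.1 <= res.latency_s <= 0.6
        assert res.latency_s == pytest.approx(expected, abs=1 / FS)


class TestSummarizePopulation:
    def test_published_table_percentages(self):
        labels = ["positive"] * 81 + ["negative"] * 102 + ["none"] * 239
        out = summarize_population(labels)
        assert out["positive"]["percent"] == 19.19
        assert out["negative"]["percent"] == 24.17
        labels = ["positive"] * 216 + ["negative"] * 374 + ["none"] * 496
        out = summarize_population(labels)
        assert out["positive"]["percent"] == 19.89
        assert out["negative"]["percent"] == 34.44

    def test_zero_counts(self):
        out = summarize_population(["none", "none"])
        assert out["positive"] == {"count": 0, "percent": 0.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_population([])


class TestPlantedModulationRecovery:
    def test_labels_recovered_for_most_cells(self):
        # 40-cell session at full 40-trial length, trace-level rendering
        params = SimParams(
            frame_height=512, frame_width=512, n_frames=10, n_cells=40,
            n_trials=40, n_correct=33, seed=21,
        )
        gt = make_ground_truth(params)
        tm = normalize_traces(render_traces(gt, params))
        trials = gt.trial_schedule.with_outcomes(gt.trial_outcomes)
        results = classify_all(tm.dff, trials, AnalysisParams(), FS)
        labels = np.array([r.label for r in results])
        agree = (labels == gt.modulation_label).mean()
        assert agree >= 0.85

    def test_null_simulation_calibrated_at_alpha(self):
        # i.i.d. noise traces: the task-relevant fraction must sit at alpha
        rng = np.random.default_rng(22)
        n_rois, n_trials = 1200, 33
        flagged = 0
        aligned_w = (-2.0, 2.0)
        for _ in range(n_rois):
            aligned = rng.normal(0, 1, (n_trials, 80))
            res = classify_modulation(aligned, range(n_trials), AnalysisParams(), FS, aligned_w)
            flagged += res.label != "none"
        frac = flagged / n_rois
        ci = 3 * np.sqrt(0.05 * 0.95 / n_rois)
        assert abs(frac - 0.05) <= ci
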
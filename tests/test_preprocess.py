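import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirsfda import (
    NIRSRecording,
    QCThresholds,
    SimulationParams,
    TSISeries,
    align_window,
    compute_tsi,
    preprocess_cohort,
    qc_evaluate,
    simulate_cohort,
)
from nirsfda.preprocess import InsufficientSpanError, qc_summary


def make_recording(fs=50.0, t0=-100.0, t1=250.0, onset=0.0, tsi_level=70.0,
                   total_hb=30.0, fit_factor=99.0, subject_id="A"):
    """Recording with constant TSI plus a small dip so QC flat rule passes."""
    n = int(round((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    tsi = np.full(n, tsi_level)
    dip = (t > onset + 5) & (t < onset + 25)
    tsi[dip] -= 2.0
    hbo2 = tsi / 100 * total_hb
    return NIRSRecording(
        subject_id=subject_id, time=t, hbo2=hbo2, hhb=total_hb - hbo2,
        fit_factor=fit_factor, stand_onset=onset,
    )


class TestComputeTSI:
    @pytest.mark.parametrize(
        "hbo2, hhb, expected", [(1.0, 1.0, 50.0), (3.0, 1.0, 75.0), (0.3, 0.1, 75.0)]
    )
    def test_values(self, hbo2, hhb, expected):
        assert compute_tsi(np.array([hbo2]), np.array([hhb]))[0] == pytest.approx(expected)

    def test_zero_denominator_flagged_not_dropped(self):
        tsi = compute_tsi(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isnan(tsi[0]) and tsi[1] == 50.0
        assert tsi.size == 2

    def test_bounded_for_nonnegative_inputs(self):
        rng = np.random.default_rng(0)
        hbo2 = rng.uniform(0, 50, 1000)
        hhb = rng.uniform(1e-6, 50, 1000)
        tsi = compute_tsi(hbo2, hhb)
        assert np.all((tsi >= 0) & (tsi <= 100))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_tsi(np.zeros(3), np.zeros(4))

    @settings(deadline=None, derandomize=True)
    @given(
        hbo2=arrays(float, 20, elements=st.floats(0.0, 100.0)),
        hhb=arrays(float, 20, elements=st.floats(0.01, 100.0)),
        scale=st.floats(0.01, 100.0),
    )
    def test_bounded_and_scale_invariant(self, hbo2, hhb, scale):
        # TSI is a fraction: bounded in [0, 100] and invariant to rescaling
        # both chromophores by the same positive factor
        tsi = compute_tsi(hbo2, hhb)
        assert np.all((tsi >= 0) & (tsi <= 100))
        np.testing.assert_allclose(
            compute_tsi(scale * hbo2, scale * hhb), tsi, rtol=1e-9
        )


class TestAlignWindow:
    def test_window_length_and_endpoints_at_50hz(self):
        series = align_window(make_recording())
        assert series.n_samples == 12001
        assert series.grid[0] == pytest.approx(-60.0)
        assert series.grid[-1] == pytest.approx(180.0)

    def test_nonzero_onset_shifts_grid(self):
        rec = make_recording(t0=0.0, t1=400.0, onset=150.0)
        series = align_window(rec)
        assert series.grid[0] == pytest.approx(-60.0)
        # value at t=0 must equal the recording's value at the onset sample
        i_onset = int(round(150.0 * 50))
        i_zero = int(round(60.0 * 50))
        tsi = compute_tsi(rec.hbo2, rec.hhb)
        assert series.values[i_zero] == tsi[i_onset]

    def test_insufficient_span_names_missing_interval(self):
        rec = make_recording(t0=-100.0, t1=100.0)  # ends 100 s after stand
        with pytest.raises(InsufficientSpanError, match=r"180"):
            align_window(rec)

    def test_idempotent_on_aligned_input(self):
        first = align_window(make_recording(fs=10.0))
        rec2 = NIRSRecording(
            subject_id="A", time=first.grid, tsi=first.values, stand_onset=0.0
        )
        second = align_window(rec2)
        np.testing.assert_array_equal(second.values, first.values)
        np.testing.assert_allclose(second.grid, first.grid)


def aligned(values, fs=10.0, subject_id="A"):
    n = int(round(240 * fs)) + 1
    grid = -60.0 + np.arange(n) / fs
    return TSISeries(subject_id=subject_id, grid=grid, values=values, sampling_rate=fs), grid


class TestQCRules:
    def test_clean_default_simulated_subject_passes(self):
        (s,) = simulate_cohort(SimulationParams(n_subjects=1, seed=1))
        rep = qc_evaluate(s.curve)
        assert rep.passed and rep.reasons == []

    def test_tsi_below_10(self):
        series, grid = aligned(np.full(2401, 70.0))
        series.values[1200] = 9.5
        rep = qc_evaluate(series)
        assert "TSI_BELOW_10" in rep.reasons
        assert rep.metrics["min_tsi"] == pytest.approx(9.5)

    def test_chromophore_near_zero_over_quarter(self):
        rec = make_recording(fs=10.0)
        tsi = compute_tsi(rec.hbo2, rec.hhb)
        # push 30% of window samples of HbO2 under 0.1 uM
        n = rec.time.size
        rec.hbo2[: int(0.5 * n)] = 0.05
        series = align_window(rec, tsi)
        rep = qc_evaluate(series, rec)
        assert "CHROMOPHORE_NEAR_ZERO" in rep.reasons
        assert rep.metrics["chromophore_near_zero_frac"] > 0.25

    def test_undefined_tsi_sample_fails_qc(self):
        series, _ = aligned(np.full(2401, 70.0))
        series.values[100] = np.nan
        rep = qc_evaluate(series)
        assert "CHROMOPHORE_NEAR_ZERO" in rep.reasons

    def test_tsi_range_over_45(self):
        series, grid = aligned(np.full(2401, 70.0))
        series.values[grid > 10] = 20.0  # 50-point swing
        rep = qc_evaluate(series)
        assert "TSI_RANGE_OVER_45" in rep.reasons

    def test_flatline_first_30s(self):
        series, _ = aligned(np.full(2401, 70.0))
        rep = qc_evaluate(series)
        assert "FLAT_FIRST_30S" in rep.reasons
        assert rep.metrics["first30_range"] == pytest.approx(0.0)

    def test_baseline_variation_over_10(self):
        series, grid = aligned(np.full(2401, 70.0))
        series.values[(grid > -30) & (grid < -20)] = 58.0
        series.values[grid > 2] = 68.0  # keep the post-stand response non-flat
        rep = qc_evaluate(series)
        assert "BASELINE_VARIATION_OVER_10" in rep.reasons
        assert rep.metrics["baseline_range"] == pytest.approx(12.0)

    def test_fit_factor_below_98(self):
        rec = make_recording(fit_factor=97.0)
        rep = qc_evaluate(align_window(rec), rec)
        assert rep.reasons == ["FIT_FACTOR_BELOW_98"]
        assert rep.metrics["fit_factor_mean"] == pytest.approx(97.0)

    def test_fit_factor_accepts_per_sample_channel(self):
        rec = make_recording()
        rec.fit_factor = np.full(rec.time.size, 96.5)
        rep = qc_evaluate(align_window(rec), rec)
        assert "FIT_FACTOR_BELOW_98" in rep.reasons

    def test_missing_stand_marker(self):
        rec = make_recording()
        series = align_window(rec)
        rec.stand_onset = None
        rep = qc_evaluate(series, rec)
        assert "MISSING_STAND_MARKER" in rep.reasons

    def test_all_violations_reported_not_just_first(self):
        series, grid = aligned(np.full(2401, 70.0))
        series.values[1200] = 9.0  # also breaks min-TSI and the 45-range rule
        rep = qc_evaluate(series)
        assert {"TSI_BELOW_10", "TSI_RANGE_OVER_45", "FLAT_FIRST_30S"} <= set(rep.reasons)

    def test_passed_iff_no_reasons(self):
        (s,) = simulate_cohort(SimulationParams(n_subjects=1, seed=1, sampling_rate=10.0))
        good = qc_evaluate(s.curve)
        assert good.passed == (len(good.reasons) == 0)
        bad, _ = aligned(np.full(2401, 5.0))
        rep = qc_evaluate(bad)
        assert (not rep.passed) and rep.reasons

    def test_every_reason_has_backing_metric(self):
        series, _ = aligned(np.full(2401, 70.0))
        series.values[0] = 9.0
        rep = qc_evaluate(series)
        backing = {
            "TSI_BELOW_10": "min_tsi",
            "TSI_RANGE_OVER_45": "tsi_range",
            "FLAT_FIRST_30S": "first30_range",
            "BASELINE_VARIATION_OVER_10": "baseline_range",
            "CHROMOPHORE_NEAR_ZERO": "chromophore_near_zero_frac",
            "FIT_FACTOR_BELOW_98": "fit_factor_mean",
            "MISSING_STAND_MARKER": "has_stand_marker",
        }
        for reason in rep.reasons:
            assert backing[reason] in rep.metrics

    def test_relative_threshold_switch(self):
        series, grid = aligned(np.full(2401, 70.0))
        series.values[grid > 10] = 36.0  # 34-point swing: ok absolute, >45% of baseline
        assert "TSI_RANGE_OVER_45" not in qc_evaluate(series).reasons
        rep = qc_evaluate(series, thresholds=QCThresholds(relative=True))
        assert "TSI_RANGE_OVER_45" in rep.reasons


class TestBatch:
    def _mixed_batch(self):
        recs = [make_recording(subject_id=f"C{i}") for i in range(5)]
        bad1 = make_recording(subject_id="BAD_FF", fit_factor=90.0)
        bad2 = make_recording(subject_id="BAD_MARKER")
        bad2.stand_onset = None
        return recs + [bad1, bad2]

    def test_counts_partition(self):
        series, reports = preprocess_cohort(self._mixed_batch())
        assert len(series) == 5
        assert len(reports) == 7
        assert sum(r.passed for r in reports) + sum(not r.passed for r in reports) == 7

    def test_empty_pass_batch(self):
        recs = [make_recording(subject_id=f"B{i}", fit_factor=90.0) for i in range(3)]
        series, reports = preprocess_cohort(recs)
        assert series == [] and len(reports) == 3

    def test_summary_counts(self):
        _, reports = preprocess_cohort(self._mixed_batch())
        summary = qc_summary(reports).set_index("reason")["count"]
        assert summary["PASSED"] == 5
        assert summary["FIT_FACTOR_BELOW_98"] == 1
        assert summary["MISSING_STAND_MARKER"] == 1

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            preprocess_cohort([])
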
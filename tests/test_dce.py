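"""Landmark detection and the SI ratio statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placentaq import dce
from placentaq.errors import (
    DataError,
    NoFirstMaximum,
    NoRecoveryLimb,
    PipelineError,
)
from placentaq.synthetic import CurveParams, ScanSchedule, simulate_si_curve


def make_curve(values, times=None, **kw):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = 60.0 * np.arange(1, values.size + 1)
    return dce.SICurve(times=times, values=values, **kw)


class TestExtractRoiTimeseries:
    def test_single_voxel_mask_returns_trajectory(self, rng):
        volumes = rng.random((6, 4, 5, 5))
        mask = np.zeros((4, 5, 5), dtype=bool)
        mask[2, 1, 3] = True
        curve = dce.extract_roi_timeseries(volumes, mask, times_s=np.arange(1, 7.0))
        np.testing.assert_array_equal(curve.values, volumes[:, 2, 1, 3])

    def test_uniform_volume_gives_constant(self):
        volumes = np.full((5, 3, 3), 7.0)
        mask = np.ones((3, 3), dtype=bool)
        curve = dce.extract_roi_timeseries(volumes, mask, times_s=np.arange(1, 6.0))
        np.testing.assert_allclose(curve.values, 7.0)

    def test_matches_bruteforce_mean_oracle(self, rng):
        for _ in range(50):
            t, ny, nx = 4, 6, 7
            volumes = rng.random((t, ny, nx)) * 100
            masks = rng.random((t, ny, nx)) > 0.5
            masks[:, 0, 0] = True  # never empty
            curve = dce.extract_roi_timeseries(volumes, masks, times_s=np.arange(1, t + 1.0))
            expected = []
            for k in range(t):  # independent per-voxel summation
                total = count = 0
                for i in range(ny):
                    for j in range(nx):
                        if masks[k, i, j]:
                            total += volumes[k, i, j]
                            count += 1
                expected.append(total / count)
            np.testing.assert_allclose(curve.values, expected, rtol=1e-12)

    def test_empty_mask_names_timepoint(self, rng):
        volumes = rng.random((3, 4, 4))
        masks = np.ones((3, 4, 4), dtype=bool)
        masks[1] = False
        with pytest.raises(DataError, match="timepoint 1"):
            dce.extract_roi_timeseries(volumes, masks, times_s=np.arange(1, 4.0))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DataError, match="mask shape"):
            dce.extract_roi_timeseries(
                rng.random((3, 4, 4)), np.ones((5, 5), bool), times_s=np.arange(1, 4.0)
            )


class TestDetectLandmarks:
    def test_forced_example(self):
        curve = make_curve([1, 2, 1, 0.5, 1.5, 2.5])
        lm = dce.detect_landmarks(curve, smooth_window=1)
        assert (lm.first_max_index, lm.interior_min_index, lm.second_max_index) == (1, 3, 5)

    def test_strictly_decreasing_raises(self):
        with pytest.raises(NoFirstMaximum):
            dce.detect_landmarks(make_curve([10, 9, 8, 7, 6, 5]), smooth_window=1)

    def test_no_recovery_limb_raises(self):
        with pytest.raises(NoRecoveryLimb):
            dce.detect_landmarks(make_curve([1, 3, 2.5, 2, 1.5]), smooth_window=1)

    def test_short_curve_rejected(self):
        with pytest.raises(DataError):
            dce.detect_landmarks(make_curve([1, 2, 1, 2]), smooth_window=1)

    def test_even_window_rejected(self):
        with pytest.raises(DataError):
            dce.detect_landmarks(make_curve([1, 2, 1, 0.5, 1.5, 2.5]), smooth_window=2)

    def test_noiseless_sweep_matches_dense_oracle(self):
        """Landmark locations within one scan interval of the dense-grid
        ground truth, ratios within 2%, across a 300+ point parameter sweep."""
        schedule = ScanSchedule()
        n_checked = 0
        for a1, t1, a2, onset, rate in itertools.product(
            (0.3, 0.5, 0.7, 0.9), (6.0, 8.0, 10.0), (0.2, 0.35, 0.5),
            (25.0, 30.0, 35.0), (0.12, 0.2, 0.3),
        ):
            params = CurveParams(
                uptake_amplitude=a1, uptake_time=t1, recovery_amplitude=a2,
                recovery_onset=onset, recovery_rate=rate, noise_sd=0.0,
            )
            sim = simulate_si_curve(params, schedule, seed=0)
            if sim.ground_truth is None:
                continue  # monophasic corner of the sweep
            curve, gt = sim.curve, sim.ground_truth
            lm = dce.detect_landmarks(curve)
            interval = schedule.scan_duration
            assert abs(curve.times[lm.first_max_index] - gt.first_max_time_s) <= interval
            assert abs(curve.times[lm.interior_min_index] - gt.interior_min_time_s) <= interval
            assert abs(curve.times[lm.second_max_index] - gt.second_max_time_s) <= interval
            assert dce.initial_enhancement(curve, lm) == pytest.approx(
                gt.initial_enhancement, rel=0.02
            )
            assert dce.recovery(curve, lm) == pytest.approx(gt.recovery, rel=0.02)
            n_checked += 1
        assert n_checked >= 200


class TestRatios:
    def test_initial_enhancement_direct(self):
        curve = make_curve([100, 150, 100, 80, 120, 140])
        lm = dce.detect_landmarks(curve, smooth_window=1)
        assert dce.initial_enhancement(curve, lm) == pytest.approx(1.5)

    def test_recovery_direct(self):
        curve = make_curve([1, 2, 1, 0.5, 1.5, 2.5])
        lm = dce.detect_landmarks(curve, smooth_window=1)
        assert dce.recovery(curve, lm) == pytest.approx(5.0)

    @pytest.mark.parametrize("c", [0.1, 3.0, 1000.0])
    def test_scale_invariance(self, c, rng):
        for _ in range(20):
            base = 100 + 50 * rng.random(25)
            curve = make_curve(base)
            scaled = make_curve(c * base)
            try:
                lm = dce.detect_landmarks(curve)
            except (NoFirstMaximum, NoRecoveryLimb):
                continue
            lm_s = dce.detect_landmarks(scaled)
            assert lm == lm_s
            assert dce.initial_enhancement(scaled, lm_s) == pytest.approx(
                dce.initial_enhancement(curve, lm), rel=1e-12
            )
            assert dce.recovery(scaled, lm_s) == pytest.approx(
                dce.recovery(curve, lm), rel=1e-12
            )

    def test_time_unit_invariance(self, wt_params):
        """E and R do not depend on the time axis; ROE scales inversely."""
        sim = simulate_si_curve(wt_params, seed=0)
        curve = sim.curve
        stretched = dce.SICurve(times=curve.times * 7.0, values=curve.values)
        lm, lm_s = dce.detect_landmarks(curve), dce.detect_landmarks(stretched)
        assert lm == lm_s
        assert dce.initial_enhancement(curve, lm) == dce.initial_enhancement(stretched, lm_s)
        vc = make_curve(np.full(25, 200.0), times=curve.times)
        vc_s = make_curve(np.full(25, 200.0), times=stretched.times)
        np.testing.assert_allclose(
            dce.compute_roe(curve, vc), 7.0 * dce.compute_roe(stretched, vc_s)
        )

    def test_recovery_ordering_in_amplitude(self, wt_params):
        from dataclasses import replace

        detected = []
        for a2 in (0.1, 0.25, 0.5, 0.7):
            sim = simulate_si_curve(replace(wt_params, recovery_amplitude=a2), seed=0)
            lm = dce.detect_landmarks(sim.curve)
            detected.append(dce.recovery(sim.curve, lm))
        assert all(b >= a for a, b in zip(detected, detected[1:]))

    def test_zero_baseline_rejected(self):
        curve = make_curve([0, 2, 1, 0.5, 1.5, 2.5])
        lm = dce.detect_landmarks(curve, smooth_window=1)
        with pytest.raises(DataError):
            dce.initial_enhancement(curve, lm)


class TestComputeRoe:
    def test_linear_rise_constant_roe(self):
        times = 60.0 * np.linspace(0, 10, 11)  # 0..10 min
        curve = make_curve(np.linspace(100, 200, 11), times=times)
        vc = make_curve(np.full(11, 200.0), times=times)
        np.testing.assert_allclose(dce.compute_roe(curve, vc), 0.05)

    def test_constant_curve_zero_roe(self):
        times = 60.0 * np.arange(1, 9.0)
        curve = make_curve(np.full(8, 150.0), times=times)
        vc = make_curve(np.full(8, 100.0), times=times)
        np.testing.assert_array_equal(dce.compute_roe(curve, vc), 0.0)

    def test_matches_finite_difference_oracle(self, rng):
        times = 163.0 * np.arange(1, 26)
        for _ in range(20):
            values = 100 + 40 * rng.random(25)
            vc_values = 150 + 40 * rng.random(25)
            curve = make_curve(values, times=times)
            vc = make_curve(vc_values, times=times)
            peak = int(np.argmax(vc_values))
            ref = np.mean(vc_values[peak + 1 : peak + 4]) if peak < 24 else vc_values[peak]
            expected = [  # independently coded finite difference
                (values[k + 1] - values[k]) / ((times[k + 1] - times[k]) / 60.0) / ref
                for k in range(24)
            ]
            np.testing.assert_allclose(dce.compute_roe(curve, vc), expected, rtol=1e-12)

    def test_schedule_mismatch_rejected(self):
        curve = make_curve([1, 2, 1.5, 1, 2])
        vc = make_curve([1, 2, 1.5, 1, 2], times=60.0 * np.arange(2, 7))
        with pytest.raises(DataError):
            dce.compute_roe(curve, vc)


class TestAnalyzeCohort:
    def test_identical_curves_zero_sem(self):
        curve_values = [1, 2, 1, 0.5, 1.5, 2.5]
        curves = [make_curve(curve_values, id=f"c{i}", group="WT") for i in range(3)]
        result = dce.analyze_cohort(curves, smooth_window=1)
        assert result.summary.loc[0, "sem_initial_enhancement"] == 0.0
        assert result.summary.loc[0, "sem_recovery"] == 0.0

    def test_failures_recorded_not_dropped(self):
        good = [make_curve([1, 2, 1, 0.5, 1.5, 2.5], id=f"g{i}") for i in range(3)]
        bad = make_curve([6, 5, 4, 3, 2, 1], id="bad")
        result = dce.analyze_cohort(good + [bad], smooth_window=1)
        assert len(result.table) == 3
        assert len(result.failures) == 1
        assert result.failures.loc[0, "id"] == "bad"
        assert result.failures.loc[0, "reason"] == "NoFirstMaximum"

    def test_all_failures_is_pipeline_error(self):
        bad = [make_curve([6, 5, 4, 3, 2, 1], id=f"b{i}") for i in range(2)]
        with pytest.raises(PipelineError):
            dce.analyze_cohort(bad, smooth_window=1)

    def test_planted_direction_power(self):
        """WT vs DKO cohorts (A2 0.5 vs 0.1, n=8, 2% noise): the detected
        group-mean recovery ratio orders as planted in >=95/100 replicates."""
        from placentaq.synthetic import GenotypePreset, default_presets, simulate_cohort

        wt = default_presets()[0]
        dko = default_presets()[-1]
        assert wt.params.recovery_amplitude == 0.5
        assert dko.params.recovery_amplitude == 0.1
        wins = 0
        for rep in range(100):
            cohort = simulate_cohort([wt, dko], n_per_group=8, seed=1000 + rep)
            result = dce.analyze_cohort([c.curve for c in cohort])
            means = result.summary.set_index("group")["mean_recovery"]
            wins += means["WT"] > means["Cdkn2a_p53_DKO"]
        assert wins >= 95


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(min_value=1.0, max_value=1000.0), min_size=6, max_size=40),
    c=st.floats(min_value=1e-3, max_value=1e3),
)
def test_ratio_scale_invariance_property(values, c):
    """For any curve with detectable landmarks, E and R are scale invariant."""
    curve = make_curve(values)
    try:
        lm = dce.detect_landmarks(curve, smooth_window=1)
    except (NoFirstMaximum, NoRecoveryLimb):
        return
    scaled = make_curve([c * v for v in values])
    lm_s = dce.detect_landmarks(scaled, smooth_window=1)
    assert dce.initial_enhancement(scaled, lm_s) == pytest.approx(
        dce.initial_enhancement(curve, lm), rel=1e-9
    )
    assert dce.recovery(scaled, lm_s) == pytest.approx(dce.recovery(curve, lm), rel=1e-9)
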
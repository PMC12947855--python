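"""Trace filtering, differentiation, onset detection, metrics, exclusions."""

import numpy as np
import pytest
from scipy import signal

from reachvigor import cohort, kinematics as km

FS = 1000.0


def make_trace(radial_pos, cue_ms=100.0, angle_deg=45.0):
    t = np.arange(len(radial_pos), dtype=float)
    rad = np.radians(angle_deg)
    return km.VelocityTrace(t=t, x=radial_pos * np.cos(rad),
                            y=radial_pos * np.sin(rad),
                            radial_pos=np.asarray(radial_pos, float),
                            events={"cue": cue_ms})


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        x = np.full(2000, 0.37)
        assert np.allclose(km.lowpass_filter(x), x, atol=1e-9)

    @pytest.mark.parametrize("freq,check", [(2.0, "pass"), (50.0, "stop")])
    def test_transfer_function_magnitude(self, freq, check):
        """Empirical sinusoid gain must match the analytic double-pass
        Butterworth response."""
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = km.lowpass_filter(x)
        mid = slice(1500, 3500)  # avoid edge transients
        gain = np.max(np.abs(y[mid])) / np.max(np.abs(x[mid]))
        sos = km.butter_double_pass_sos()
        w, h = signal.sosfreqz(sos, worN=[2 * np.pi * freq / FS])
        analytic = float(np.abs(h[0]) ** 2)  # forward+backward squares |H|
        assert gain == pytest.approx(analytic, abs=0.01)
        if check == "pass":
            assert gain > 0.99
        else:
            assert gain < 0.10

    def test_double_pass_cutoff_calibrated_to_10hz(self):
        sos = km.butter_double_pass_sos()
        w, h = signal.sosfreqz(sos, worN=[2 * np.pi * 10.0 / FS])
        assert np.abs(h[0]) ** 2 == pytest.approx(1 / np.sqrt(2), abs=0.005)

    def test_zero_phase_pulse_peak_unshifted(self):
        x = np.exp(-0.5 * ((np.arange(3000) - 1500) / 120.0) ** 2)
        y = km.lowpass_filter(x)
        assert np.argmax(y) == 1500

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            km.lowpass_filter(np.zeros(5))

    def test_filter_idempotent_on_well_resolved_content(self):
        """Content far below the cutoff passes with gain ~1, so refiltering
        changes the trace negligibly."""
        t = np.arange(6000) / FS
        x = (np.sin(2 * np.pi * 0.3 * t) + 0.5 * np.sin(2 * np.pi * 0.6 * t)
             + 0.3 * np.sin(2 * np.pi * 1.0 * t))
        once = km.lowpass_filter(x)
        twice = km.lowpass_filter(once)
        mid = slice(1000, 5000)
        rel = np.max(np.abs(twice[mid] - once[mid])) / np.max(np.abs(once[mid]))
        assert rel < 1e-5


class TestRadialVelocity:
    def test_exact_for_linear(self):
        p = 0.1 * np.arange(100) / FS
        v = km.radial_velocity(p)
        assert np.allclose(v[1:-1], 0.1, atol=1e-12)

    def test_exact_for_quadratic_interior(self):
        t = np.arange(200) / FS
        p = 3.0 * t ** 2
        v = km.radial_velocity(p)
        assert np.allclose(v[1:-1], 6.0 * t[1:-1], atol=1e-9)


class TestOnsetDetection:
    def make_burst(self, rt_ms=250.0, peak=0.6, cue_ms=100.0):
        kin = cohort.KinematicGenParams()
        return cohort.simulate_trace(peak, peak * 0.9, 0.0, kin, 45.0,
                                     rt_ms=rt_ms, cue_delay_ms=cue_ms)

    @pytest.mark.parametrize("rt", [150.0, 300.0, 500.0])
    def test_onset_within_10ms_of_ground_truth(self, rt):
        tr = self.make_burst(rt_ms=rt)
        onset = km.detect_onset(tr)
        assert onset == pytest.approx(tr.events["true_onset"], abs=10.0)

    def test_flat_trace_returns_none(self):
        tr = make_trace(np.zeros(2000))
        assert km.detect_onset(tr) is None

    def test_scale_invariance(self):
        tr = self.make_burst()
        onset1 = km.detect_onset(tr)
        tr2 = km.VelocityTrace(t=tr.t, x=2 * tr.x, y=2 * tr.y,
                               radial_pos=2 * tr.radial_pos,
                               radial_vel=2 * tr.radial_vel, events=dict(tr.events))
        assert km.detect_onset(tr2) == onset1


class TestExtractMetrics:
    def test_generator_peaks_recovered_within_1pct(self):
        kin = cohort.KinematicGenParams()
        tr = cohort.simulate_trace(0.6, 0.5, 0.0, kin, 45.0)
        f = km.filter_trace(tr)
        m = km.extract_metrics(f, 45.0)
        assert not m.excluded
        assert m.out_peak_vel == pytest.approx(0.6, rel=0.01)
        assert m.return_peak_vel == pytest.approx(0.5, rel=0.01)
        assert m.max_excursion >= 0.10

    def test_short_reach_flagged_double_peak(self):
        kin = cohort.KinematicGenParams()
        tr = cohort.simulate_trace(0.6, 0.5, 0.0, kin, 45.0, max_excursion=0.09)
        m = km.extract_metrics(km.filter_trace(tr), 45.0)
        assert m.excluded and m.exclusion_reason == km.EXCLUSION_DOUBLE_PEAK

    def test_angular_miss_flagged(self):
        kin = cohort.KinematicGenParams()
        tr = cohort.simulate_trace(0.6, 0.5, 0.0, kin, 45.0)
        m = km.extract_metrics(km.filter_trace(tr), target_angle_deg=45.0 + 23.0)
        assert m.excluded and m.exclusion_reason == km.EXCLUSION_MISS
        assert m.angular_error == pytest.approx(23.0, abs=0.5)

    def test_events_embedded_after_extraction(self):
        kin = cohort.KinematicGenParams()
        tr = cohort.simulate_trace(0.6, 0.5, 0.0, kin, 45.0)
        f = km.filter_trace(tr)
        km.extract_metrics(f, 45.0)
        assert {"cue", "onset", "hit", "feedback"} <= set(f.events)
        assert f.events["feedback"] == f.events["hit"]


class TestExclusions:
    def test_clean_cohort_nothing_excluded(self, small_learned_cohort):
        out = km.apply_exclusions(small_learned_cohort)
        assert out.excluded.sum() == 0
        assert np.array_equal(out.reward_for_history, out.reward.astype(float))

    def test_injected_failures_flagged_and_zeroed(self):
        kin = cohort.KinematicGenParams(failure_rate=0.05)
        rec, _ = cohort.simulate_cohort(n_subjects=2, kin=kin, seed=9)
        out = km.apply_exclusions(rec)
        assert out.excluded.equals(out.gen_failure)
        excl_rewarded = out[out.excluded & (out.reward == 1)]
        assert len(excl_rewarded) > 0
        assert (excl_rewarded.reward_for_history == 0).all()


class TestNormalizationAndDifferences:
    def test_normalized_outgoing_max_is_one(self):
        kin = cohort.KinematicGenParams()
        tr = cohort.simulate_trace(0.6, 0.5, 0.0, kin, 45.0)
        v = km.normalize_velocity(tr.radial_vel, float(np.max(tr.radial_vel)))
        assert np.max(v) == pytest.approx(1.0)
        assert np.allclose(v, km.normalize_velocity(2 * tr.radial_vel,
                                                    2 * float(np.max(tr.radial_vel))))

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            km.normalize_velocity(np.ones(10), 0.0)

    def test_baseline_group_difference_is_zero_and_identical_subjects_sem_zero(self):
        rng = np.random.default_rng(4)
        T = 50
        curves, subs, grps = [], [], []
        base_curve = rng.standard_normal(T)
        for s in range(3):
            for g in ("base", "hi"):
                for _ in range(5):
                    curves.append(base_curve + (1.0 if g == "hi" else 0.0))
                    subs.append(s)
                    grps.append(g)
        df = km.difference_traces(np.array(curves), subs, grps, {"base"},
                                  np.arange(T))
        base = df[df.group == "base"]
        hi = df[df.group == "hi"]
        assert np.allclose(base["mean"], 0.0, atol=1e-12)
        assert np.allclose(hi["mean"], 1.0, atol=1e-12)
        assert np.allclose(df["sem"], 0.0, atol=1e-12)  # identical participants

    def test_missing_baseline_participant_dropped_with_warning(self):
        curves = np.ones((4, 10))
        subs = [0, 0, 1, 1]
        grps = ["base", "hi", "hi", "hi"]
        with pytest.warns(UserWarning, match="no baseline"):
            df = km.difference_traces(curves, subs, grps, {"base"}, np.arange(10))
        assert (df.n_subjects == 1).all()

    def test_rpe_ordering_of_post_feedback_difference_traces(self):
        """Post-latency difference curves must be ordered by RPE level when
        the generator modulates the return phase."""
        kin = cohort.KinematicGenParams(rpe_gain=0.08)
        rpes = [-2 / 3, 0.0, 2 / 3]
        curves, subs, grps = [], [], []
        for s in range(3):
            for rpe in rpes:
                for rep in range(3):
                    tr = cohort.simulate_trace(0.6, 0.54, rpe, kin, 45.0)
                    f = km.filter_trace(tr)
                    km.attach_radial_velocity(f)
                    m = km.extract_metrics(f)
                    w = km.extract_aligned_window(f, "feedback",
                                                  out_peak_vel=m.out_peak_vel)
                    curves.append(w)
                    subs.append(s)
                    grps.append(rpe)
        df = km.difference_traces(np.array(curves), subs, grps, {0.0},
                                  np.arange(-150, 300))
        late = df[df.time_ms > 262]
        mean_by_rpe = late.groupby("group")["mean"].mean()
        # return velocity is negative, so positive RPE -> more negative normalized values
        assert mean_by_rpe[2 / 3] < mean_by_rpe[0.0] < mean_by_rpe[-2 / 3]
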
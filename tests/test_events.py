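import numpy as np
import pytest

from atriapop import synth
from atriapop.events import (
    BeatWindow,
    DetectionConfig,
    apd_at_level,
    ctd_at_level,
    detect_eads,
    detect_pause_events,
    segment_beats,
)


def make_trace(dt=1.0, total=1000.0):
    t = np.arange(0.0, total, dt)
    return t, np.full_like(t, -80.0)


class TestApdGeometry:
    def test_square_pulse_all_levels(self):
        t, v = make_trace()
        v[100:300] = 20.0  # 200 ms square AP
        w = BeatWindow(0, len(t), 100)
        for level in (10, 25, 50, 75, 90):
            assert apd_at_level(t, v, w, level) == pytest.approx(200.0, abs=1.0)

    def test_linear_repolarization_ramp(self):
        """Instant upstroke then a linear 300 ms ramp: APD75 = 225 ms."""
        t, v = make_trace()
        v[100] = 20.0
        ramp = np.linspace(20.0, -80.0, 301)
        v[100:401] = ramp
        w = BeatWindow(0, len(t), 100)
        assert apd_at_level(t, v, w, 75) == pytest.approx(225.0, abs=1.0)
        assert apd_at_level(t, v, w, 50) == pytest.approx(150.0, abs=1.0)

    def test_unreached_level_is_nan(self):
        t, v = make_trace()
        v[100:] = 20.0  # never repolarizes
        w = BeatWindow(0, len(t), 100)
        assert np.isnan(apd_at_level(t, v, w, 90))

    def test_level_bounds(self):
        t, v = make_trace()
        w = BeatWindow(0, len(t), 100)
        with pytest.raises(ValueError):
            apd_at_level(t, v, w, 0.0)

    def test_monotone_in_level(self):
        """APD10 <= APD25 <= ... <= APD90 on a smooth repolarization."""
        t = np.arange(0.0, 600.0)
        v = -80.0 + 100.0 / (1.0 + np.exp((t - 250.0) / 40.0))
        v[:50] = -80.0
        w = BeatWindow(0, len(t), 50)
        apds = [apd_at_level(t, v, w, lv) for lv in (10, 25, 50, 75, 90)]
        assert all(b >= a for a, b in zip(apds, apds[1:]))


class TestCtd:
    def test_square_ca_pulse(self):
        t, ca = make_trace()
        ca[:] = 0.1
        ca[100:500] = 1.0
        w = BeatWindow(0, len(t), 100)
        assert ctd_at_level(t, ca, w, 50) == pytest.approx(400.0, abs=1.0)

    def test_triangular_decay(self):
        """Instant rise, 500 ms linear decay: CTD75 = 375 ms."""
        t, ca = make_trace()
        ca[:] = 0.1
        ca[100:601] = np.linspace(1.1, 0.1, 501)
        w = BeatWindow(0, len(t), 100)
        assert ctd_at_level(t, ca, w, 75) == pytest.approx(375.0, abs=1.0)


class TestSegmentation:
    def test_n_stimuli_n_windows(self):
        t, v = make_trace(total=4000.0)
        stim = np.array([0.0, 1000.0, 2000.0, 3000.0])
        for s in stim.astype(int):
            v[s + 5:s + 205] = 10.0
        windows = segment_beats(t, v, stim)
        assert len(windows) == 4

    def test_quiescent_trace_empty(self):
        t, v = make_trace()
        assert segment_beats(t, v) == []

    def test_jittered_train_recovers_generator_beats(self):
        """Detected upstrokes sit within one sample of generator truth."""
        spec = synth.TraceGeneratorSpec(jitter_cv=0.03, noise_sd=0.0,
                                        drift_per_s=0.0, seed=4)
        trace, truth = synth.synth_ap_train(spec)
        windows = segment_beats(trace.t_ms, trace.values)
        assert len(windows) == len(truth.beat_times_ms) == 5
        dt = 1000.0 / spec.sampling_hz
        for w, t_true in zip(windows, truth.beat_times_ms):
            assert abs(trace.t_ms[w.upstroke] - t_true) <= 2 * dt


class TestPauseEvents:
    def pause_trace(self, total=6000.0):
        t = np.arange(0.0, total)
        v = np.full_like(t, -80.0)
        return t, v

    def test_flat_pause_no_events(self):
        t, v = self.pause_trace()
        rep = detect_pause_events(t, v, 0.0)
        assert rep.dad_count == 0 and rep.tap_count == 0

    def test_subthreshold_bump_is_one_dad(self):
        """An 8 mV bump below the tAP voltage level counts as one DAD."""
        t, v = self.pause_trace()
        v += 8.0 * np.exp(-0.5 * ((t - 3000.0) / 50.0) ** 2)
        rep = detect_pause_events(t, v, 0.0)
        assert rep.dad_count == 1 and rep.tap_count == 0
        assert rep.has_dad

    def test_fast_large_deflection_is_tap(self):
        """Crossing -40 mV with a fast upstroke classifies as tAP, not DAD."""
        t, v = self.pause_trace()
        mask = (t >= 3000) & (t < 3100)
        v[mask] = -80.0 + 60.0 * np.exp(-0.5 * ((t[mask] - 3040.0) / 10.0) ** 2)
        rep = detect_pause_events(t, v, 0.0)
        assert rep.tap_count == 1 and rep.dad_count == 0

    def test_merge_window_fuses_close_deflections(self):
        t, v = self.pause_trace()
        for center in (3000.0, 3030.0):  # closer than the 50 ms merge window
            v += 8.0 * np.exp(-0.5 * ((t - center) / 8.0) ** 2)
        rep = detect_pause_events(t, v, 0.0)
        assert rep.dad_count + rep.tap_count == 1

    def test_short_pause_rejected(self):
        t = np.arange(0.0, 30.0)
        v = np.full_like(t, -80.0)
        with pytest.raises(ValueError, match="merge window"):
            detect_pause_events(t, v, 0.0)

    def test_slow_drift_is_not_an_event(self):
        """Slow diastolic drift (seconds scale) is not a DAD."""
        t, v = self.pause_trace(10000.0)
        v += 12.0 * (t / t[-1])
        rep = detect_pause_events(t, v, 0.0)
        assert rep.dad_count == 0 and rep.tap_count == 0

    def test_classification_exhaustive_exclusive(self):
        t, v = self.pause_trace()
        v += 8.0 * np.exp(-0.5 * ((t - 2000.0) / 40.0) ** 2)
        mask = (t >= 4000) & (t < 4100)
        v[mask] += 60.0 * np.exp(-0.5 * ((t[mask] - 4040.0) / 10.0) ** 2)
        rep = detect_pause_events(t, v, 0.0)
        assert rep.dad_count == 1 and rep.tap_count == 1


class TestEads:
    def beat(self):
        t = np.arange(0.0, 1100.0)
        v = np.full_like(t, -80.0)
        v[50:] = -80.0 + 100.0 / (1.0 + np.exp((t[50:] - 420.0) / 60.0))
        return t, v

    def test_monotone_repolarization_no_ead(self):
        t, v = self.beat()
        w = BeatWindow(0, len(t), 50)
        assert detect_eads(t, v, [w]) == []

    def test_single_notch_detected(self):
        """A re-depolarizing notch inside the repolarization window whose
        net dV/dt reverses counts as one EAD."""
        t, v = self.beat()
        v += 14.0 * np.exp(-0.5 * ((t - 500.0) / 20.0) ** 2)
        w = BeatWindow(0, len(t), 50)
        assert len(detect_eads(t, v, [w])) == 1

    def test_n_notches_counted(self):
        t, v = self.beat()
        for c in (500.0, 590.0):
            v += 14.0 * np.exp(-0.5 * ((t - c) / 20.0) ** 2)
        w = BeatWindow(0, len(t), 50)
        assert len(detect_eads(t, v, [w])) == 2


class TestRelativeThresholds:
    def test_affine_rescaled_optical_agrees(self):
        """Detection with relative thresholds is invariant under affine
        rescaling of the trace."""
        t = np.arange(0.0, 6000.0)
        v = np.full_like(t, -80.0)
        v[:100] = 20.0  # establishes beat amplitude reference
        v += 8.0 * np.exp(-0.5 * ((t - 3000.0) / 50.0) ** 2)
        cfg = DetectionConfig(relative=True, smooth_samples=0)
        rep_mv = detect_pause_events(t, v, 500.0, cfg)
        rep_opt = detect_pause_events(t, 0.013 * v + 7.0, 500.0, cfg)
        assert rep_mv.dad_count == rep_opt.dad_count == 1
        assert rep_mv.tap_count == rep_opt.tap_count
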
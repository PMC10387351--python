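import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from atriapop import synth
from atriapop.metrics import (
    IntervalSeries,
    MetricsConfig,
    OpticalTrace,
    arrhythmia_index,
    classify_irregular,
    ks_distance,
    mad,
    mmode_intervals,
    nmad,
    normalize,
    peak_intervals,
    rates_comparable,
)


def brute_force_ks(a, b):
    """Independent oracle: evaluate both ECDFs at every breakpoint."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.searchsorted(a, x, side="right") / len(a)
        fb = np.searchsorted(b, x, side="right") / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestNormalize:
    def test_affine_invariance(self):
        spec = synth.TraceGeneratorSpec(seed=3)
        trace, _ = synth.synth_ap_train(spec)
        n1 = normalize(trace)
        n2 = normalize(OpticalTrace(2.7 * trace.values + 11.0, trace.rate_hz))
        assert np.allclose(n1.values, n2.values, atol=1e-10)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize(OpticalTrace(np.ones(100)))

    def test_linear_drift_removed(self):
        """5%/s linear drift: post-normalization beat baselines level to
        within 1% of amplitude."""
        spec = synth.TraceGeneratorSpec(noise_sd=0.0, drift_per_s=0.05, seed=0)
        trace, truth = synth.synth_ap_train(spec)
        norm = normalize(trace)
        # baseline sampled just before each beat
        idx = [int(t / 10.0) - 2 for t in truth.beat_times_ms if t > 50]
        baselines = norm.values[idx]
        assert baselines.max() - baselines.min() < 0.01


class TestIntervals:
    def test_ideal_train(self):
        spec = synth.TraceGeneratorSpec(noise_sd=0.0, drift_per_s=0.0, seed=0)
        trace, _ = synth.synth_ap_train(spec)
        iv, rate = peak_intervals(trace)
        assert len(iv) == 4
        assert iv.intervals_ms == pytest.approx([1000.0] * 4, abs=10.0)
        assert rate == pytest.approx(1.0, rel=0.02)

    def test_quiescent_warns_empty(self):
        trace = OpticalTrace(np.random.default_rng(0).normal(0, 1e-6, 500))
        with pytest.warns(UserWarning):
            iv, rate = peak_intervals(trace)
        assert len(iv) == 0

    def test_jittered_train_matches_truth(self):
        spec = synth.TraceGeneratorSpec(jitter_cv=0.04, noise_sd=0.0,
                                        drift_per_s=0.0, seed=9)
        trace, truth = synth.synth_ap_train(spec)
        iv, _ = peak_intervals(trace)
        assert len(iv) == len(truth.intervals_ms)
        assert np.allclose(iv.intervals_ms, truth.intervals_ms, atol=11.0)


class TestArrhythmiaIndex:
    def test_constant_intervals_regular(self):
        ai = arrhythmia_index(IntervalSeries(np.full(6, 500.0)))
        assert ai == 0.0
        assert not classify_irregular(ai)

    def test_two_interval_value(self):
        """{400, 600} ms: CV = sd/mean = 141.42/500 -> AI = 28.28."""
        ai = arrhythmia_index(IntervalSeries(np.array([400.0, 600.0])))
        assert ai == pytest.approx(28.2842712, abs=1e-4)
        assert classify_irregular(ai)

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        base = np.array([400.0, 500.0, 650.0, 480.0])
        assert arrhythmia_index(base * c) == pytest.approx(
            arrhythmia_index(base), rel=1e-9
        )

    def test_undefined_below_two(self):
        with pytest.warns(UserWarning):
            assert np.isnan(arrhythmia_index(IntervalSeries(np.array([500.0]))))


class TestKsDistance:
    def test_identical_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ks_distance(x, x) == 0.0

    def test_disjoint_one(self):
        assert ks_distance([1, 2, 3], [10, 11, 12]) == 1.0

    def test_quarter_shift(self):
        assert ks_distance([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_distance([], [1.0])

    @given(
        a=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=50),
        b=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=50),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_and_symmetry(self, a, b):
        d = ks_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)
        assert d == pytest.approx(ks_distance(b, a), abs=1e-12)


class TestMad:
    def test_constant_zero(self):
        assert mad(np.full(10, 3.0)) == 0.0

    def test_hand_computed(self):
        """{1..5}: median 3, |devs| {2,1,0,1,2}, median 1, x 1.4826."""
        assert mad([1, 2, 3, 4, 5]) == pytest.approx(1.4826)

    def test_k_is_reciprocal_normal_quartile(self):
        assert MetricsConfig().mad_k == pytest.approx(
            1.0 / stats.norm.ppf(0.75), rel=1e-4
        )

    def test_normal_consistency(self):
        """MAD of 1e5 normal draws estimates sigma within 1%."""
        x = np.random.default_rng(12).normal(0.0, 2.5, 100_000)
        assert mad(x) == pytest.approx(2.5, rel=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad([])


class TestNmad:
    def test_scale_invariance(self):
        x = np.array([500.0, 520.0, 800.0, 490.0])
        assert nmad(3.0 * x) == pytest.approx(nmad(x), rel=1e-12)

    def test_constant_zero(self):
        assert nmad(np.full(5, 700.0)) == 0.0

    def test_median_robustness(self):
        """{500, 500, 1000}: deviations {0, 0, 500}, median 0 -> nMAD 0."""
        assert nmad([500.0, 500.0, 1000.0]) == 0.0


class TestMmode:
    def test_square_wave_intervals(self):
        """200 ms contraction in an 800 ms period: SI 200, DI 600, HP 800."""
        t, d, _ = synth.synth_mmode(hp_ms=800.0, si_ms=200.0, n_beats=8)
        table, summary = mmode_intervals(t, d)
        assert summary["SI_ms"] == pytest.approx(200.0, abs=4.0)
        assert summary["DI_ms"] == pytest.approx(600.0, abs=4.0)
        assert summary["HP_ms"] == pytest.approx(800.0, abs=4.0)

    def test_hp_identity(self):
        t, d, _ = synth.synth_mmode(n_beats=6, noise_sd=0.5, seed=3)
        table, _ = mmode_intervals(t, d)
        assert np.allclose(table["HP_ms"], table["SI_ms"] + table["DI_ms"])

    def test_fractional_shortening_recovery(self):
        t, d, truth = synth.synth_mmode(fractional_shortening=0.4, n_beats=10)
        _, summary = mmode_intervals(t, d)
        assert summary["fractional_shortening"] == pytest.approx(0.40, abs=0.01)

    def test_no_contractions_warns(self):
        with pytest.warns(UserWarning):
            table, summary = mmode_intervals(np.arange(100.0), np.full(100, 50.0))
        assert len(table) == 0


def test_rate_guard():
    assert rates_comparable(1.0, 1.05)
    assert not rates_comparable(1.0, 1.2)
    assert not rates_comparable(0.0, 1.0)
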
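"""Exponential decay fitting, weighted tau, desensitization, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptoscope import (ExpFit, Trace, average_waveform, desens_extent,
                          fit_exponentials, pp_recovery, weighted_tau)
from synaptoscope.kinetics import (FitError, InsufficientDecayError,
                                   measure_desensitization)

RATE = 50_000.0


def decay_trace(fn, duration=0.25):
    t_ms = np.arange(int(duration * RATE)) / RATE * 1e3
    return Trace(fn(t_ms), RATE)


class TestExponentialFits:
    def test_single_component_exact(self):
        f = fit_exponentials(decay_trace(lambda t: 80 * np.exp(-t / 10.0)),
                             include_offset=False)
        assert f.n_components == 1
        a, tau = f.components[0]
        assert tau == pytest.approx(10.0, rel=1e-3)
        assert a == pytest.approx(80.0, rel=1e-3)

    def test_two_components_within_one_percent(self):
        f = fit_exponentials(
            decay_trace(lambda t: 50 * np.exp(-t / 5.0)
                        + 50 * np.exp(-t / 50.0), duration=0.4),
            include_offset=False)
        assert f.n_components == 2
        taus = [tau for _, tau in f.components]
        assert taus[0] == pytest.approx(5.0, rel=0.01)
        assert taus[1] == pytest.approx(50.0, rel=0.01)

    def test_offset_recovered(self):
        f = fit_exponentials(decay_trace(lambda t: -20 + 60 * np.exp(-t / 8.0)))
        assert f.offset == pytest.approx(-20.0, abs=0.1)

    def test_constant_segment_is_insufficient_decay(self):
        with pytest.raises(InsufficientDecayError):
            fit_exponentials(Trace(np.full(5000, -40.0), RATE))


class TestWeightedTau:
    @pytest.mark.parametrize("components, expected", [
        ([(1.0, 12.0)], 12.0),
        ([(1.0, 10.0), (1.0, 20.0)], 15.0),
        ([(3.0, 10.0), (1.0, 50.0)], 20.0),
    ])
    def test_hand_arithmetic(self, components, expected):
        fit = ExpFit(components=components, offset=0.0, sse=0.0, n_points=0)
        assert weighted_tau(fit) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.1, 100.0), st.floats(0.1, 500.0)),
                    min_size=1, max_size=3),
           st.floats(0.01, 100.0))
    def test_scale_invariance_and_bounds(self, comps, scale):
        fit = ExpFit(components=comps, offset=0.0, sse=0.0, n_points=0)
        tw = weighted_tau(fit)
        scaled = ExpFit(components=[(a * scale, t) for a, t in comps],
                        offset=0.0, sse=0.0, n_points=0)
        assert weighted_tau(scaled) == pytest.approx(tw, rel=1e-9)
        taus = [t for _, t in comps]
        assert min(taus) - 1e-9 <= tw <= max(taus) + 1e-9

    def test_zero_amplitude_sum_rejected(self):
        fit = ExpFit(components=[(1.0, 5.0), (-1.0, 10.0)], offset=0.0,
                     sse=0.0, n_points=0)
        with pytest.raises(FitError):
            weighted_tau(fit)


class TestDesensExtent:
    @pytest.mark.parametrize("peak, steady, expected", [
        (-90.0, -40.0, 55.6), (-50.0, -50.0, 0.0), (-50.0, 0.0, 100.0),
    ])
    def test_arithmetic(self, peak, steady, expected):
        assert desens_extent(peak, steady) == pytest.approx(expected, abs=0.1)

    def test_sign_convention_invariance(self):
        assert desens_extent(-90.0, -40.0) == pytest.approx(
            desens_extent(90.0, 40.0))

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            desens_extent(0.0, -10.0)

    def test_measured_extent_from_trace(self):
        t = np.arange(int(0.2 * RATE)) / RATE
        y = -100 * (0.444 + 0.556 * np.exp(-t / 0.03))
        peak, steady, extent = measure_desensitization(Trace(y, RATE))
        assert extent == pytest.approx(55.6, abs=0.5)


class TestAverageWaveform:
    def _events_df(self, t_peaks):
        import pandas as pd
        return pd.DataFrame({"t_peak": t_peaks,
                             "t_onset": np.asarray(t_peaks) - 0.002,
                             "baseline": 0.0})

    def test_identical_events_mean_equals_each(self):
        n = int(1.0 * RATE)
        x = np.zeros(n)
        shape = -50 * np.exp(-np.arange(int(0.05 * RATE)) / RATE / 0.02)
        for t0 in (0.2, 0.6):
            j = int(t0 * RATE)
            x[j:j + shape.size] += shape
        tr = Trace(x, RATE)
        mean, mat, peak_idx = average_waveform(
            tr, self._events_df([0.2, 0.6]), align="peak")
        np.testing.assert_allclose(mat[0], mat[1], atol=1e-12)
        np.testing.assert_allclose(mean.samples, mat[0], atol=1e-12)
        assert mean.samples[peak_idx] == pytest.approx(-50.0)

    def test_peak_aligned_mean_peak_is_average(self):
        n = int(1.0 * RATE)
        x = np.zeros(n)
        base = -(1 - np.exp(-np.arange(int(0.05 * RATE)) / RATE / 5e-4)) \
            * np.exp(-np.arange(int(0.05 * RATE)) / RATE / 0.02)
        base /= np.abs(base).max()
        j1, j2 = int(0.2 * RATE), int(0.6 * RATE)
        x[j1:j1 + base.size] += 50 * base
        x[j2:j2 + base.size] += 100 * base
        tr = Trace(x, RATE)
        p = int(np.argmin(x[j1:j1 + base.size]))
        t_peaks = [(j1 + p) / RATE, (j2 + p) / RATE]
        mean, _, peak_idx = average_waveform(tr, self._events_df(t_peaks),
                                             align="peak")
        assert mean.samples[peak_idx] == pytest.approx(-75.0, rel=1e-6)

    def test_too_few_events_rejected(self):
        tr = Trace(np.zeros(int(RATE)), RATE)
        with pytest.raises(FitError):
            average_waveform(tr, self._events_df([0.5]))


class TestRecovery:
    def test_synthetic_ratio_curve_fit(self):
        """Synthetic paired traces built from a known (d, tau) recover it."""
        intervals = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        d_true, tau_true = 0.6, 2.0
        rate = 5000.0
        traces = {}
        for iv in intervals:
            n = int((iv + 0.1) * rate)
            y = np.zeros(n)
            shape = -100 * np.exp(-np.arange(int(0.02 * rate)) / rate / 0.004)
            y[0:shape.size] += shape
            j2 = int(iv * rate)
            ratio = 1 - d_true * np.exp(-iv / tau_true)
            y[j2:j2 + shape.size] += ratio * shape[:min(shape.size, n - j2)]
            traces[float(iv)] = Trace(y, rate)
        curve = pp_recovery(traces)
        np.testing.assert_allclose(
            curve.ratios, 1 - d_true * np.exp(-intervals / tau_true),
            atol=0.02)
        assert curve.d == pytest.approx(d_true, rel=0.05)
        assert curve.tau_rec == pytest.approx(tau_true, rel=0.05)

    def test_suppression_duration_interpolation(self):
        from synaptoscope import RecoveryCurve
        c = RecoveryCurve(intervals=np.array([0.5, 1.0, 2.0]),
                          ratios=np.array([0.5, 0.7, 0.9]))
        assert 1.0 < c.suppression_duration(0.8) < 2.0
        flat = RecoveryCurve(intervals=np.array([0.5, 1.0]),
                             ratios=np.array([0.99, 1.0]))
        assert flat.suppression_duration(0.8) == 0.0
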
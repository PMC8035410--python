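"""Event detection, selection flags, and per-event features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptoscope import (ChannelEnsemble, Template, Trace, burst_windows,
                          detect_events, extract_features, feature_matrix,
                          flag_selection, simulate_event)
from synaptoscope.events import CLUSTER_FEATURES, DetectionError

RATE = 20_000.0
DT = 1.0 / RATE


def build_train(onsets, ensemble=None, noise=1.0, duration=0.5, seed=3):
    ensemble = ensemble or ChannelEnsemble(
        N=60, i=-2.0, rise_tau_ms=0.5, decay=((1.0, 15.0),), p_peak=0.9)
    rng = np.random.default_rng(seed)
    n = int(duration * RATE)
    x = np.zeros(n)
    for onset in onsets:
        ev = simulate_event(ensemble, DT, 0.12, rng)
        j = int(onset * RATE)
        x[j:j + ev.samples.size] += ev.samples
    if noise > 0:
        x += rng.normal(0, noise, n)
    return Trace(x, RATE)


class TestDetection:
    def test_flat_trace_no_events(self):
        tr = Trace(np.zeros(20_000), RATE)
        det = detect_events(tr, Template(0.5, 15.0), 4.0)
        assert len(det) == 0

    def test_template_longer_than_trace_rejected(self):
        tr = Trace(np.zeros(100), RATE)
        with pytest.raises(DetectionError):
            detect_events(tr, Template(0.5, 15.0), 4.0)

    def test_recall_and_precision_at_snr10(self, snr10_train,
                                           snr10_detections):
        from conftest import match_events
        _, truth = snr10_train
        det = snr10_detections
        tp = match_events(det["t_peak"].to_numpy(),
                          truth["t_peak"].to_numpy())
        assert tp / len(truth) >= 0.95
        assert tp / len(det) >= 0.95

    def test_translation_equivariance(self):
        tr = build_train([0.1, 0.3])
        shift = 40  # samples
        shifted = Trace(np.concatenate([tr.samples[-shift:],
                                        tr.samples[:-shift]]), RATE)
        # compare on the interior (wrap-around region differs)
        d1 = detect_events(tr, Template(0.5, 15.0), 5.0, fit_window_ms=3.0)
        d2 = detect_events(shifted, Template(0.5, 15.0), 5.0,
                           fit_window_ms=3.0)
        t1 = d1["t_peak"].to_numpy()
        t2 = d2["t_peak"].to_numpy()
        assert t1.size == t2.size
        np.testing.assert_allclose(t2, t1 + shift * DT, atol=1e-9)

    def test_overlapping_pair_both_detected_second_not_clean(self):
        tr = build_train([0.1, 0.103])
        det = detect_events(tr, Template(0.5, 15.0), 5.0, fit_window_ms=3.0)
        det = flag_selection(det, tr)
        assert len(det) == 2
        assert bool(det["clean_rise"].iloc[0])
        assert not bool(det["clean_rise"].iloc[1])

    def test_noiseless_peaks_exact(self):
        """On a noiseless train the detected peak amplitudes equal the
        ground-truth event peaks exactly."""
        from synaptoscope import EventClass, TrainConfig, simulate_train
        ens = ChannelEnsemble(N=100, i=-1.0, rise_tau_ms=0.5,
                              decay=((1.0, 15.0),), p_peak=1.0)
        cfg = TrainConfig(duration=30.0, classes=(EventClass(0.3, ens),),
                          noise_sd=0.0, rate=RATE, seed=5)
        trace, truth = simulate_train(cfg)
        det = detect_events(trace, Template(0.5, 15.0), 5.0,
                            fit_window_ms=3.0)
        assert len(det) == len(truth)
        for _, row in det.iterrows():
            assert row.amplitude == pytest.approx(-100.0, abs=1e-9)


class TestFlags:
    def test_isolated_event_clean(self):
        tr = build_train([0.1])
        det = flag_selection(
            detect_events(tr, Template(0.5, 15.0), 5.0, fit_window_ms=3.0), tr)
        assert bool(det["clean_rise"].iloc[0])
        assert bool(det["clean_decay"].iloc[0])

    def test_summated_pair_first_not_clean_decay(self):
        tr = build_train([0.1, 0.13])
        det = flag_selection(
            detect_events(tr, Template(0.5, 15.0), 5.0, fit_window_ms=3.0), tr)
        assert bool(det["clean_rise"].iloc[0])
        assert not bool(det["clean_decay"].iloc[0])

    def test_notched_rise_not_clean(self):
        rng = np.random.default_rng(0)
        n = int(0.5 * RATE)
        j0 = int(0.1 * RATE)
        y = np.zeros(n)
        y[j0:j0 + 20] = np.linspace(0, -60, 20)
        y[j0 + 20:j0 + 30] = np.linspace(-60, -45, 10)  # rebound on the rise
        y[j0 + 30:j0 + 50] = np.linspace(-45, -120, 20)
        y[j0 + 50:] = -120 * np.exp(-(np.arange(n - j0 - 50) * DT) / 0.015)
        y += rng.normal(0, 1.0, n)
        tr = Trace(y, RATE)
        det = flag_selection(
            detect_events(tr, Template(0.5, 15.0), 5.0, fit_window_ms=3.0), tr)
        assert len(det) >= 1
        assert not bool(det["clean_rise"].iloc[0])


class TestFeatures:
    def test_rise_times_match_closed_form(self):
        """A(t) = -100 (1 - e^(-t/0.5ms)) e^(-t/20ms): the 20-80% rise time
        agrees with root-finding on the closed form within one sample."""
        from scipy.optimize import brentq
        t = np.arange(int(0.3 * RATE)) * DT
        j0 = int(0.05 * RATE)
        wave = np.zeros_like(t)
        tt = (t[: t.size - j0]) * 1e3
        wave[j0:] = -100 * (1 - np.exp(-tt / 0.5)) * np.exp(-tt / 20.0)
        tr = Trace(wave, RATE)
        det = detect_events(tr, Template(0.5, 20.0), 5.0, fit_window_ms=3.0)
        feats = extract_features(det, tr)
        amp = wave.min()

        def f(ms, frac):
            return (-100 * (1 - np.exp(-ms / 0.5)) * np.exp(-ms / 20.0)
                    - frac * amp)

        t20 = brentq(f, 1e-6, 2.0, args=(0.2,))
        t80 = brentq(f, 1e-6, 6.0, args=(0.8,))
        expected = t80 - t20
        assert feats["rise_20_80"].iloc[0] == pytest.approx(
            expected, abs=DT * 1e3)

    def test_rise_time_ordering_invariant(self, snr10_train,
                                          snr10_detections):
        trace, _ = snr10_train
        feats = extract_features(snr10_detections, trace)
        ok = feats[["rise_30_70", "rise_20_80", "rise_10_90"]].dropna()
        assert (ok["rise_30_70"] <= ok["rise_20_80"] + 1e-12).all()
        assert (ok["rise_20_80"] <= ok["rise_10_90"] + 1e-12).all()

    def test_iei_reciprocal_is_instantaneous_frequency(self):
        tr = build_train([0.1, 0.35])
        det = detect_events(tr, Template(0.5, 15.0), 5.0, fit_window_ms=3.0)
        feats = extract_features(det, tr)
        assert np.isnan(feats["iei"].iloc[0])
        iei = feats["iei"].iloc[1]
        assert feats["inst_freq"].iloc[1] == pytest.approx(1.0 / iei)

    def test_burst_window_example(self):
        """Events at 0, 0.5, 1.0, 5.0 s: the 0.5 s event's burst window is
        the 1.0 s triplet {0, 0.5, 1.0}."""
        bw, cv = burst_windows(np.array([0.0, 0.5, 1.0, 5.0]))
        assert bw[1] == pytest.approx(1.0)
        assert cv[1] == pytest.approx(0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 100.0), min_size=3, max_size=40,
                    unique=True))
    def test_burst_window_equals_brute_force(self, times):
        """The sliding triplet rule equals exhaustive minimisation over all
        consecutive triplets containing each event."""
        t = np.sort(np.asarray(times))
        bw, _ = burst_windows(t)
        n = t.size
        for j in range(n):
            widths = [t[first + 2] - t[first]
                      for first in range(max(0, j - 2), min(j, n - 3) + 1)]
            assert bw[j] == pytest.approx(min(widths))

    def test_burst_window_missing_below_three_events(self):
        bw, cv = burst_windows(np.array([0.0, 1.0]))
        assert np.isnan(bw).all() and np.isnan(cv).all()

    def test_feature_matrix_excludes_amplitude(self, snr10_train,
                                               snr10_detections):
        trace, _ = snr10_train
        feats = extract_features(snr10_detections, trace)
        assert "amplitude" not in CLUSTER_FEATURES
        X, keep = feature_matrix(feats)
        assert X.shape[1] == 9
        assert np.all(np.isfinite(X))

    def test_feature_matrix_requires_columns(self):
        with pytest.raises(ValueError, match="burst_cv"):
            feature_matrix(pd.DataFrame({"iei": [1.0]}))
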
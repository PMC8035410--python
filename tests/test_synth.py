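"""Generative model: binomial ensembles, Poisson trains, C-O-D kinetics."""

import numpy as np
import pytest

from synaptoscope import (ChannelEnsemble, EventClass, KineticScheme,
                          ProtocolSpec, TrainConfig, preset_scheme,
                          simulate_event, simulate_paired_pulse,
                          simulate_train)
from synaptoscope.synth import ConfigError, _deterministic_sweep, _segments


class TestChannelEnsemble:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ChannelEnsemble(N=0, i=-3.0)
        with pytest.raises(ConfigError):
            ChannelEnsemble(N=10, i=-3.0, p_peak=1.5)
        with pytest.raises(ConfigError):
            ChannelEnsemble(N=10, i=-3.0, decay=((0.5, 10.0), (0.3, 50.0)))

    def test_single_channel_saturated_is_constant(self):
        ens = ChannelEnsemble(N=1, i=-3.0, rise_tau_ms=1e-4,
                              decay=((1.0, 1e9),), p_peak=1.0)
        tr = simulate_event(ens, 1e-4, 0.01, rng=0)
        assert np.all(tr.samples[1:] == -3.0)

    def test_mean_peak_matches_binomial_closed_form(self):
        """2,000 peaks at N=60, i=-3, p=0.9: mean within Monte-Carlo error
        of N*i*p = -162 pA (SE = |i| sqrt(N p (1-p) / n) ~ 0.15 pA)."""
        ens = ChannelEnsemble(N=60, i=-3.0, p_peak=0.9)
        rng = np.random.default_rng(42)
        k_peak = int(round(ens.peak_time() / 5e-5))
        peaks = []
        for _ in range(2000):
            tr = simulate_event(ens, 5e-5, ens.peak_time() + 2e-3, rng)
            peaks.append(tr.samples[k_peak])
        se = 3.0 * np.sqrt(60 * 0.9 * 0.1 / 2000)
        assert np.mean(peaks) == pytest.approx(-162.0, abs=4 * se)

    def test_variance_at_half_open_probability(self):
        """Across-event variance at p=0.5 equals N p (1-p) i^2 = 50 pA^2."""
        ens = ChannelEnsemble(N=50, i=-2.0, p_peak=0.5)
        rng = np.random.default_rng(3)
        k_peak = int(round(ens.peak_time() / 5e-5))
        vals = [simulate_event(ens, 5e-5, ens.peak_time() + 2e-3, rng)
                .samples[k_peak] for _ in range(4000)]
        assert np.var(vals, ddof=1) == pytest.approx(50.0, rel=0.12)


class TestTrain:
    def test_seed_determinism_bitwise(self):
        ens = ChannelEnsemble(N=26, i=-3.33)
        cfg = TrainConfig(duration=20.0, classes=(EventClass(1.0, ens),),
                          noise_sd=2.0, rate=5000.0, seed=9)
        t1, e1 = simulate_train(cfg)
        t2, e2 = simulate_train(cfg)
        assert np.array_equal(t1.samples, t2.samples)
        assert e1.equals(e2)

    def test_noise_free_ground_truth_peaks_exact(self):
        ens = ChannelEnsemble(N=26, i=-3.33)
        cfg = TrainConfig(duration=30.0, classes=(EventClass(0.5, ens),),
                          noise_sd=0.0, rate=5000.0, seed=5)
        trace, truth = simulate_train(cfg)
        # isolated events only: each true peak is present in the summed trace
        iei_ok = np.diff(truth["t_onset"], prepend=-1.0) > 0.5
        for row, ok in zip(truth.itertuples(index=False), iei_ok):
            if not ok:
                continue
            j = int(round(row.t_peak * 5000.0))
            assert trace.samples[j] == pytest.approx(row.amplitude, abs=1e-9)

    def test_class_mixing_fractions_follow_rates(self):
        """Poisson thinning: class rates 0.5/1.5 Hz give a 0.75 class-2
        fraction of events up to binomial Monte-Carlo error."""
        a = EventClass(0.5, ChannelEnsemble(N=20, i=-2.0), name="a")
        b = EventClass(1.5, ChannelEnsemble(N=20, i=-2.0), name="b")
        cfg = TrainConfig(duration=400.0, classes=(a, b), noise_sd=0.0,
                          rate=1000.0, seed=11)
        _, truth = simulate_train(cfg)
        frac_b = (truth["class_name"] == "b").mean()
        n = len(truth)
        assert frac_b == pytest.approx(0.75, abs=4 * np.sqrt(0.75 * 0.25 / n))

    def test_empty_train_warns(self):
        ens = ChannelEnsemble(N=10, i=-2.0)
        cfg = TrainConfig(duration=0.05, classes=(EventClass(0.01, ens),),
                          noise_sd=0.0, rate=10_000.0, seed=1)
        with pytest.warns(UserWarning, match="no events"):
            _, truth = simulate_train(cfg)
        assert truth.empty


class TestKineticScheme:
    def test_occupancies_conserved(self):
        scheme = preset_scheme("wild-type")
        prot = ProtocolSpec(intervals=(0.5,))
        traj = _deterministic_sweep(scheme, prot, 0.5, 2e-4)
        np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(traj >= -1e-12)

    def test_no_desensitization_full_recovery(self):
        scheme = KineticScheme(beta=5000.0, alpha=300.0, delta=0.0, rho=1.0)
        prot = ProtocolSpec(intervals=(0.1, 0.5, 2.0))
        from synaptoscope import pp_recovery
        traces = simulate_paired_pulse(scheme, prot, mode="deterministic")
        curve = pp_recovery(traces, fit=False)
        np.testing.assert_allclose(curve.ratios, 1.0, atol=0.01)

    def test_closed_form_recovery_ratio(self):
        """With fraction d desensitized after pulse 1 and recovery rate rho,
        the paired-pulse ratio at interval t is 1 - d exp(-rho t)."""
        scheme = KineticScheme(beta=50_000.0, alpha=2000.0, delta=3000.0,
                               rho=0.5)
        prot = ProtocolSpec(intervals=(1.0, 2.0, 4.0), tail=0.02)
        from synaptoscope import pp_recovery
        traces = simulate_paired_pulse(scheme, prot, mode="deterministic",
                                       dt=5e-5)
        curve = pp_recovery(traces, fit=False)
        # extract d from the deterministic occupancies just after pulse 1
        traj = _deterministic_sweep(scheme, prot, 1.0, 5e-5)
        k_ref = int(round(0.05 / 5e-5))  # 50 ms: open state fully drained
        d = traj[k_ref, 2] * np.exp(scheme.rho * 0.05)
        expected = 1.0 - d * np.exp(-scheme.rho * np.array(prot.intervals))
        np.testing.assert_allclose(curve.ratios, expected, atol=0.02)

    def test_stochastic_mean_approaches_deterministic(self):
        scheme = preset_scheme("wild-type")
        prot = ProtocolSpec(intervals=(0.25,), tail=0.02)
        det = simulate_paired_pulse(scheme, prot, mode="deterministic",
                                    n_channels=100, dt=2e-4)[0.25]
        sto = simulate_paired_pulse(scheme, prot, mode="stochastic",
                                    n_trials=500, n_channels=100, dt=2e-4,
                                    rng=123)[0.25]
        n_min = min(det.samples.size, sto.samples.size)
        occ_det = det.samples[:n_min] / (100 * -1.0)
        occ_sto = sto.samples[:n_min] / (100 * -1.0)
        # binomial MC standard error on the mean open occupancy
        se = np.sqrt(np.maximum(occ_det * (1 - occ_det), 1e-6)
                     / (500 * 100))
        excess = np.abs(occ_sto - occ_det) / (3 * se + 1e-12)
        assert np.quantile(excess, 0.99) < 1.5

    def test_preset_suppression_ordering(self):
        from synaptoscope import pp_recovery
        prot = ProtocolSpec(intervals=(0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0,
                                       8.0))
        durations = {}
        for name in ("non-desensitizing", "wild-type", "hyper-desensitizing"):
            traces = simulate_paired_pulse(preset_scheme(name), prot,
                                           mode="deterministic")
            durations[name] = pp_recovery(traces, fit=False) \
                .suppression_duration()
        assert (durations["hyper-desensitizing"] > durations["wild-type"]
                > durations["non-desensitizing"])

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ConfigError):
            ProtocolSpec(pulse_duration=0.01, intervals=(0.005,))

    def test_segments_cover_protocol(self):
        prot = ProtocolSpec(intervals=(0.5,), tail=0.03)
        segs = _segments(prot, 0.5)
        assert sum(d for d, _ in segs) == pytest.approx(0.5 + 1e-3 + 0.03)
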
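import numpy as np
import pytest

from synaptoscope import (ChannelEnsemble, EventClass, Template, TrainConfig,
                          detect_events, simulate_train)


@pytest.fixture(scope="session")
def snr10_train():
    """A 60 s synthetic train at SNR ~10 (peak / noise SD) with ground truth."""
    ens = ChannelEnsemble(N=26, i=-3.33, p_peak=0.95)
    cfg = TrainConfig(duration=60.0, classes=(EventClass(1.0, ens),),
                      noise_sd=8.2, rate=10_000.0, seed=7)
    trace, truth = simulate_train(cfg)
    return trace, truth


@pytest.fixture(scope="session")
def snr10_detections(snr10_train):
    trace, _ = snr10_train
    return detect_events(trace, Template(0.5, 20.0), threshold=5.0,
                         fit_window_ms=10.0)


def match_events(detected_peaks, truth_peaks, window=5e-3):
    """Greedy one-to-one matching of detected to true peaks within a window.

    Returns the number of true positives.
    """
    detected_peaks = np.asarray(detected_peaks, dtype=float)
    used = np.zeros(detected_peaks.size, dtype=bool)
    tp = 0
    for t in truth_peaks:
        if detected_peaks.size == 0:
            break
        d = np.abs(detected_peaks - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] < window:
            used[j] = True
            tp += 1
    return tp
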
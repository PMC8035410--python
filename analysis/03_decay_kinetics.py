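"""Decay kinetics of averaged sIPSCs and of sustained agonist responses.

Part 1: average the clean-decay sIPSCs per condition (rise-aligned), fit a
two-component exponential to the averaged decay and report the weighted
time constant T_w = sum(a_k t_k)/sum(a_k).

Part 2: integrate a 200 ms saturating-agonist application on a slowly
desensitizing C-O-D receptor and report the extent of desensitization
D = (1 - steady/peak) x 100 and the weighted fit constant of the
desensitization phase.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from synaptoscope import (KineticScheme, ProtocolSpec, Trace,
                          average_waveform, fit_exponentials,
                          measure_desensitization, read_sweep, weighted_tau)
from synaptoscope.core import read_events, write_events
from synaptoscope.synth import _deterministic_sweep

DATA = Path("scratch/data")
RESULTS = Path("results")


def sipsc_decays():
    index = pd.read_csv(RESULTS / "simulated_cells_index.tsv", sep="\t")
    events = read_events(RESULTS / "event_features.tsv")
    rows = []
    for cond in index["condition"].unique():
        sub_idx = index[index["condition"] == cond]
        mats = []
        rate = None
        for rec in sub_idx.itertuples(index=False):
            trace = read_sweep(DATA / rec.sweep)
            rate = trace.rate
            ev = events.query(
                "condition == @cond and cell == @rec.cell and clean_rise "
                "and clean_decay")
            if len(ev) < 2:
                continue
            _, mat, peak_idx = average_waveform(trace, ev, align="peak",
                                                pre=0.005, post=0.15)
            mats.append((mat, peak_idx))
        pooled = np.vstack([m for m, _ in mats])
        peak_idx = mats[0][1]
        mean = pooled.mean(axis=0)
        decay = Trace(mean[peak_idx:], rate)
        fit = fit_exponentials(decay, max_components=2,
                               include_offset=False)
        tw = weighted_tau(fit)
        rows.append({"condition": cond, "n_events": pooled.shape[0],
                     "peak_pA": round(float(mean[peak_idx]), 1),
                     "n_components": fit.n_components,
                     "tau_fast_ms": round(fit.components[0][1], 1),
                     "tau_slow_ms": round(fit.components[-1][1], 1),
                     "weighted_tau_ms": round(tw, 1)})
        print(f"{cond}: mean peak {rows[-1]['peak_pA']} pA, "
              f"T_w {rows[-1]['weighted_tau_ms']} ms "
              f"({pooled.shape[0]} clean events)")
    return pd.DataFrame(rows)


def patch_desensitization():
    # slowly desensitizing receptor under a 200 ms saturating pulse
    rows = []
    for label, delta in [("moderate", 5.5), ("weak", 0.7),
                         ("strong", 18.0)]:
        scheme = KineticScheme(beta=5000.0, alpha=400.0, delta=delta,
                               rho=0.4)
        prot = ProtocolSpec(pulse_duration=0.2, intervals=(1.0,), tail=0.0)
        occ = _deterministic_sweep(scheme, prot, 1.0, 2e-5)[:, 1]
        n_pulse = int(round(0.2 / 2e-5))
        current = Trace(-100.0 * occ[:n_pulse + 1] / occ.max(), 1.0 / 2e-5)
        peak, steady, extent = measure_desensitization(current)
        k_peak = int(np.argmin(current.samples))
        fit = fit_exponentials(Trace(current.samples[k_peak:], current.rate),
                               max_components=3)
        rows.append({"desensitization": label, "delta_per_s": delta,
                     "extent_percent": round(extent, 1),
                     "weighted_tau_ms": round(weighted_tau(fit), 1)})
        print(f"{label} (delta={delta}/s): extent {extent:.1f}%, "
              f"T_w {rows[-1]['weighted_tau_ms']} ms")
    return pd.DataFrame(rows)


def main():
    print("== averaged sIPSC decays ==")
    sipsc = sipsc_decays()
    write_events(sipsc, RESULTS / "sipsc_decay_fits.tsv")
    print("\n== macroscopic desensitization (200 ms agonist) ==")
    patch = patch_desensitization()
    write_events(patch, RESULTS / "patch_desensitization.tsv")


if __name__ == "__main__":
    main()
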
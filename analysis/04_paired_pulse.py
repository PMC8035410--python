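"""Paired-pulse re-sensitization across desensitization regimes.

Two 1 ms saturating agonist pulses at increasing inter-pulse intervals,
for three C-O-D regimes (non-desensitizing, wild-type-like,
hyper-desensitizing).  The deterministic solution gives the reference
recovery curve; a 200-trial stochastic run confirms it and the fitted
1 - d exp(-dt/tau) recovers the generative (d, tau_rec).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from synaptoscope import (ProtocolSpec, pp_recovery, preset_scheme,
                          simulate_paired_pulse)
from synaptoscope.core import write_events
from synaptoscope.synth import _deterministic_sweep

RESULTS = Path("results")
SEED = 404


def main():
    protocol = ProtocolSpec(intervals=(0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0,
                                       8.0))
    rows, curves = [], []
    rng = np.random.default_rng(SEED)
    for name in ("non-desensitizing", "wild-type", "hyper-desensitizing"):
        scheme = preset_scheme(name)
        det = pp_recovery(simulate_paired_pulse(scheme, protocol,
                                                mode="deterministic"))
        sto = pp_recovery(simulate_paired_pulse(
            scheme, protocol, mode="stochastic", n_trials=200,
            n_channels=200, rng=int(rng.integers(0, 2 ** 31 - 1))))
        # generative recovery parameters from the deterministic occupancies
        traj = _deterministic_sweep(scheme, protocol, 1.0, 1e-4)
        k = int(round(0.05 / 1e-4))
        d_gen = float(traj[k, 2] * np.exp(scheme.rho * (0.05 - 1e-3)))
        rows.append({
            "regime": name,
            "d_generative": round(d_gen, 3),
            "tau_generative_s": round(1.0 / scheme.rho, 3)
            if scheme.rho > 0 else np.inf,
            "d_fitted": round(sto.d, 3) if sto.d is not None else np.nan,
            "tau_fitted_s": round(sto.tau_rec, 3)
            if sto.tau_rec is not None else np.nan,
            "suppression_duration_s": round(det.suppression_duration(), 2),
        })
        for iv, r_det, r_sto in zip(det.intervals, det.ratios, sto.ratios):
            curves.append({"regime": name, "interval_s": iv,
                           "ratio_deterministic": round(float(r_det), 4),
                           "ratio_stochastic": round(float(r_sto), 4)})
        print(f"{name}: d={rows[-1]['d_fitted']} "
              f"(generative {rows[-1]['d_generative']}), "
              f"tau={rows[-1]['tau_fitted_s']} s "
              f"(generative {rows[-1]['tau_generative_s']}), "
              f"suppression lasts {rows[-1]['suppression_duration_s']} s")
    write_events(pd.DataFrame(rows), RESULTS / "pp_recovery_fits.tsv")
    write_events(pd.DataFrame(curves), RESULTS / "pp_recovery_curves.tsv")
    order = {r["regime"]: r["suppression_duration_s"] for r in rows}
    assert (order["hyper-desensitizing"] > order["wild-type"]
            > order["non-desensitizing"])
    print("\nsuppression duration ordering: hyper > wild-type > non — as "
          "expected for desensitization-limited recovery")


if __name__ == "__main__":
    main()
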
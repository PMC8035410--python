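"""Simulate the two-condition whole-cell dataset.

Control synapses activate ~26 receptors at the sIPSC peak; potentiated
synapses ~2.4x more with the same unitary current (~-3.33 pA).  Writes one
sweep + ground-truth table per cell under scratch/data/ (large raw
traces stay out of the results tree) and a small index under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from synaptoscope import EventClass, TrainConfig, simulate_train, write_sweep
from synaptoscope.core import write_events
from synaptoscope.synth import control_ensemble, potentiated_ensemble

OUT = Path("scratch/data")
RESULTS = Path("results")
SEED = 20_260_920
N_CELLS = 3
DURATION = 60.0  # s per cell
RATE = 10_000.0  # Hz


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    index = []
    for name, ensemble in [("control", control_ensemble()),
                           ("potentiated", potentiated_ensemble())]:
        for cell in range(N_CELLS):
            seed = int(rng.integers(0, 2 ** 31 - 1))
            cfg = TrainConfig(duration=DURATION,
                              classes=(EventClass(0.8, ensemble, name),),
                              noise_sd=2.0, rate=RATE, seed=seed)
            trace, truth = simulate_train(cfg)
            stem = f"{name}_cell{cell}"
            write_sweep(trace, OUT / f"{stem}.tsv")
            write_events(truth, OUT / f"{stem}_truth.tsv")
            index.append({"condition": name, "cell": cell, "seed": seed,
                          "sweep": f"{stem}.tsv",
                          "truth": f"{stem}_truth.tsv",
                          "n_true_events": len(truth)})
            print(f"{stem}: {len(truth)} events over {DURATION:.0f} s")
    RESULTS.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(index).to_csv(RESULTS / "simulated_cells_index.tsv", sep="\t", index=False)
    print(f"wrote {2 * N_CELLS} sweeps to {OUT}")


if __name__ == "__main__":
    main()
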
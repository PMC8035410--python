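# synaptoscope

Quantitative analysis of inhibitory synaptic currents, built around the
question of how receptor desensitization reshapes synaptic strength.
Whole-cell recordings of spontaneous inhibitory postsynaptic currents
(sIPSCs) carry more information than their mean amplitude: the
fluctuations of the decaying current report the unitary current *i* and
the number *N* of receptors open at the peak, the recovery of a second
agonist-evoked response probes exit from desensitized states, and the
joint distribution of amplitude-independent event features reveals whether
a potentiation is confined to particular classes of synaptic events.

The package provides, as a tested library plus numbered analysis drivers:

- **Simulation** (`synaptoscope.synth`) — stochastic binomial
  channel-ensemble sIPSC trains (per-sample open counts ~ Binomial(N, p(t)),
  so the variance–mean parabola is exact by construction), Poisson event
  processes with mixture classes, and a C–O–D
  (closed/open/desensitized) receptor scheme driven by square agonist
  pulses, integrated exactly (matrix exponentials) or realised
  channel-by-channel.
- **Detection and features** (`synaptoscope.events`) — sliding
  scaled-template event search (detection statistic = fitted scale / its
  standard error), clean-rise / clean-decay selection rules, and the full
  per-event feature set: 10–90 / 20–80 / 30–70 % rise times, normalized
  rise slopes, interevent interval, instantaneous frequency, burst window
  (shortest interval containing three consecutive events) and its
  interval CV.
- **Kinetics** (`synaptoscope.kinetics`) — multi-exponential decay fits
  with SSE-guided component selection, the weighted time constant
  `T_w = Σ(a_k·t_k)/Σ(a_k)`, desensitization extent
  `D = (1 − steady/peak) × 100`, averaged waveforms, and paired-pulse
  recovery curves fitted with `1 − d·exp(−Δt/τ_rec)`.
- **Peak-scaled NSFA** (`synaptoscope.nsfa`) — non-stationary fluctuation
  analysis of peak-aligned decays: the mean waveform is scaled to each
  event's peak and subtracted, and the across-event variance is fitted
  with `σ² = i·I_m − I_m²/N + var`.
- **Skew-t mixture clustering** (`synaptoscope.skewt`) — finite mixtures
  of restricted multivariate skew-t distributions fitted by ECME, with
  component count chosen by BIC, for the nine amplitude-independent event
  features.
- **Pipeline and statistics** (`synaptoscope.pipeline`) — a seeded
  end-to-end two-condition emulation (simulate → detect → features →
  NSFA → cluster) with per-cell aggregation and Student/ANOVA+Tukey group
  comparisons.

## Worked example

Recover the unitary current and receptor number from simulated synaptic
events:

```python
import numpy as np
from synaptoscope import nsfa_from_matrix
from synaptoscope.synth import nsfa_ensemble, simulate_aligned_events

ens = nsfa_ensemble(N=26, i=-3.33)          # 26 receptors, -3.33 pA each
mat, peak = simulate_aligned_events(ens, 300, noise_sd=2.0, dt=5e-5, rng=1)
res = nsfa_from_matrix(mat, peak, n_bins=50)
print(f"i = {res.i:.2f} pA, N = {res.N:.1f}, var = {res.var_baseline:.1f} pA^2")
```

```
i = -3.34 pA, N = 26.2, var = 3.9 pA^2
```

300 noisy events suffice to read back the generative unitary current
(−3.33 pA), the number of receptors open at the peak (26), and the
baseline noise variance (2 pA SD → 4 pA²) from the curvature, slope and
intercept of the variance–mean parabola.

The numbered scripts under `analysis/` run the full study on simulated
data (each prints what it found and writes tables under `results/`):

```
01_simulate_trains.py      two-condition sweeps (control N=26 vs potentiated N=63)
02_detect_and_features.py  template search + features; recall/precision vs truth
03_decay_kinetics.py       averaged-decay fits, T_w, desensitization extents
04_paired_pulse.py         re-sensitization curves for three C-O-D regimes
05_nsfa.py                 per-cell parabola fits; known-truth validation
06_cluster.py              skew-t mixture + BIC; per-cluster condition mix
07_group_stats.py          per-cell t-tests; null calibration of the test
```

On the bundled simulation the pipeline reproduces the qualitative
signature of desensitization-driven inhibitory potentiation: mean sIPSC
amplitude roughly doubles (−68 → −156 pA across cells), median interevent
intervals are statistically indistinguishable, the per-cell fitted
receptor number rises ~2.4× with the unitary current unchanged, and every
mixture cluster contains both conditions in proportions matching the
global mix.

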
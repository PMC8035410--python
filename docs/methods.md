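# Methods

This note records the models behind each stage, the parameters that
matter, and the design choices made where the underlying procedures are
conventionally under-specified.

## Units and conventions

Current is in pA with inward currents negative; event timestamps in
seconds; kinetic time constants in milliseconds. Filtering is causal
(single-pass) by default, matching acquisition hardware; zero-phase
(forward–backward) filtering is available by flag for offline feature
extraction where group delay matters. Digital Bessel filters are designed
from the analogue prototype and discretized by the bilinear transform with
frequency pre-warping, with `norm="mag"` so the −3 dB point lands on the
nominal cutoff. Note that a true 8-pole Bessel is a gentle filter: at
twice its cutoff it is only ~13.5 dB down (a ~22× power ratio), which the
filter tests check against the analogue magnitude response rather than
against a steeper stereotype.

## Generative model for sIPSCs

A synaptic event is an ensemble of `N` independent channels with unitary
current `i` whose open probability follows a difference-of-exponentials
waveform `p(t)` (rise τ_r, one or two decay components, normalized so the
maximum equals `p_peak`). At every sample the open count is drawn
independently as Binomial(N, p(t)), so the ensemble mean is `N·i·p(t)` and
the across-event variance is exactly `N·p(1−p)·i² = i·I − I²/N` — the
fluctuation-analysis parabola holds by construction, giving a clean oracle
for the NSFA stage.

Two consequences of the per-sample independence deserve note, because
real channels are correlated over the filter timescale:

- The *realized* peak of an event (its extreme sample) sits systematically
  below `N·i·p_peak` by an extreme-value offset that grows with the
  binomial flicker `√(N p(1−p))·|i|`. Measured mean amplitudes on the
  default train regime are therefore ~−70 pA rather than the −56 pA of
  the underlying mean waveform.
- Scaling each event by its *measured* peak (the peak-scaled NSFA step)
  can add rather than remove variance: if the scaling peak were an
  independent binomial draw the fitted N would be inflated by
  `1/(2 − 1/p_peak)` (≈ 2× at p_peak = 0.65, ≈ 1.06× at 0.95). The
  dedicated NSFA validation regime therefore runs at `p_peak = 0.95`
  (`synth.nsfa_ensemble`). In practice, locating each peak as the extreme
  sample near the waveform maximum couples the scaling factor to the
  event's own fluctuation and the empirical bias is small even at
  `p_peak = 0.65` (the per-cell fits in `analysis/05_nsfa.py` recover
  N ≈ 22–24 at true 26 and ≈ 62–66 at true 63).

Event trains are Poisson processes per event class (classes differ in
rate, kinetics and amplitude scale, to create separable feature
clusters); baseline noise is additive white Gaussian, whose variance maps
onto the parabola's intercept. Default train regime: event rate 0.8 Hz
(median IEI ≈ 0.9 s), noise SD 2 pA, sampling 10–20 kHz, control ensemble
N=26 / i=−3.33 pA / p_peak=0.65, potentiated ensemble N=63 with everything
else identical — the "more receptors, same unitary current" contrast.

## C–O–D desensitization scheme

Macroscopic desensitization is represented by the minimal scheme
C →(β·agonist) O →(δ) D, with O →(α) C and D →(ρ) C. Deterministic
occupancies are propagated exactly with per-segment matrix exponentials
(agonist is piecewise constant); probability conservation is asserted at
1e-8. The stochastic mode advances channel counts with binomial
transition draws, sub-stepping inside each output sample so no per-step
transition probability exceeds 0.2 (needed during the 1 ms pulses, where
β ≈ 5000 s⁻¹).

Because no rate constants are published for these receptors, the three
presets ("wild-type", "non-desensitizing", "hyper-desensitizing") are
calibrated only to the qualitative paired-pulse phenotype — the duration
of second-pulse suppression orders hyper > wild-type > non — not to
quantitative rates. A single C–O–D scheme cannot simultaneously show
~50 % desensitization over a 200 ms application and seconds-scale
recovery, so the 200 ms-application demonstrations in
`analysis/03_decay_kinetics.py` use a slower-desensitizing variant
(δ ≈ 0.7–18 s⁻¹) of the same scheme.

For a brief pulse the recovery of the second response follows
`1 − d·e^(−Δt/τ_rec)` with `τ_rec = 1/ρ` exactly; the suppressed fraction
`d` is read from the deterministic solution (D occupancy 50 ms after the
pulse, back-extrapolated by `e^{ρ(t−t_pulse)}`), and serves as ground
truth for the stochastic recovery fits.

## Event detection

Detection uses the sliding scaled-template statistic: at each offset the
template `(1 − e^{−t/τ_r}) e^{−t/τ_d}` is fitted by optimal scale and
offset, and the statistic is scale / SE(scale). Candidates are local
maxima above threshold that also rise by the threshold above their
surroundings (plain local maxima would let noise wiggles on a single
event's criterion plateau register as events), separated by at least one
template rise time.

The fitting window is a parameter. With the full template (~5 decay
constants) the statistic matches the published criterion and threshold 4
is appropriate, but any event falling inside the window corrupts the fit
of the one before it, so summated pairs lose their first member. A short
window (rise time + about half a decay constant; 10 ms for the default
20 ms template) keeps the statistic local and resolves pairs tens of ms
apart — and pairs 3 ms apart with a ~3 ms window — at the cost of a
noisier statistic, for which threshold ≈ 5 restores the false-positive
rate. The synthetic-regime drivers and pipeline use (10 ms, 5.0); both
defaults are exposed. A template-subtraction second pass was tried and
rejected: template/shape mismatch leaves decay residuals that flood the
re-run criterion with false positives.

Peaks are located on a 2 kHz low-pass copy (so single deep noise samples
on a decay cannot masquerade as the peak), refined on the raw trace
within ±1 ms (the causal filter's group delay), and measured against a
local baseline (mean of the 2 ms before onset — for a summated event this
is the preceding event's decay level). On noiseless trains detected
amplitudes equal ground-truth peaks exactly.

## Selection flags

`clean_rise` — the 2 kHz-filtered derivative keeps its sign between the
10 % and 90 % rise points (no inflection), and the event rises from a
resting baseline (pre-onset level within 3 robust SDs of the recording's
median — an event starting on another's decay is summated, not clean).
`clean_decay` — additionally, on a 500 Hz zero-phase copy the decay back
to 10 % of peak never turns inward again by more than a floor combining
the expected extreme drawdown of baseline noise over the segment with
0.3 × the event amplitude (the event's own channel flicker scales with
amplitude; only a genuine secondary peak exceeds both). The heavier
smoothing for the decay check is deliberate: broadband channel flicker
averages away at 500 Hz while tens-of-ms secondary events survive.

Mean-amplitude statistics use clean-rise events only; kinetic fits and
NSFA use clean-decay events only; rise-rate, IEI and cumulative-probability
analyses use all detected events.

## Features

Threshold crossings for rise times are linearly interpolated on the raw
trace; the maximum rise slope is the extreme of the 2 kHz (8-pole)
filtered derivative, reported as a positive magnitude in pA/ms and also
normalized by the peak; "mean rise slope normalized to peak" is
0.6 / (20–80 % rise time) in 1/ms. Instantaneous frequency is the
reciprocal of the preceding interevent interval (the first event of a
record has neither). The burst window is the shortest interval containing
three consecutive events including the one in question, computed by
scanning the three candidate triplets (proved equal to exhaustive
enumeration in tests); its CV is the sample CV of the two intervals
inside the chosen triplet. Records with fewer than three events leave the
burst features missing, and feature-incomplete events are excluded from
the clustering matrix (and counted).

## Decay fitting

Sums of decaying exponentials are fitted by bounded nonlinear least
squares with variable-projection initialisation (log-spaced τ seeds,
amplitudes by linear least squares) and five multi-starts. The component
count is the smallest m for which an (m+1)-th component fails to reduce
the SSE by ≥ 2 % (any added component reduces SSE strictly, so a
tolerance is required; 2 % is permissive but stable under noise). Flat
segments raise an "insufficient decay" error rather than returning
degenerate constants. Patch-current fits include an offset term (the
steady-state plateau); sIPSC decay fits do not (return to baseline). The
steady state for the desensitization extent is the mean of the final 10 %
of the application window.

## Peak-scaled NSFA

Clean-decay events are aligned at their peaks; the mean waveform, scaled
by (event peak / mean peak), is subtracted from each event over the decay
window (peak → 10 % of the mean's peak), and the across-event variance of
the residuals is paired with the mean current at each sample. Pairs are
pooled into equal-count bins along I_m (default 50 — quantile binning
stabilises per-bin variances where exponential decays crowd samples near
baseline) and fitted by ordinary least squares on the basis {I, I², 1}.
Because the model is linear in (I, I²), the second regressor per bin is
the bin mean of I² — using (bin mean of I)² would bias the curvature.
Then i = a, N = −1/b, var = c; a non-negative or numerically negligible
quadratic coefficient raises a "non-parabolic variance" error. Fits are
per cell; group statistics operate on per-cell (i, N).

## Skew-t mixtures

Components are restricted multivariate skew-t distributions:
`Y = μ + δ|W| + V` with a Gamma(ν/2, ν/2) mixing weight τ,
`W|τ ~ N(0, 1/τ)`, `V|τ ~ N(0, Σ/τ)`; density
`f(y) = 2 t_d(y; μ, Ω, ν) T_{ν+d}(A√((ν+d)/(ν+Δ)))` with
`Ω = Σ + δδᵀ`. Fitting is ECME: the E-step evaluates the closed-form
conditional moments E[τ|y], E[τ|W||y], E[τW²|y] (scalar-t cdf ratios plus
a direct Gamma-integral term); the CM-steps update weights, then (μ, δ)
jointly by a 2×2 linear solve, then Σ (ridge-regularised if singular);
each ν_g is profiled on the actual observed log-likelihood
(Brent, bounded to [2.5, 200], every third iteration), which keeps the
likelihood monotone — asserted at 1e-8 every iteration. Initialisation is
k-means with δ=0, ν=40; five restarts by default. BIC uses
`p = (G−1) + G(2d + d(d+1)/2 + 1)` free parameters. Features are
standardized (zero mean, unit SD) before fitting by default.
The Gaussian-limit route (δ pinned at 0, ν pinned large) reproduces an
independent Gaussian-mixture fit, which the tests use as an oracle.

## Pipeline and statistics

The end-to-end run is deterministic given one seed (all per-cell seeds
are spawned from it, kept below 2³¹) and writes per-cell summaries, the
pooled event table, the BIC table, the per-cluster condition summary and
a JSON manifest carrying the seed and a config hash. Group comparisons
always operate on per-cell summaries (per-cell medians for IEI), never on
pooled events: two groups get a two-tailed Student t-test (Welch by
flag), more get one-way ANOVA with Tukey's HSD. Cumulative-probability
curves are means of per-cell empirical CDFs on a common grid.

## Problem sizes

The test-suite and acceptance-script simulations are sized for a single
CPU: 60–120 s sweeps at 10 kHz for detection (~60–120 events at 0.8–1 Hz),
300 events per NSFA fit (10–20 seeds), 200 trials per paired-pulse
interval, 600 points per clustering dataset with the component scan over
G = 1…5. These sizes leave all recovery margins comfortably inside their
tolerances; larger runs only tighten the Monte-Carlo error.

## Known limitations

- No temporal channel correlation in the default event generator (see the
  consequences above); a correlated C–O–D event mode is approximated only
  through the paired-pulse machinery, not the train generator.
- The C–O–D scheme has a single desensitized state; real receptors need
  at least fast+slow desensitized states to reconcile 200 ms
  desensitization extents with seconds-scale paired-pulse recovery.
- ABF (Axon Binary Format) ingestion is not implemented; sweeps are
  two-column TSV/CSV plus a JSON manifest.
- The skew-t family is the restricted (single skew direction per
  component) variant; unrestricted and Bayesian variants are out of scope.
- Passing tests certify recovery under this generator's assumptions
  (white noise, independent gating, exact Poisson timing), not
  performance on recordings with drift, series-resistance artefacts or
  correlated noise.
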
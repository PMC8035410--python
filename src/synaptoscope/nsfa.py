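"""Peak-scaled non-stationary fluctuation analysis.

From a set of peak-aligned synaptic-current decays, the mean waveform is
scaled to each event's peak and subtracted; the across-event variance of
the residuals, plotted against the mean current, follows

    sigma^2 = i * I_m - I_m^2 / N + var

whose parabolic fit yields the unitary current i, the number of receptors
open at the peak N, and the baseline variance var.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NSFAError(RuntimeError):
    pass


class InsufficientEventsError(NSFAError):
    pass


class NonParabolicError(NSFAError):
    """The variance-mean relation has no downward curvature."""


@dataclass
class NSFAResult:
    i: float              # unitary current, pA (signed)
    N: float              # receptors open at the sIPSC peak
    var_baseline: float   # pA^2
    r_squared: float
    n_events: int
    n_bins: int
    binned_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    binned_var: np.ndarray = field(default_factory=lambda: np.empty(0))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


def peak_scaled_variance(matrix: np.ndarray, peak_idx: int,
                         min_events: int = 25, window_frac: float = 0.10
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint (mean current, variance) pairs over the decay.

    ``matrix`` holds one peak-aligned event per row with the peak in column
    ``peak_idx``.  Each event is divided out by its own measured peak: the
    mean waveform scaled by (event peak / mean peak) is subtracted, and the
    across-event variance of the residuals is taken at every decay sample
    from the peak until the mean has fallen to ``window_frac`` of its peak.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_events = matrix.shape[0]
    if n_events < min_events:
        raise InsufficientEventsError(
            f"insufficient events for fluctuation analysis: {n_events} < {min_events}")
    mean = matrix.mean(axis=0)
    mean_peak = mean[peak_idx]
    if mean_peak == 0:
        raise NSFAError("mean waveform peak is zero")
    decay = mean[peak_idx:]
    crossed = np.flatnonzero(np.abs(decay) <= window_frac * np.abs(mean_peak))
    stop = peak_idx + (crossed[0] if crossed.size else decay.size)
    window = slice(peak_idx, max(stop, peak_idx + 3))
    scale = matrix[:, peak_idx] / mean_peak
    resid = matrix[:, window] - scale[:, None] * mean[window]
    variance = resid.var(axis=0, ddof=1)
    return mean[window], variance


def parabola_fit(mean_current: np.ndarray, variance: np.ndarray,
                 n_bins: int = 50, n_events: int = 0,
                 var_tolerance: float = 1e-6) -> NSFAResult:
    """Fit sigma^2 = i*I - I^2/N + var by least squares on binned pairs.

    Pairs are pooled into equal-count bins along the mean current (default
    50) before an ordinary least-squares fit on the basis {I, I^2, 1}; with
    coefficients (a, b, c), i = a, N = -1/b and var = c.  Raises
    NonParabolicError when the quadratic coefficient is non-negative.
    """
    I = np.asarray(mean_current, dtype=float)
    s2 = np.asarray(variance, dtype=float)
    ok = np.isfinite(I) & np.isfinite(s2)
    I, s2 = I[ok], s2[ok]
    if I.size < 3:
        raise NSFAError("need at least 3 finite variance-mean pairs")
    if I.size > n_bins >= 3:
        order = np.argsort(I)
        splits = np.array_split(order, n_bins)
        bin_I = np.array([I[s].mean() for s in splits if s.size])
        # the model is linear in (I, I^2), so the bin mean of I^2 is the
        # correct second regressor (using bin_I**2 would bias the curvature)
        bin_I2 = np.array([(I[s] ** 2).mean() for s in splits if s.size])
        bin_s2 = np.array([s2[s].mean() for s in splits if s.size])
    else:
        bin_I, bin_I2, bin_s2 = I, I ** 2, s2
    X = np.column_stack([bin_I, bin_I2, np.ones_like(bin_I)])
    coef, *_ = np.linalg.lstsq(X, bin_s2, rcond=None)
    a, b, c = coef
    # downward curvature must be present and numerically meaningful: the
    # quadratic term's contribution at the largest currents has to exceed
    # rounding noise relative to the variance scale
    curv_contrib = abs(b) * float(np.max(bin_I2))
    scale = max(float(np.max(np.abs(bin_s2))), 1e-30)
    if b >= 0 or curv_contrib < 1e-9 * scale:
        raise NonParabolicError(
            "non-parabolic variance: no downward curvature in the "
            "variance-mean relation")
    fitted = X @ coef
    ss_res = float(np.sum((bin_s2 - fitted) ** 2))
    ss_tot = float(np.sum((bin_s2 - bin_s2.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    result = NSFAResult(i=float(a), N=float(-1.0 / b), var_baseline=float(c),
                        r_squared=r2, n_events=n_events, n_bins=len(bin_I),
                        binned_mean=bin_I, binned_var=bin_s2,
                        residuals=bin_s2 - fitted)
    return result


def nsfa_from_matrix(matrix: np.ndarray, peak_idx: int, n_bins: int = 50,
                     min_events: int = 25, window_frac: float = 0.10) -> NSFAResult:
    """Convenience wrapper: peak-scaled variance then parabola fit."""
    I, s2 = peak_scaled_variance(matrix, peak_idx, min_events=min_events,
                                 window_frac=window_frac)
    return parabola_fit(I, s2, n_bins=n_bins, n_events=matrix.shape[0])
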
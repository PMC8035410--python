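"""Decay kinetics: multi-exponential fits, weighted time constants,
desensitization extent, averaged waveforms and paired-pulse recovery.

The weighted time constant of a multi-exponential decay is
T_w = sum(a_k * t_k) / sum(a_k), and the extent of desensitization of a
sustained agonist response is D = (1 - steady/peak) * 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .core import Trace


class FitError(RuntimeError):
    pass


class InsufficientDecayError(FitError):
    """The segment has no resolvable decay (e.g. a flat plateau)."""


@dataclass
class ExpFit:
    """Sum-of-exponentials fit: y(t) = sum a_k exp(-t / t_k) + offset.

    Amplitudes in pA (or fractions for normalized waveforms), time
    constants in ms, components sorted ascending by time constant.
    """

    components: list[tuple[float, float]]  # (a_k, t_k ms)
    offset: float
    sse: float
    n_points: int

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c[1])
        if any(t <= 0 for _, t in self.components):
            raise ValueError("time constants must be positive")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def predict(self, t_ms: np.ndarray) -> np.ndarray:
        t_ms = np.asarray(t_ms, dtype=float)
        y = np.full_like(t_ms, self.offset)
        for a, tau in self.components:
            y = y + a * np.exp(-t_ms / tau)
        return y


def _model(t, params, m, offset_flag):
    y = np.full_like(t, params[-1] if offset_flag else 0.0)
    for k in range(m):
        y = y + params[2 * k] * np.exp(-t / params[2 * k + 1])
    return y


def _fit_m(t_ms: np.ndarray, y: np.ndarray, m: int, include_offset: bool,
           n_restarts: int = 5) -> tuple[np.ndarray, float]:
    """Best-of-multistart nonlinear least squares for m components.

    Tau seeds are log-spaced over the segment duration; amplitudes are
    initialised by linear least squares given the seed taus (variable
    projection), the standard remedy for exponential-fit multimodality.
    """
    span = t_ms[-1] - t_ms[0]
    dt = t_ms[1] - t_ms[0]
    best = None
    rng = np.random.default_rng(0)
    for trial in range(n_restarts):
        if trial == 0:
            taus = np.geomspace(max(2 * dt, span / 200), span, m + 2)[1:m + 1] \
                if m > 1 else np.array([span / 5])
        else:
            taus = np.sort(rng.uniform(np.log(max(2 * dt, span / 300)),
                                       np.log(2 * span), size=m))
            taus = np.exp(taus)
        basis = [np.exp(-t_ms / tau) for tau in taus]
        if include_offset:
            basis.append(np.ones_like(t_ms))
        A = np.column_stack(basis)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        p0 = []
        for k in range(m):
            p0 += [coef[k], taus[k]]
        if include_offset:
            p0.append(coef[-1])
        p0 = np.asarray(p0)

        def resid(p):
            return _model(t_ms, p, m, include_offset) - y

        lb = np.full(p0.size, -np.inf)
        ub = np.full(p0.size, np.inf)
        for k in range(m):
            lb[2 * k + 1] = dt / 10
            ub[2 * k + 1] = 50 * span
        p0 = np.clip(p0, lb + 1e-12, ub - 1e-12)
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        sse = float(2 * sol.cost)
        if best is None or sse < best[1]:
            best = (sol.x, sse)
    if best is None:
        raise FitError(f"{m}-component exponential fit failed to converge")
    return best


def fit_exponentials(segment: Trace, max_components: int = 3,
                     include_offset: bool = True,
                     sse_tol: float = 0.02) -> ExpFit:
    """Fit a sum of decaying exponentials to a decay segment.

    The component count is the smallest m for which adding an (m+1)-th
    component fails to reduce the sum of squared errors by at least
    ``sse_tol`` (relative).  The segment's time origin is its first sample
    (normally the current peak).  Raises InsufficientDecayError for flat
    segments where no decay is resolvable.
    """
    y = segment.samples.astype(float)
    t_ms = (np.arange(y.size) / segment.rate) * 1e3
    const_sse = float(np.sum((y - y.mean()) ** 2))
    if const_sse < 1e-20 * max(1.0, float(np.abs(y).max())) ** 2:
        raise InsufficientDecayError("segment is constant; no decay to fit")
    fits = {}
    prev_sse = const_sse
    chosen = None
    for m in range(1, max_components + 1):
        params, sse = _fit_m(t_ms, y, m, include_offset)
        fits[m] = (params, sse)
        if m == 1 and sse > (1 - 1e-3) * const_sse:
            raise InsufficientDecayError(
                "insufficient decay: an exponential explains no variance "
                "beyond a constant")
        if sse > (1 - sse_tol) * prev_sse and m > 1:
            chosen = m - 1
            break
        prev_sse = sse
        chosen = m
    params, sse = fits[chosen]
    comps = [(float(params[2 * k]), float(params[2 * k + 1])) for k in range(chosen)]
    offset = float(params[-1]) if include_offset else 0.0
    return ExpFit(components=comps, offset=offset, sse=sse, n_points=y.size)


def weighted_tau(fit: ExpFit) -> float:
    """Amplitude-weighted mean time constant, ms: sum(a*t)/sum(a)."""
    a = np.array([c[0] for c in fit.components])
    t = np.array([c[1] for c in fit.components])
    s = a.sum()
    if s == 0:
        raise FitError("weighted tau undefined: amplitudes sum to zero")
    return float((a * t).sum() / s)


def desens_extent(peak: float, steady: float) -> float:
    """Percent depression of the steady-state current relative to its peak."""
    if peak == 0:
        raise ValueError("peak current is zero")
    if peak * steady < 0:
        raise ValueError("peak and steady-state currents have opposite signs")
    return (1.0 - steady / peak) * 100.0


def measure_desensitization(response: Trace, steady_frac: float = 0.1) -> tuple[float, float, float]:
    """(peak, steady_state, extent%) of a sustained agonist response.

    Peak = extreme current; steady state = mean over the final
    ``steady_frac`` of the segment.
    """
    y = response.samples
    peak = y[np.argmax(np.abs(y))]
    n_tail = max(1, int(round(steady_frac * y.size)))
    steady = float(y[-n_tail:].mean())
    return float(peak), steady, desens_extent(float(peak), steady)


def average_waveform(trace: Trace, events: pd.DataFrame, align: str = "peak",
                     pre: float = 0.005, post: float = 0.08
                     ) -> tuple[Trace, np.ndarray, int]:
    """Mean event waveform plus the aligned per-event matrix.

    Events are aligned either at their peak sample or at their rise onset;
    windows reaching outside the trace are dropped.  Returns
    (mean trace with t0 = -pre, matrix (n_events x L), peak column index).
    """
    if align not in ("peak", "onset"):
        raise ValueError(f"unknown alignment {align!r}")
    if len(events) < 2:
        raise FitError("need at least 2 events to average")
    n_pre = int(round(pre * trace.rate))
    n_post = int(round(post * trace.rate))
    rows = []
    for row in events.itertuples(index=False):
        anchor_t = row.t_peak if align == "peak" else row.t_onset
        c = int(round((anchor_t - trace.t0) * trace.rate))
        if c - n_pre < 0 or c + n_post > trace.samples.size:
            continue
        base = getattr(row, "baseline", 0.0)
        rows.append(trace.samples[c - n_pre:c + n_post] - base)
    if len(rows) < 2:
        raise FitError("fewer than 2 events fit inside the trace")
    mat = np.asarray(rows)
    mean = mat.mean(axis=0)
    peak_idx = n_pre if align == "peak" else int(np.argmin(mean))
    return Trace(mean, trace.rate, -pre), mat, peak_idx


@dataclass
class RecoveryCurve:
    """Paired-pulse ratio vs inter-pulse interval, plus optional exponential fit."""

    intervals: np.ndarray
    ratios: np.ndarray
    d: float | None = None        # fitted suppressed fraction
    tau_rec: float | None = None  # fitted recovery time constant, s
    n_per_interval: list[int] = field(default_factory=list)

    def suppression_duration(self, level: float = 0.8) -> float:
        """Interpolated interval at which the ratio recovers to ``level``.

        0 if never suppressed below `level`; the last interval if still
        suppressed there.
        """
        if np.all(self.ratios >= level):
            return 0.0
        above = np.flatnonzero(self.ratios >= level)
        below = np.flatnonzero(self.ratios < level)
        j = below[-1]
        if j + 1 >= self.ratios.size:
            return float(self.intervals[-1])
        x0, x1 = self.intervals[j], self.intervals[j + 1]
        y0, y1 = self.ratios[j], self.ratios[j + 1]
        return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))


def _pulse_peaks(trace: Trace, onset1: float, onset2: float,
                 window: float = 0.02) -> tuple[float, float]:
    """(first peak from baseline, second peak from the pre-second-pulse level)."""
    y = trace.samples
    r = trace.rate
    i1 = int(round((onset1 - trace.t0) * r))
    i2 = int(round((onset2 - trace.t0) * r))
    w = int(round(window * r))
    base = y[max(0, i1 - int(0.002 * r)):i1].mean() if i1 > 2 else 0.0
    seg1 = y[i1:min(i1 + w, i2)]
    peak1 = seg1[np.argmax(np.abs(seg1 - base))] - base
    pre2 = y[max(i2 - max(2, int(0.0005 * r)), 0):i2].mean()
    seg2 = y[i2:i2 + w]
    if seg2.size == 0:
        raise FitError("second pulse epoch missing from trace")
    peak2 = seg2[np.argmax(np.abs(seg2 - pre2))] - pre2
    return float(peak1), float(peak2)


def pp_recovery(traces: dict[float, Trace], pulse_duration: float = 1e-3,
                fit: bool = True) -> RecoveryCurve:
    """Recovery curve from paired-pulse traces keyed by inter-pulse interval.

    The second-pulse peak is measured from the local pre-pulse current
    level; the ratio is second/first.  Optionally fits
    ratio = 1 - d * exp(-interval / tau_rec).
    """
    intervals = np.array(sorted(traces))
    ratios = []
    for iv in intervals:
        tr = traces[iv]
        p1, p2 = _pulse_peaks(tr, onset1=0.0, onset2=iv)
        if p1 == 0:
            raise FitError(f"unresolved first pulse at interval {iv}")
        ratios.append(p2 / p1)
    ratios = np.array(ratios)
    curve = RecoveryCurve(intervals=intervals, ratios=ratios)
    if fit and intervals.size >= 3 and ratios.min() < 0.97:
        def model(dt, d, tau):
            return 1.0 - d * np.exp(-dt / tau)
        try:
            popt, _ = curve_fit(model, intervals, ratios,
                                p0=[1 - ratios.min(), np.median(intervals)],
                                bounds=([0, 1e-4], [1.5, 1e3]), maxfev=5000)
            curve.d, curve.tau_rec = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass
    return curve
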
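"""Shared signal types, Bessel filtering, baseline handling, and sweep/event I/O.

Conventions used package-wide: current in pA with inward currents negative,
event timestamps in seconds, kinetic time constants in milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal


class InvalidFilterError(ValueError):
    """Filter specification incompatible with the trace sampling rate."""


class SweepParseError(ValueError):
    """A sweep or event file failed to parse."""


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled current record.

    Parameters
    ----------
    samples : ndarray
        Current in pA; inward currents are negative.
    rate : float
        Sampling frequency in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def slice(self, t_start: float, t_end: float) -> "Trace":
        """Extract the sub-trace covering [t_start, t_end)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.rate - 1e-9)))
        i1 = min(self.samples.size, int(np.ceil((t_end - self.t0) * self.rate - 1e-9)))
        if i1 - i0 < 2:
            raise ValueError("requested slice contains fewer than 2 samples")
        return Trace(self.samples[i0:i1], self.rate, self.t0 + i0 / self.rate)


@dataclass
class SweepSet:
    """An ordered collection of sweeps sharing one sampling rate."""

    traces: list[Trace]
    labels: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        rates = {t.rate for t in self.traces}
        if len(rates) > 1:
            raise ValueError(f"sweeps have mixed sampling rates: {sorted(rates)}")
        if not self.labels:
            self.labels = [{} for _ in self.traces]
        if len(self.labels) != len(self.traces):
            raise ValueError("labels and traces must have equal length")

    def __len__(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class FilterSpec:
    """A low-pass Bessel filter specification (cutoff in Hz)."""

    cutoff: float
    poles: int = 4
    kind: str = "bessel"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise InvalidFilterError(f"cutoff must be positive, got {self.cutoff}")
        if self.poles not in (4, 8):
            raise InvalidFilterError(f"poles must be 4 or 8, got {self.poles}")
        if self.kind != "bessel":
            raise InvalidFilterError(f"only 'bessel' filters are supported, got {self.kind!r}")


def bessel_sos(spec: FilterSpec, rate: float) -> np.ndarray:
    """Second-order sections for an analogue-prototype Bessel low-pass.

    The analogue design is discretized by the bilinear transform with
    frequency pre-warping so the -3 dB point lands on ``spec.cutoff``.
    """
    if spec.cutoff >= rate / 2:
        raise InvalidFilterError(
            f"cutoff {spec.cutoff} Hz is at or above Nyquist ({rate / 2} Hz)"
        )
    return signal.bessel(spec.poles, spec.cutoff, btype="low", norm="mag",
                         output="sos", fs=rate)


def bessel_filter(trace: Trace, spec: FilterSpec, zero_phase: bool = False) -> Trace:
    """Low-pass Bessel filter a trace.

    Causal (single-pass) by default, matching acquisition hardware; pass
    ``zero_phase=True`` for forward-backward filtering in offline feature
    extraction where group delay matters.
    """
    sos = bessel_sos(spec, trace.rate)
    if zero_phase:
        out = signal.sosfiltfilt(sos, trace.samples)
    else:
        # steady-state initial conditions so a constant input maps to itself
        zi = signal.sosfilt_zi(sos) * trace.samples[0]
        out, _ = signal.sosfilt(sos, trace.samples, zi=zi)
    return Trace(out, trace.rate, trace.t0)


def subtract_baseline(trace: Trace, window: tuple[float, float]) -> Trace:
    """Subtract the mean current over a time window (seconds, absolute)."""
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError(f"empty baseline window ({t_start}, {t_end})")
    i0 = int(np.ceil((t_start - trace.t0) * trace.rate - 1e-9))
    i1 = int(np.ceil((t_end - trace.t0) * trace.rate - 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, trace.samples.size)
    if i1 <= i0:
        raise ValueError("baseline window lies outside the trace extent")
    return Trace(trace.samples - trace.samples[i0:i1].mean(), trace.rate, trace.t0)


# ---------------------------------------------------------------------------
# Sweep and event-table I/O
#
# Sweep files are two-column (time_s, current_pA) TSV/CSV with one header
# line; a multi-sweep set is one file per sweep plus a JSON manifest.
# ---------------------------------------------------------------------------

SWEEP_COLUMNS = ["time_s", "current_pA"]


def write_sweep(trace: Trace, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame({"time_s": trace.times, "current_pA": trace.samples})
    df.to_csv(path, sep=sep, index=False, float_format="%.9g")


def read_sweep(path: str | Path, sep: str | None = None) -> Trace:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SweepParseError(f"{path}: {exc}") from exc
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise SweepParseError(f"{path}: missing required column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    y = df["current_pA"].to_numpy(dtype=float)
    if t.size < 2:
        raise SweepParseError(f"{path}: fewer than 2 samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise SweepParseError(f"{path}: time column is not uniformly sampled")
    return Trace(y, 1.0 / dts[0], t[0])


def write_sweeps(sweeps: SweepSet, directory: str | Path, stem: str = "sweep") -> Path:
    """Write a SweepSet as one TSV per sweep plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, (trace, label) in enumerate(zip(sweeps.traces, sweeps.labels)):
        name = f"{stem}_{k:03d}.tsv"
        write_sweep(trace, directory / name)
        entries.append({"file": name, "label": label})
    manifest = {"rate_hz": sweeps.traces[0].rate if sweeps.traces else None,
                "sweeps": entries}
    mpath = directory / f"{stem}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_sweeps(manifest_path: str | Path) -> SweepSet:
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise SweepParseError(f"{manifest_path}: invalid JSON manifest: {exc}") from exc
    if "sweeps" not in manifest:
        raise SweepParseError(f"{manifest_path}: manifest missing 'sweeps' field")
    traces, labels = [], []
    for entry in manifest["sweeps"]:
        traces.append(read_sweep(manifest_path.parent / entry["file"]))
        labels.append(entry.get("label", {}))
    return SweepSet(traces, labels)


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise SweepParseError(f"{path}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SweepParseError(f"{path}: missing required column(s) {missing}")
    return df
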
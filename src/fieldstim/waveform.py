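"""Render event timelines into sampled voltage traces; trace I/O and charge.

A trace is the signal an oscilloscope would record across the chamber
electrodes: 0 V during gaps, ±amplitude during pulse phases.  Edges are ideal
squares by default (so analytic examples stay exact); a linear slew and a
supply-decay envelope are opt-in.  The default 1 MHz sample rate resolves the
~31 µs fast-inversion phases with ≥30 samples.

Files are two-column CSV (``time_s,voltage_v``, one header line) with a JSON
metadata sidecar ``<stem>.meta.json`` — a deliberately oscilloscope-export-
compatible format.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, ResolutionError
from .firmware import EventTimeline

__all__ = ["Trace", "render", "net_charge_vs", "write_trace", "read_trace"]

DEFAULT_SAMPLE_RATE_HZ = 1_000_000.0


@dataclass
class Trace:
    """Uniformly sampled voltage waveform."""

    sample_rate_hz: float
    samples: np.ndarray
    start_time_s: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise DomainError("sample rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz


def render(
    timeline: EventTimeline,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    amplitude_v: float = 9.0,
    slew_us: float | None = None,
    supply_decay: tuple[float, float] | None = None,
) -> Trace:
    """Sample the voltage across the electrodes for a whole session.

    The sample period must be at most half the shortest scheduled phase
    (raises :class:`ResolutionError` otherwise).  ``slew_us`` applies a linear
    ramp of that length to every level change.  ``supply_decay=(s0, s1)``
    scales the amplitude linearly from ``s0`` at session start to ``s1`` at
    session end, emulating a draining battery.
    """
    min_phase = timeline.min_phase_us()
    if math.isfinite(min_phase) and (1e6 / sample_rate_hz) > min_phase / 2.0:
        raise ResolutionError(
            f"sample period {1e6 / sample_rate_hz:g} µs exceeds half the "
            f"shortest phase ({min_phase:g} µs); raise the sample rate"
        )
    n = int(round(timeline.wall_time_us * 1e-6 * sample_rate_hz)) + 1
    v = np.zeros(n)
    for ev in timeline.events:
        d = ev.plan.durations_us
        starts_us = ev.start_us + np.concatenate(([0.0], np.cumsum(d[:-1])))
        ends_us = starts_us + d
        i0 = np.round(starts_us * 1e-6 * sample_rate_hz).astype(int)
        i1 = np.round(ends_us * 1e-6 * sample_rate_hz).astype(int)
        for a, b, p in zip(i0, i1, ev.plan.polarities):
            v[a : min(b, n)] = p * amplitude_v

    if slew_us:
        v = _apply_slew(v, slew_us, sample_rate_hz)
    if supply_decay is not None:
        s0, s1 = supply_decay
        v = v * np.linspace(s0, s1, n)

    meta = {
        "sample_rate_hz": sample_rate_hz,
        "amplitude_v": amplitude_v,
        "device_kind": timeline.device_kind,
        "settings": timeline.settings,
        "seed": timeline.seed,
    }
    return Trace(sample_rate_hz=sample_rate_hz, samples=v, metadata=meta)


def _apply_slew(v: np.ndarray, slew_us: float, fs: float) -> np.ndarray:
    """Replace every instantaneous level change with a linear ramp."""
    k = max(1, int(round(slew_us * 1e-6 * fs)))
    out = v.copy()
    changes = np.flatnonzero(np.diff(v) != 0) + 1
    for i in changes:
        lo = v[i - 1]
        hi = v[i]
        stop = min(i + k, len(v))
        ramp = np.linspace(lo, hi, stop - i + 2)[1:-1]
        out[i:stop] = ramp[: stop - i]
    return out


def net_charge_vs(trace: Trace, window: tuple[float, float] | None = None) -> float:
    """Time integral of voltage over ``window`` (s), in volt-seconds.

    A proxy for injected-charge balance: zero over a charge-balanced
    (biphasic or even-phase polyphasic) pulse.  Uses the rectangle rule,
    which is exact for ideal square traces.
    """
    t = trace.times()
    v = trace.samples
    if window is not None:
        t0, t1 = window
        sel = (t >= t0) & (t < t1)
        if not np.any(sel):
            raise DomainError("window contains no samples")
        v = v[sel]
    return float(np.sum(v) / trace.sample_rate_hz)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trace(trace: Trace, path) -> None:
    """Write ``time_s,voltage_v`` CSV plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.times(), "voltage_v": trace.samples}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = dict(trace.metadata)
    meta.update(
        {
            "sample_rate_hz": trace.sample_rate_hz,
            "start_time_s": trace.start_time_s,
            "n_samples": trace.n_samples,
        }
    )
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh)


def read_trace(path) -> Trace:
    """Read a trace CSV (and its sidecar when present); lossless round trip.

    Without a sidecar the sample rate is inferred from the time column.
    Malformed files raise :class:`ParseError` with a line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if header.split(",")[:2] != ["time_s", "voltage_v"]:
        raise ParseError(f"expected header 'time_s,voltage_v', got {header!r}", line=1)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(str(exc))
    cols = frame[["time_s", "voltage_v"]].apply(pd.to_numeric, errors="coerce")
    if cols.isna().any(axis=None):
        bad = int(np.flatnonzero(cols.isna().any(axis=1).to_numpy())[0]) + 2
        raise ParseError("non-numeric or missing value", line=bad)
    frame = cols

    meta_path = _sidecar(path)
    meta: dict = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    t = frame["time_s"].to_numpy()
    if "sample_rate_hz" in meta:
        fs = float(meta["sample_rate_hz"])
    elif len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        raise ParseError("cannot infer sample rate from a single sample")
    return Trace(
        sample_rate_hz=fs,
        samples=frame["voltage_v"].to_numpy(),
        start_time_s=float(meta.get("start_time_s", t[0] if len(t) else 0.0)),
        metadata=meta,
    )
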
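"""Oscilloscope-style verification of rendered (or recorded) traces.

Given a sampled voltage trace, this module quantizes it to three levels
(−, 0, +) with hysteresis and debouncing, interpolates edge times between
samples, segments the signal into pulses and phases, classifies each pulse
(monophasic / biphasic / polyphasic, plus the sequence-level "alternating"
label), and measures pulse, gap and intra-pulse AC-frequency statistics —
optionally as percent deviation from the nominal protocol settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .protocol import ProtocolSettings, PulseType
from .waveform import Trace

__all__ = [
    "Edge",
    "MeasuredPulse",
    "MeasurementReport",
    "detect_edges",
    "segment_and_classify",
    "classify_sequence",
    "measure_report",
    "deviation_percent",
    "write_report",
]

#: Default pulse-merge window: twice the polarity bridge's 10 µs switching
#: time, so the brief dropout during a polarity flip never splits a pulse.
DEFAULT_MERGE_WINDOW_US = 20.0


@dataclass(frozen=True)
class Edge:
    """A level transition, with time interpolated between samples."""

    time_s: float
    from_level: int
    to_level: int


@dataclass
class MeasuredPulse:
    start_s: float
    duration_ms: float
    phases: list  # [(duration_ms, sign), ...]
    classified_type: PulseType
    intra_pulse_ac_khz: float | None = None

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_ms / 1000.0


@dataclass
class MeasurementReport:
    pulses: list[MeasuredPulse] = field(default_factory=list)
    gaps_ms: list[float] = field(default_factory=list)
    sequence_type: PulseType | None = None
    summary: dict = field(default_factory=dict)
    deviations: dict | None = None

    @property
    def empty(self) -> bool:
        return not self.pulses

    def to_dict(self) -> dict:
        return {
            "n_pulses": len(self.pulses),
            "empty": self.empty,
            "sequence_type": self.sequence_type.value if self.sequence_type else None,
            "gaps_ms": self.gaps_ms,
            "summary": self.summary,
            "deviations": self.deviations,
        }


def detect_edges(
    trace: Trace, threshold_fraction: float = 0.5, debounce_samples: int = 3
) -> list[Edge]:
    """Quantize to three levels and return every level transition.

    ``threshold_fraction`` sets the hysteresis thresholds at that fraction of
    the peak |voltage|; level runs shorter than ``debounce_samples`` are
    treated as transients (this keeps optional slew ramps from chattering).
    Edge times are linearly interpolated between the bracketing samples.  A
    flat trace yields an empty list.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise DomainError("threshold_fraction must be in (0, 1)")
    v = trace.samples
    if len(v) == 0:
        return []
    vmax = float(np.max(np.abs(v)))
    if vmax == 0.0:
        return []
    thr = threshold_fraction * vmax
    raw = np.where(v > thr, 1, np.where(v < -thr, -1, 0)).astype(np.int8)

    change = np.flatnonzero(np.diff(raw) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(raw)]))
    levels = raw[starts]

    # debounce: drop interior runs shorter than the window, merging neighbours
    kept = [0]
    for k in range(1, len(levels)):
        if (ends[k] - starts[k]) < debounce_samples and k != len(levels) - 1:
            continue
        if levels[k] == levels[kept[-1]]:
            continue
        kept.append(k)

    dt = 1.0 / trace.sample_rate_hz
    t0 = trace.start_time_s
    edges: list[Edge] = []

    if levels[kept[0]] != 0:
        # trace starts mid-pulse: synthesize the opening edge at sample 0
        edges.append(Edge(t0, 0, int(levels[kept[0]])))

    for prev, cur in zip(kept, kept[1:]):
        la, lb = int(levels[prev]), int(levels[cur])
        if la == 0 or lb == 0:
            sign = lb if la == 0 else la
            target = sign * thr
        else:
            target = 0.0
        i0, i1 = ends[prev] - 1, starts[cur]
        tcross = None
        for j in range(i0, i1):
            va, vb = v[j], v[j + 1]
            if va != vb and (va - target) * (vb - target) <= 0:
                frac = (target - va) / (vb - va)
                tcross = t0 + (j + frac) * dt
                break
        if tcross is None:
            tcross = t0 + 0.5 * (i0 + i1) * dt
        edges.append(Edge(tcross, la, lb))

    if levels[kept[-1]] != 0:
        # trace ends mid-pulse: close it at the final sample
        edges.append(Edge(t0 + (len(v) - 1) * dt, int(levels[kept[-1]]), 0))

    return edges


def _segments(edges: list[Edge]) -> list[tuple[float, float, int]]:
    """Non-zero level segments (t_start, t_end, sign) implied by the edges."""
    out = []
    open_t, open_sign = None, 0
    for e in edges:
        if open_sign != 0:
            out.append((open_t, e.time_s, open_sign))
        open_sign, open_t = e.to_level, e.time_s
    return out


def _classify(phases: list[tuple[float, float]]) -> PulseType:
    if len(phases) == 1:
        return PulseType.MONOPHASIC
    if len(phases) == 2:
        (d1, s1), (d2, s2) = phases
        if s1 == -s2 and abs(d1 - d2) <= 0.05 * max(d1, d2):
            return PulseType.BIPHASIC
    return PulseType.POLYPHASIC


def segment_and_classify(
    edges: list[Edge], merge_window_us: float = DEFAULT_MERGE_WINDOW_US
) -> list[MeasuredPulse]:
    """Group non-zero segments into pulses and classify each.

    Segments separated by less than ``merge_window_us`` of zero level belong
    to the same pulse (so the ~10 µs dropout while the polarity bridge
    switches never splits a biphasic pulse).
    """
    segs = _segments(edges)
    if not segs:
        return []
    groups: list[list[tuple[float, float, int]]] = [[segs[0]]]
    for seg in segs[1:]:
        if (seg[0] - groups[-1][-1][1]) * 1e6 <= merge_window_us:
            groups[-1].append(seg)
        else:
            groups.append([seg])

    pulses = []
    for group in groups:
        phases = [((t1 - t0) * 1000.0, sign) for t0, t1, sign in group]
        start = group[0][0]
        duration_ms = (group[-1][1] - start) * 1000.0
        ptype = _classify(phases)
        ac = None
        if len(phases) >= 3:
            mean_phase_ms = duration_ms / len(phases)
            ac = 1.0 / mean_phase_ms  # kHz: inversion rate
        pulses.append(MeasuredPulse(start, duration_ms, phases, ptype, ac))
    return pulses


def classify_sequence(pulses: list[MeasuredPulse]) -> PulseType | None:
    """Sequence-level label: ALTERNATING when every pulse is single-phase and
    polarity strictly flips pulse to pulse; otherwise None."""
    if len(pulses) < 2:
        return None
    if any(len(p.phases) != 1 for p in pulses):
        return None
    signs = [p.phases[0][1] for p in pulses]
    if all(b == -a for a, b in zip(signs, signs[1:])):
        return PulseType.ALTERNATING
    return None


def deviation_percent(measured: float, nominal: float) -> float:
    """Signed percent deviation of a measured quantity from its setting."""
    if nominal <= 0:
        raise DomainError("nominal must be positive")
    return 100.0 * (measured - nominal) / nominal


def _sd(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")


def measure_report(
    trace: Trace,
    nominal: ProtocolSettings | None = None,
    threshold_fraction: float = 0.5,
    merge_window_us: float = DEFAULT_MERGE_WINDOW_US,
) -> MeasurementReport:
    """Full oscilloscope-style measurement of a trace.

    Measures every pulse and inter-pulse gap, summarizes durations,
    repetition frequency, duty cycle and intra-pulse AC frequency, and — when
    nominal settings are supplied — the percent deviation of the measured
    means from those settings.
    """
    edges = detect_edges(trace, threshold_fraction)
    pulses = segment_and_classify(edges, merge_window_us)
    if not pulses:
        return MeasurementReport()

    gaps_ms = [
        (b.start_s - a.end_s) * 1000.0 for a, b in zip(pulses, pulses[1:])
    ]
    durs = [p.duration_ms for p in pulses]
    acs = [p.intra_pulse_ac_khz for p in pulses if p.intra_pulse_ac_khz is not None]
    span_s = pulses[-1].end_s - pulses[0].start_s
    summary = {
        "n_pulses": len(pulses),
        "pulse_mean_ms": float(np.mean(durs)),
        "pulse_sd_ms": _sd(durs),
        "gap_mean_ms": float(np.mean(gaps_ms)) if gaps_ms else float("nan"),
        "gap_sd_ms": _sd(gaps_ms),
        "frequency_hz": (
            1000.0 / (float(np.mean(durs)) + float(np.mean(gaps_ms))) if gaps_ms else float("nan")
        ),
        "duty_percent": float(100.0 * sum(durs) / 1000.0 / span_s) if span_s > 0 else float("nan"),
        "ac_mean_khz": float(np.mean(acs)) if acs else None,
    }

    deviations = None
    if nominal is not None:
        deviations = {}
        plo, phi = nominal.pulse_range()
        if plo == phi:
            deviations["pulse_percent"] = deviation_percent(summary["pulse_mean_ms"], plo)
        grange = nominal.gap_range()
        if grange and grange[0] == grange[1] and gaps_ms:
            deviations["gap_percent"] = deviation_percent(summary["gap_mean_ms"], grange[0])

    return MeasurementReport(
        pulses=pulses,
        gaps_ms=gaps_ms,
        sequence_type=classify_sequence(pulses),
        summary=summary,
        deviations=deviations,
    )


def write_report(report: MeasurementReport, base_path) -> tuple[str, str]:
    """Write per-pulse TSV and summary JSON; returns the two paths."""
    base = str(base_path)
    tsv_path, json_path = base + ".tsv", base + ".json"
    rows = [
        {
            "index": i,
            "start_s": p.start_s,
            "duration_ms": p.duration_ms,
            "n_phases": len(p.phases),
            "type": p.classified_type.value,
            "ac_khz": p.intra_pulse_ac_khz,
            "gap_after_ms": report.gaps_ms[i] if i < len(report.gaps_ms) else float("nan"),
        }
        for i, p in enumerate(report.pulses)
    ]
    pd.DataFrame(
        rows,
        columns=["index", "start_s", "duration_ms", "n_phases", "type", "ac_khz", "gap_after_ms"],
    ).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return tsv_path, json_path
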
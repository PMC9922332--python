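"""Synthetic excitable-cell responder for pacing-fidelity analysis.

Converts a stimulation timeline into contraction events using three standard
ingredients of excitable-cell physiology:

* a Lapicque strength–duration threshold, ``rheobase × (1 + chronaxie/t)`` —
  a stimulus captures only if the chamber field meets the threshold for its
  pulse duration;
* an absolute refractory period — no contraction can follow another within
  it (cardiomyocytes paced with very short gaps simply stop following);
* a contraction latency (normal, truncated at zero) and optional
  quantization of contraction times to the video frame rate of the
  measurement chain (default 240 fps).

This lets pacing fidelity (mean inter-contraction interval vs. applied
pulse+gap period) be studied as a pure parameter-recovery problem, without
biological data: with a deterministic cell the deviation is exactly zero,
and stochastic latency plus frame quantization reproduce the sub-percent
deviation regime seen in real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .firmware import EventTimeline, make_rng
from .protocol import ChamberModel, ProtocolSettings, field_strength_v_per_m

__all__ = [
    "CellModel",
    "ContractionTrain",
    "IntervalStats",
    "threshold_field",
    "respond",
    "interval_stats",
]


@dataclass(frozen=True)
class CellModel:
    """Excitability parameters of the synthetic cell.

    ``frame_rate_fps=None`` disables measurement quantization;
    ``spontaneous_rate_hz`` adds a Poisson stream of unpaced contractions
    (suppressed within the refractory period).
    """

    rheobase_field_v_per_m: float = 300.0
    chronaxie_ms: float = 2.0
    refractory_ms: float = 250.0
    latency_mean_ms: float = 20.0
    latency_sd_ms: float = 5.0
    frame_rate_fps: float | None = 240.0
    spontaneous_rate_hz: float = 0.0


@dataclass
class ContractionTrain:
    """Contraction event times plus per-stimulus capture flags."""

    times_s: np.ndarray
    capture: list[bool] = field(default_factory=list)

    @property
    def n_contractions(self) -> int:
        return len(self.times_s)

    @property
    def capture_ratio(self) -> float:
        return float(np.mean(self.capture)) if self.capture else float("nan")

    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.times_s) * 1000.0


def threshold_field(duration_ms: float, cell: CellModel) -> float:
    """Lapicque strength–duration threshold in V/m.

    Approaches the rheobase for long pulses and doubles it at the chronaxie.
    """
    if duration_ms <= 0:
        raise DomainError("stimulus duration must be positive")
    return cell.rheobase_field_v_per_m * (1.0 + cell.chronaxie_ms / duration_ms)


def respond(
    timeline: EventTimeline,
    chamber: ChamberModel,
    cell: CellModel,
    seed=None,
) -> ContractionTrain:
    """Simulate the cell's contractions under a stimulation timeline.

    A stimulus captures iff the chamber field reaches the strength–duration
    threshold for its pulse duration *and* the refractory period since the
    last contraction has elapsed.  Captures contract after a latency draw;
    spontaneous contractions (if enabled) share the same refractory state.
    Reported times are optionally quantized to the frame period; the
    refractory bookkeeping uses the true (unquantized) times.
    """
    rng, _ = make_rng(seed)
    fieldstr = field_strength_v_per_m(chamber)
    wall_s = timeline.wall_time_us / 1e6

    # candidate events in time order: (time_s, kind, duration_ms)
    candidates = [
        (ev.start_us / 1e6, "stimulus", ev.plan.total_us / 1000.0) for ev in timeline.events
    ]
    if cell.spontaneous_rate_hz > 0 and wall_s > 0:
        n_spont = rng.poisson(cell.spontaneous_rate_hz * wall_s)
        for t in np.sort(rng.uniform(0.0, wall_s, size=n_spont)):
            candidates.append((float(t), "spontaneous", None))
        candidates.sort(key=lambda c: c[0])

    refr_s = cell.refractory_ms / 1000.0
    times: list[float] = []
    reported: list[float] = []
    capture: list[bool] = []
    last = -np.inf
    for t, kind, dur_ms in candidates:
        if kind == "stimulus":
            ok = fieldstr >= threshold_field(dur_ms, cell) and (t - last) >= refr_s
            capture.append(ok)
            if not ok:
                continue
            lat = max(0.0, float(rng.normal(cell.latency_mean_ms, cell.latency_sd_ms))) / 1000.0
            c = t + lat
        else:
            if (t - last) < refr_s:
                continue
            c = t
        last = c
        times.append(c)
        if cell.frame_rate_fps:
            c = round(c * cell.frame_rate_fps) / cell.frame_rate_fps
        reported.append(c)

    return ContractionTrain(times_s=np.asarray(reported), capture=capture)


@dataclass
class IntervalStats:
    mean_interval_ms: float
    sd_ms: float
    deviation_percent: float
    n_intervals: int
    ok: bool = True

    @classmethod
    def insufficient(cls) -> "IntervalStats":
        nan = float("nan")
        return cls(nan, nan, nan, 0, ok=False)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def interval_stats(train: ContractionTrain, settings: ProtocolSettings) -> IntervalStats:
    """Inter-contraction interval statistics vs. the nominal pacing period.

    The nominal period is set pulse + set gap (scalar settings).  Fewer than
    two contractions yield the insufficient-data flag rather than an error.
    """
    if train.n_contractions < 2:
        return IntervalStats.insufficient()
    plo, phi = settings.pulse_range()
    grange = settings.gap_range()
    if plo != phi or grange is None or grange[0] != grange[1]:
        raise DomainError("nominal period requires scalar pulse and gap settings")
    nominal_ms = plo + grange[0]
    iv = train.intervals_ms()
    mean = float(np.mean(iv))
    sd = float(np.std(iv, ddof=1)) if iv.size >= 2 else float("nan")
    return IntervalStats(
        mean_interval_ms=mean,
        sd_ms=sd,
        deviation_percent=100.0 * (mean - nominal_ms) / nominal_ms,
        n_intervals=int(iv.size),
    )
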
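"""Discrete-event model of the stimulator's controller firmware.

The controller realizes a protocol as a cycle of pulse → gap, with three
timing artifacts a real microcontroller cannot avoid:

* a *forced gap* — the per-cycle processing time between two pulses (mean
  24.42 ms in uniform mode, 34.59 ms in random mode for the analog build),
  absorbed into the user's gap via max() semantics, so a 1000 ms setting
  realizes ~1000.4 ms rather than 1024 ms;
* a per-phase *repolarization overhead* (~21.4 µs of polarity-inversion code)
  in polyphasic pulses, compensated by trimming the commanded duration of the
  last phase so the pulse ends exactly on time;
* a small amount of per-cycle wall time attributed to neither pulse nor gap,
  which is why logged pulse+gap sums cover only ~99.9 % of a session.

Pulse durations themselves carry no jitter — all stochasticity lives in the
gap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, SchedulingError, UsageError, ValidationError
from .logbook import PulseLog, PulseRecord
from .protocol import (
    FAST_INVERSION_PERIOD_US,
    DeviceKind,
    DeviceModel,
    Mode,
    PhaseSpec,
    ProtocolSettings,
    PulseType,
    phase_duration_us,
    validate_settings,
)

__all__ = [
    "TimingModel",
    "PhasePlan",
    "StimulusEvent",
    "EventTimeline",
    "plan_phases",
    "accumulated_trim_us",
    "draw_intervals",
    "realized_gap_ms",
    "run_session",
    "manual_session",
    "host_time_s",
    "make_rng",
]


@dataclass
class TimingModel:
    """Timing-artifact parameters of one device build.

    All durations are non-negative.  ``clock_skew_ppm`` models the linear
    drift between the device clock and a connected host computer (digital
    build); it affects only host-time conversion, never the device-side
    schedule.
    """

    forced_gap_mean_ms: dict = field(
        default_factory=lambda: {Mode.NORMAL: 24.42, Mode.RANDOM: 34.59, Mode.MANUAL: 24.42}
    )
    forced_gap_sd_ms: dict = field(
        default_factory=lambda: {Mode.NORMAL: 0.62, Mode.RANDOM: 0.64, Mode.MANUAL: 0.62}
    )
    repol_overhead_us: float = 21.4
    polarity_switch_us: float = 10.0
    fast_inversion_period_us: float = FAST_INVERSION_PERIOD_US
    gap_jitter_ms: float = 0.5
    unaccounted_cycle_ms: float = 1.0
    log_resolution_ms: int = 1
    clock_skew_ppm: float = 0.0

    @classmethod
    def for_device(cls, device: DeviceModel) -> "TimingModel":
        if device.kind is DeviceKind.DIGITAL:
            # Gap floor set by the host software's frame period, not CPU speed;
            # the faster controller leaves the last phase only insignificantly
            # shortened, modelled as a 2 µs per-phase overhead.
            return cls(
                forced_gap_mean_ms={m: 20.0 for m in Mode},
                forced_gap_sd_ms={m: 0.2 for m in Mode},
                repol_overhead_us=2.0,
                clock_skew_ppm=40.0,
            )
        return cls()

    def quiet(self) -> "TimingModel":
        """Deterministic copy: no gap jitter, fixed forced gaps."""
        t = TimingModel(
            forced_gap_mean_ms=dict(self.forced_gap_mean_ms),
            forced_gap_sd_ms={m: 0.0 for m in self.forced_gap_sd_ms},
            repol_overhead_us=self.repol_overhead_us,
            polarity_switch_us=self.polarity_switch_us,
            fast_inversion_period_us=self.fast_inversion_period_us,
            gap_jitter_ms=0.0,
            unaccounted_cycle_ms=self.unaccounted_cycle_ms,
            log_resolution_ms=self.log_resolution_ms,
            clock_skew_ppm=self.clock_skew_ppm,
        )
        return t


@dataclass
class PhasePlan:
    """Exact polarity schedule of one pulse.

    ``durations_us`` are the realized phase durations (commanded duration
    plus per-phase code overhead); they sum to the set pulse length exactly.
    ``commanded_us`` are the firmware set-points, whose last entry shows the
    trim correction.
    """

    durations_us: np.ndarray
    polarities: np.ndarray
    commanded_us: np.ndarray
    pulse_index: int = 0

    @property
    def n_phases(self) -> int:
        return len(self.durations_us)

    @property
    def total_us(self) -> float:
        return float(np.sum(self.durations_us))


@dataclass
class StimulusEvent:
    start_us: float
    plan: PhasePlan


@dataclass
class EventTimeline:
    """Ordered stimulus schedule of one session (device-clock time base)."""

    events: list[StimulusEvent]
    wall_time_us: float
    settings: dict
    device_kind: str = DeviceKind.ANALOG.value
    seed: int | None = None
    clock_skew_ppm: float = 0.0
    start_time_s: float = 0.0

    def __post_init__(self):
        starts = [e.start_us for e in self.events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("stimulus events must have strictly increasing starts")

    def min_phase_us(self) -> float:
        if not self.events:
            return math.inf
        return min(float(np.min(e.plan.durations_us)) for e in self.events)

    def to_dict(self) -> dict:
        return {
            "wall_time_us": self.wall_time_us,
            "settings": self.settings,
            "device_kind": self.device_kind,
            "seed": self.seed,
            "clock_skew_ppm": self.clock_skew_ppm,
            "start_time_s": self.start_time_s,
            "events": [
                {
                    "start_us": e.start_us,
                    "durations_us": [float(x) for x in e.plan.durations_us],
                    "polarities": [int(x) for x in e.plan.polarities],
                    "commanded_us": [float(x) for x in e.plan.commanded_us],
                    "pulse_index": e.plan.pulse_index,
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventTimeline":
        events = [
            StimulusEvent(
                start_us=ev["start_us"],
                plan=PhasePlan(
                    durations_us=np.asarray(ev["durations_us"], dtype=float),
                    polarities=np.asarray(ev["polarities"], dtype=np.int8),
                    commanded_us=np.asarray(ev["commanded_us"], dtype=float),
                    pulse_index=ev.get("pulse_index", 0),
                ),
            )
            for ev in d["events"]
        ]
        return cls(
            events=events,
            wall_time_us=d["wall_time_us"],
            settings=d.get("settings", {}),
            device_kind=d.get("device_kind", DeviceKind.ANALOG.value),
            seed=d.get("seed"),
            clock_skew_ppm=d.get("clock_skew_ppm", 0.0),
            start_time_s=d.get("start_time_s", 0.0),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "EventTimeline":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def accumulated_trim_us(n_phases: int, repol_overhead_us: float) -> float:
    """Total timing error accumulated over the polarity operations of a pulse.

    One overhead per phase: ten 1 ms phases at 21.4 µs each accumulate 214 µs.
    """
    if n_phases < 1:
        raise UsageError("a pulse has at least one phase")
    return n_phases * repol_overhead_us


def plan_phases(
    pulse_ms: int,
    pulse_type: PulseType,
    phase_us: float | None = None,
    repol_overhead_us: float = 0.0,
    base_polarity: int = 1,
    pulse_index: int = 0,
) -> PhasePlan:
    """Schedule the polarity segments of one pulse.

    MONOPHASIC (and each ALTERNATING member pulse) is a single phase at
    ``base_polarity``; the session runner flips the base polarity per pulse
    for ALTERNATING.  BIPHASIC inverts at exactly 50 %.  POLYPHASIC tiles the
    pulse with ``phase_us`` segments of alternating polarity; each realized
    phase is stretched by the per-phase code overhead, and the commanded
    duration of the last phase is trimmed by the accumulated error so the
    realized total equals the set pulse length exactly.

    Raises :class:`SchedulingError` when the trim exceeds the last phase —
    the pulse is unrealizable at this phase setting.
    """
    if base_polarity not in (1, -1):
        raise UsageError("base_polarity must be +1 or -1")
    total_us = float(pulse_ms) * 1000.0
    if total_us <= 0:
        raise UsageError("pulse length must be positive")

    if pulse_type in (PulseType.MONOPHASIC, PulseType.ALTERNATING):
        d = np.array([total_us])
        return PhasePlan(d, np.array([base_polarity], dtype=np.int8), d.copy(), pulse_index)

    if pulse_type is PulseType.BIPHASIC:
        half = total_us / 2.0
        d = np.array([half, half])
        pol = np.array([base_polarity, -base_polarity], dtype=np.int8)
        return PhasePlan(d, pol, d.copy(), pulse_index)

    # POLYPHASIC
    if phase_us is None or phase_us <= 0:
        raise UsageError("polyphasic pulses need a positive phase duration")
    n = int(math.ceil(total_us / phase_us - 1e-9))
    o = float(repol_overhead_us)
    last_cmd = total_us - (n - 1) * phase_us - n * o
    if last_cmd <= 0:
        raise SchedulingError(
            f"accumulated trim {n * o:g} µs exceeds the final phase; "
            f"{pulse_ms} ms pulse unrealizable at {phase_us:g} µs phases"
        )
    commanded = np.full(n, float(phase_us))
    commanded[-1] = last_cmd
    durations = commanded + o
    # pin the float sum to the set pulse length exactly
    durations[-1] = total_us - float(np.sum(durations[:-1]))
    pol = np.empty(n, dtype=np.int8)
    pol[0::2] = base_polarity
    pol[1::2] = -base_polarity
    return PhasePlan(durations, pol, commanded, pulse_index)


def make_rng(seed) -> tuple[np.random.Generator, int | None]:
    """Build the session RNG.  ``"entropy"`` draws a fresh OS seed (the
    resulting session is not reproducible, by design); integers reproduce."""
    if seed == "entropy" or seed is None:
        return np.random.default_rng(), None
    return np.random.default_rng(int(seed)), int(seed)


def draw_intervals(settings: ProtocolSettings, rng: np.random.Generator) -> tuple[int, int]:
    """Draw (pulse_ms, gap_ms) for the next cycle.

    RANDOM mode draws independent uniform integers on the closed ranges;
    other modes return the fixed settings unchanged.
    """
    (plo, phi) = settings.pulse_range()
    grange = settings.gap_range()
    if plo > phi or (grange is not None and grange[0] > grange[1]):
        raise ConfigError("range min must not exceed max")
    if settings.mode is Mode.RANDOM:
        pulse = int(rng.integers(plo, phi + 1))
        gap = int(rng.integers(grange[0], grange[1] + 1)) if grange else 0
        return pulse, gap
    return plo, (grange[0] if grange else 0)


def realized_gap_ms(
    user_gap_ms: float, mode: Mode, timing: TimingModel, rng: np.random.Generator
) -> tuple[float, float]:
    """Realize one inter-pulse gap; returns ``(realized_ms, forced_ms)``.

    The forced gap (controller processing time) is drawn from a normal
    truncated at zero and *absorbed* into the user gap: the realized gap is
    max(user, forced) plus a half-normal scheduling jitter.  A 1000 ms
    setting therefore realizes ≈1000.4 ms, not 1024 ms.
    """
    forced = max(0.0, float(rng.normal(timing.forced_gap_mean_ms[mode], timing.forced_gap_sd_ms[mode])))
    jitter = abs(float(rng.normal(0.0, timing.gap_jitter_ms))) if timing.gap_jitter_ms > 0 else 0.0
    return max(float(user_gap_ms), forced) + jitter, forced


def _phase_setting(settings: ProtocolSettings, device: DeviceModel, timing: TimingModel):
    """(phase_us, overhead_us, logged phase value) for the current protocol."""
    if settings.pulse_type is not PulseType.POLYPHASIC:
        return None, 0.0, float("nan")
    phase = phase_duration_us(settings, device, timing.fast_inversion_period_us)
    if device.phase_spec is PhaseSpec.MULTIPLIER:
        logged = float(settings.phase_multiplier)
        # multiplier 0 = fast inversion loop: its period *is* the
        # overhead-limited rate, so no extra per-phase charge applies
        overhead = 0.0 if settings.phase_multiplier == 0 else timing.repol_overhead_us
    else:
        logged = float(phase)
        overhead = timing.repol_overhead_us
    return phase, overhead, logged


def run_session(
    settings: ProtocolSettings,
    device: DeviceModel | None = None,
    timing: TimingModel | None = None,
    stop_pulses: int | None = None,
    stop_seconds: float | None = None,
    seed=None,
) -> tuple[EventTimeline, PulseLog]:
    """Run a NORMAL or RANDOM session and return its timeline and log.

    Stops after ``stop_pulses`` pulses or once wall time reaches
    ``stop_seconds`` (whichever is given; both fall back to the settings).
    Identical settings and integer seed give bit-identical output.
    """
    device = device or DeviceModel.analog()
    timing = timing or TimingModel.for_device(device)
    result = validate_settings(settings, device)
    if not result.ok:
        raise ValidationError(result.violations)
    if settings.mode is Mode.MANUAL:
        raise UsageError("use manual_session() for manually triggered pulses")

    if stop_pulses is None:
        stop_pulses = settings.stop_pulses
    if stop_seconds is None:
        stop_seconds = settings.stop_seconds
    if stop_pulses is None and stop_seconds is None:
        raise ConfigError("a stop condition (pulse count or duration) is required")

    rng, used_seed = make_rng(seed if seed is not None else settings.seed)
    phase_us, overhead, logged_phase = _phase_setting(settings, device, timing)

    events: list[StimulusEvent] = []
    records: list[PulseRecord] = []
    plan_cache: dict[tuple, PhasePlan] = {}
    t_us = 0.0
    cum_pulse_us = 0  # integer µs: pulses are integer ms with no jitter
    cum_gap_us = 0.0
    pol = 1
    i = 0
    while True:
        if stop_pulses is not None and i >= stop_pulses:
            break
        if stop_seconds is not None and t_us >= stop_seconds * 1e6:
            break
        pulse_ms, gap_ms = draw_intervals(settings, rng)
        key = (pulse_ms, pol)
        plan = plan_cache.get(key)
        if plan is None:
            plan = plan_phases(pulse_ms, settings.pulse_type, phase_us, overhead, pol)
            plan_cache[key] = plan
        events.append(StimulusEvent(start_us=t_us, plan=plan))
        t_us += pulse_ms * 1000.0
        cum_pulse_us += pulse_ms * 1000
        realized_gap, forced = realized_gap_ms(gap_ms, settings.mode, timing, rng)
        t_us += realized_gap * 1000.0 + timing.unaccounted_cycle_ms * 1000.0
        cum_gap_us += realized_gap * 1000.0
        records.append(
            PulseRecord(
                index=i,
                mode=settings.mode.value,
                type=settings.pulse_type.value,
                set_pulse_ms=pulse_ms,
                realized_pulse_ms=pulse_ms,
                set_gap_ms=float(gap_ms),
                realized_gap_ms=float(round(realized_gap / timing.log_resolution_ms) * timing.log_resolution_ms),
                forced_gap_ms=round(forced, 3),
                phase=logged_phase,
                cum_pulse_s=cum_pulse_us / 1e6,
                cum_gap_s=cum_gap_us / 1e6,
                wall_time_s=t_us / 1e6,
            )
        )
        if settings.pulse_type is PulseType.ALTERNATING:
            pol = -pol
        i += 1

    timeline = EventTimeline(
        events=events,
        wall_time_us=t_us,
        settings=settings.to_dict(),
        device_kind=device.kind.value,
        seed=used_seed,
        clock_skew_ppm=timing.clock_skew_ppm if device.kind is DeviceKind.DIGITAL else 0.0,
    )
    return timeline, PulseLog(records, meta={"seed": used_seed})


def manual_session(
    trigger_times_s: Sequence[float],
    pulse_ms: int,
    pulse_type: PulseType = PulseType.MONOPHASIC,
    timing: TimingModel | None = None,
    device: DeviceModel | None = None,
    phase_us: float | None = None,
    seed=None,
) -> tuple[EventTimeline, PulseLog]:
    """Apply one pulse per push-button trigger.

    Triggers arriving while a pulse or its forced gap is still running are
    dropped (and counted in ``log.meta['dropped_triggers']``).
    """
    device = device or DeviceModel.analog()
    timing = timing or TimingModel.for_device(device)
    triggers = [float(t) for t in trigger_times_s]
    if any(b <= a for a, b in zip(triggers, triggers[1:])):
        raise ConfigError("trigger times must be strictly increasing")
    rng, used_seed = make_rng(seed)

    if pulse_type is PulseType.POLYPHASIC and phase_us is None:
        raise UsageError("polyphasic manual pulses need phase_us")
    overhead = timing.repol_overhead_us if pulse_type is PulseType.POLYPHASIC else 0.0

    events: list[StimulusEvent] = []
    records: list[PulseRecord] = []
    dropped = 0
    blocked_until_us = -math.inf
    cum_pulse_us = 0
    pol = 1
    t_end = 0.0
    for trig_s in triggers:
        t_us = trig_s * 1e6
        if t_us < blocked_until_us:
            dropped += 1
            continue
        plan = plan_phases(pulse_ms, pulse_type, phase_us, overhead, pol)
        events.append(StimulusEvent(start_us=t_us, plan=plan))
        forced = max(
            0.0,
            float(rng.normal(timing.forced_gap_mean_ms[Mode.MANUAL], timing.forced_gap_sd_ms[Mode.MANUAL])),
        )
        blocked_until_us = t_us + pulse_ms * 1000.0 + forced * 1000.0
        t_end = blocked_until_us
        cum_pulse_us += pulse_ms * 1000
        records.append(
            PulseRecord(
                index=len(records),
                mode=Mode.MANUAL.value,
                type=pulse_type.value,
                set_pulse_ms=pulse_ms,
                realized_pulse_ms=pulse_ms,
                set_gap_ms=float("nan"),
                realized_gap_ms=float("nan"),
                forced_gap_ms=round(forced, 3),
                phase=float("nan"),
                cum_pulse_s=cum_pulse_us / 1e6,
                cum_gap_s=0.0,
                wall_time_s=t_end / 1e6,
            )
        )
        if pulse_type is PulseType.ALTERNATING:
            pol = -pol

    timeline = EventTimeline(
        events=events,
        wall_time_us=t_end,
        settings={"mode": Mode.MANUAL.value, "pulse_type": pulse_type.value, "pulse_ms": pulse_ms},
        device_kind=device.kind.value,
        seed=used_seed,
    )
    return timeline, PulseLog(records, meta={"dropped_triggers": dropped, "seed": used_seed})


def host_time_s(device_time_s: float, clock_skew_ppm: float) -> float:
    """Convert device-clock time to host-clock time under linear skew."""
    return device_time_s * (1.0 + clock_skew_ppm * 1e-6)
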
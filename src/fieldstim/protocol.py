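"""Stimulation-protocol settings, device limits and derived quantities.

A field stimulator applies rectangular voltage pulses across a pair of
electrodes immersed in the sample bath.  A protocol is described by a pulsing
*mode* (uniform, randomized, or manually triggered), a *pulse type* (how
polarity behaves within and across pulses), pulse and gap durations in
milliseconds, and — for polyphasic pulses — the repolarization (phase)
duration.  Two device generations are modelled: an ``ANALOG`` front panel
whose polyphasic phase is set as an integer millisecond "phase multiplier",
and a ``DIGITAL`` build whose phase is set directly in microseconds.

This module owns settings validation against per-mode device limits and the
small analytic conversions a protocol implies: stimulation frequency, electric
field strength in the sample chamber, and the intra-pulse AC frequency of
polyphasic pulses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import DomainError, UsageError

__all__ = [
    "PulseType",
    "Mode",
    "DeviceKind",
    "PhaseSpec",
    "Limits",
    "DeviceModel",
    "ProtocolSettings",
    "ChamberModel",
    "Violation",
    "ValidationResult",
    "validate_settings",
    "stimulation_frequency_hz",
    "field_strength_v_per_m",
    "phase_duration_us",
    "ac_frequency_khz",
    "FAST_INVERSION_PERIOD_US",
]

#: Default period of the fastest polarity inversion the analog controller can
#: drive (multiplier 0), chosen so the reported AC frequency is 32 kHz.
FAST_INVERSION_PERIOD_US = 31.25


class PulseType(str, enum.Enum):
    """Polarity behaviour of the stimulus.

    MONOPHASIC: single-polarity rectangle.  BIPHASIC: polarity inverts at 50 %
    of the pulse, giving zero net charge.  ALTERNATING: monophasic pulses whose
    polarity flips from pulse to pulse.  POLYPHASIC: many inversions within one
    pulse — effectively high-frequency AC.
    """

    MONOPHASIC = "monophasic"
    BIPHASIC = "biphasic"
    ALTERNATING = "alternating"
    POLYPHASIC = "polyphasic"


class Mode(str, enum.Enum):
    NORMAL = "normal"
    RANDOM = "random"
    MANUAL = "manual"


class DeviceKind(str, enum.Enum):
    ANALOG = "analog"
    DIGITAL = "digital"


class PhaseSpec(str, enum.Enum):
    MULTIPLIER = "multiplier"
    MICROSECONDS = "microseconds"


@dataclass(frozen=True)
class Limits:
    """Closed integer ranges for pulse and gap durations, in ms."""

    pulse_ms: tuple[int, int]
    gap_ms: tuple[int, int] | None = None


@dataclass(frozen=True)
class DeviceModel:
    """Per-mode duration limits and phase semantics of a device generation."""

    kind: DeviceKind
    limits: Mapping[Mode, Limits]
    phase_spec: PhaseSpec
    phase_us_range: tuple[int, int] = (30, 1000)

    @classmethod
    def analog(cls) -> "DeviceModel":
        """Microcontroller with analog front panel; phase set as multiplier.

        Minimum gaps (24 / 34 ms) reflect the controller's per-cycle
        processing time in the respective mode.
        """
        return cls(
            kind=DeviceKind.ANALOG,
            limits={
                Mode.NORMAL: Limits(pulse_ms=(1, 100), gap_ms=(24, 2000)),
                Mode.RANDOM: Limits(pulse_ms=(1, 200), gap_ms=(34, 2000)),
                Mode.MANUAL: Limits(pulse_ms=(1, 200)),
            },
            phase_spec=PhaseSpec.MULTIPLIER,
        )

    @classmethod
    def digital(cls) -> "DeviceModel":
        """Faster build controlled from a host computer; phase set in µs.

        The 20 ms gap floor comes from the host software's 60 Hz frame
        period, not from controller speed.
        """
        return cls(
            kind=DeviceKind.DIGITAL,
            limits={
                Mode.NORMAL: Limits(pulse_ms=(1, 100), gap_ms=(20, 2000)),
                Mode.RANDOM: Limits(pulse_ms=(1, 200), gap_ms=(20, 2000)),
                Mode.MANUAL: Limits(pulse_ms=(1, 200)),
            },
            phase_spec=PhaseSpec.MICROSECONDS,
        )


def _as_range(value) -> tuple[int, int]:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return int(lo), int(hi)
    return int(value), int(value)


@dataclass
class ProtocolSettings:
    """User-facing stimulation parameters.

    ``pulse_ms`` and ``gap_ms`` are single integers in NORMAL/MANUAL mode and
    ``(min, max)`` closed ranges in RANDOM mode.  ``seed`` may be an integer
    (reproducible sessions) or the string ``"entropy"`` (seeded from OS
    entropy, deliberately non-reproducible, mirroring the hardware's
    floating-pin seeding).
    """

    mode: Mode = Mode.NORMAL
    pulse_type: PulseType = PulseType.BIPHASIC
    pulse_ms: int | tuple[int, int] = 5
    gap_ms: int | tuple[int, int] | None = 1000
    phase_multiplier: int | None = None
    phase_us: int | None = None
    amplitude_v: float = 9.0
    stop_pulses: int | None = None
    stop_seconds: float | None = None
    seed: int | str | None = 0

    def __post_init__(self):
        if isinstance(self.mode, str) and not isinstance(self.mode, Mode):
            self.mode = Mode(self.mode.lower())
        if isinstance(self.pulse_type, str) and not isinstance(self.pulse_type, PulseType):
            self.pulse_type = PulseType(self.pulse_type.lower())

    def pulse_range(self) -> tuple[int, int]:
        return _as_range(self.pulse_ms)

    def gap_range(self) -> tuple[int, int] | None:
        if self.gap_ms is None:
            return None
        return _as_range(self.gap_ms)

    def replace(self, **kw) -> "ProtocolSettings":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "pulse_type": self.pulse_type.value,
            "pulse_ms": list(self.pulse_ms) if isinstance(self.pulse_ms, (tuple, list)) else self.pulse_ms,
            "gap_ms": list(self.gap_ms) if isinstance(self.gap_ms, (tuple, list)) else self.gap_ms,
            "phase_multiplier": self.phase_multiplier,
            "phase_us": self.phase_us,
            "amplitude_v": self.amplitude_v,
            "stop_pulses": self.stop_pulses,
            "stop_seconds": self.stop_seconds,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolSettings":
        kw = dict(d)
        for key in ("pulse_ms", "gap_ms"):
            if isinstance(kw.get(key), list):
                kw[key] = tuple(kw[key])
        return cls(**kw)


@dataclass(frozen=True)
class ChamberModel:
    """Sample chamber geometry: parallel electrodes a fixed distance apart."""

    electrode_distance_m: float = 0.005
    voltage_v: float = 9.0

    def __post_init__(self):
        if self.electrode_distance_m <= 0:
            raise DomainError("electrode distance must be > 0 m")


@dataclass(frozen=True)
class Violation:
    field: str
    message: str
    allowed: str = ""

    def __str__(self) -> str:
        s = f"{self.field}: {self.message}"
        if self.allowed:
            s += f" (allowed: {self.allowed})"
        return s


@dataclass
class ValidationResult:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def _check_range(name, rng, limits, out):
    lo, hi = rng
    llo, lhi = limits
    if lo > hi:
        out.append(Violation(name, f"range min {lo} > max {hi}", f"min <= max"))
        return
    if lo < llo or hi > lhi:
        out.append(
            Violation(name, f"value {rng[0] if lo == hi else rng} outside device limits", f"[{llo}, {lhi}] ms")
        )


def validate_settings(settings: ProtocolSettings, device: DeviceModel) -> ValidationResult:
    """Check settings against the device's per-mode limits.

    Violations are returned as data, never raised: the caller (CLI, session
    runner) decides whether to refuse.  Checked: pulse and gap inside the
    per-mode ranges, RANDOM ranges well-ordered, positive amplitude, the
    polyphasic phase parameter present / in range, and the rule that a
    polyphasic repolarization must not exceed 25 % of the shortest pulse
    (longer phases are what biphasic pulsing is for).
    """
    out: list[Violation] = []
    limits = device.limits.get(settings.mode)
    if limits is None:
        return ValidationResult([Violation("mode", f"mode {settings.mode} unsupported by device")])

    _check_range("pulse_ms", settings.pulse_range(), limits.pulse_ms, out)

    if settings.mode is not Mode.MANUAL:
        gap = settings.gap_range()
        if gap is None:
            out.append(Violation("gap_ms", "gap required in this mode"))
        elif limits.gap_ms is not None:
            _check_range("gap_ms", gap, limits.gap_ms, out)

    if settings.amplitude_v <= 0:
        out.append(Violation("amplitude_v", f"{settings.amplitude_v} V not positive", "> 0 V"))

    if settings.pulse_type is PulseType.POLYPHASIC:
        if device.phase_spec is PhaseSpec.MULTIPLIER:
            m = settings.phase_multiplier
            if m is None or m < 0:
                out.append(Violation("phase_multiplier", "non-negative integer required for polyphasic"))
                return ValidationResult(out)
        else:
            u = settings.phase_us
            lo, hi = device.phase_us_range
            if u is None:
                out.append(Violation("phase_us", "phase duration in µs required for polyphasic"))
                return ValidationResult(out)
            if not (lo <= u <= hi):
                out.append(Violation("phase_us", f"{u} µs outside range", f"[{lo}, {hi}] µs"))
                return ValidationResult(out)
        dur_us = phase_duration_us(settings, device)
        pulse_min = settings.pulse_range()[0]
        if dur_us > 250.0 * pulse_min:
            out.append(
                Violation(
                    "phase",
                    f"repolarization {dur_us:g} µs exceeds 25% of the {pulse_min} ms pulse",
                    f"<= {250.0 * pulse_min:g} µs",
                )
            )

    return ValidationResult(out)


def stimulation_frequency_hz(pulse_ms: float, gap_ms: float) -> float:
    """Pulse repetition rate, 1000 / (pulse + gap) Hz."""
    if pulse_ms <= 0 or gap_ms <= 0:
        raise DomainError("pulse and gap must be positive")
    return 1000.0 / (pulse_ms + gap_ms)


def field_strength_v_per_m(chamber: ChamberModel) -> float:
    """Electric field between the electrodes, V / d (uniform-field estimate)."""
    return chamber.voltage_v / chamber.electrode_distance_m


def phase_duration_us(
    settings: ProtocolSettings,
    device: DeviceModel,
    fast_inversion_period_us: float = FAST_INVERSION_PERIOD_US,
) -> float:
    """Repolarization (phase) duration of a polyphasic pulse, in µs.

    ANALOG devices express it as an integer multiplier in milliseconds;
    multiplier 0 means "as fast as the controller can", i.e. the fast
    inversion period.  DIGITAL devices take microseconds verbatim, clamped to
    the hardware range.
    """
    if settings.pulse_type is not PulseType.POLYPHASIC:
        raise UsageError("phase duration is defined only for polyphasic pulses")
    if device.phase_spec is PhaseSpec.MULTIPLIER:
        m = settings.phase_multiplier
        if m is None or m < 0:
            raise UsageError("phase_multiplier must be a non-negative integer")
        if m == 0:
            return float(fast_inversion_period_us)
        return m * 1000.0
    u = settings.phase_us
    if u is None:
        raise UsageError("phase_us must be set for a digital device")
    lo, hi = device.phase_us_range
    return float(min(max(u, lo), hi))


def ac_frequency_khz(phase_duration_us: float) -> float:
    """Intra-pulse AC frequency as the polarity-inversion rate, 1000/phase kHz.

    Reported as the inversion rate (not the full-cycle rate): a 30 µs phase is
    33.33 kHz and the 10 µs switching floor of the polarity bridge caps it at
    100 kHz.
    """
    if phase_duration_us <= 0:
        raise DomainError("phase duration must be positive")
    return 1000.0 / phase_duration_us
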
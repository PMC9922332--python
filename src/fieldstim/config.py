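"""Plain-text protocol configuration (``key = value``), mirroring the CLI.

Example::

    device = analog
    mode = random
    pulse_type = biphasic
    pulse_ms = 5-40
    gap_ms = 40-95
    stop_pulses = 100
    seed = 1
    timing.gap_jitter_ms = 0

Ranges use ``min-max``.  ``timing.<field>`` keys override the device's
default timing model; ``timing.forced_gap_mean_ms`` / ``..._sd_ms`` apply to
every mode.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import ConfigError
from .firmware import TimingModel
from .protocol import ChamberModel, DeviceKind, DeviceModel, Mode, ProtocolSettings

__all__ = ["RunConfig", "parse_kv", "load_config", "build_run_config", "config_hash"]

_SETTINGS_KEYS = {
    "mode",
    "pulse_type",
    "pulse_ms",
    "gap_ms",
    "phase_multiplier",
    "phase_us",
    "amplitude_v",
    "stop_pulses",
    "stop_seconds",
    "seed",
}
_SCALAR_TIMING = {
    "repol_overhead_us",
    "polarity_switch_us",
    "fast_inversion_period_us",
    "gap_jitter_ms",
    "unaccounted_cycle_ms",
    "log_resolution_ms",
    "clock_skew_ppm",
}


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    settings: ProtocolSettings
    device: DeviceModel
    timing: TimingModel
    chamber: ChamberModel
    sample_rate_hz: float = 1_000_000.0

    def snapshot(self) -> dict:
        return {
            "settings": self.settings.to_dict(),
            "device": self.device.kind.value,
            "chamber": {
                "electrode_distance_m": self.chamber.electrode_distance_m,
                "voltage_v": self.chamber.voltage_v,
            },
            "sample_rate_hz": self.sample_rate_hz,
        }


def parse_kv(text: str) -> dict[str, str]:
    """Parse ``key = value`` lines; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {ln}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ConfigError(f"line {ln}: empty key")
        out[key.lower()] = value
    return out


def load_config(path) -> dict[str, str]:
    return parse_kv(Path(path).read_text())


def _parse_duration(value: str):
    if "-" in value.strip().lstrip("-"):
        lo, hi = value.split("-", 1)
        return (int(lo), int(hi))
    return int(value)


def _parse_number(value: str):
    try:
        return int(value)
    except ValueError:
        return float(value)


def build_run_config(mapping: dict[str, str]) -> RunConfig:
    """Materialize a :class:`RunConfig` from string key/value pairs."""
    m = {k.lower(): v for k, v in mapping.items() if v is not None}

    kind = str(m.pop("device", "analog")).lower()
    try:
        device = DeviceModel.analog() if DeviceKind(kind) is DeviceKind.ANALOG else DeviceModel.digital()
    except ValueError:
        raise ConfigError(f"unknown device {kind!r} (analog|digital)")
    timing = TimingModel.for_device(device)

    skw: dict = {}
    for key in list(m):
        if key.startswith("timing."):
            fname = key.split(".", 1)[1]
            value = m.pop(key)
            if fname in _SCALAR_TIMING:
                timing = replace(timing)  # fresh copy before mutating dict fields
                setattr(timing, fname, float(value))
            elif fname == "forced_gap_mean_ms":
                timing.forced_gap_mean_ms = {mode: float(value) for mode in Mode}
            elif fname == "forced_gap_sd_ms":
                timing.forced_gap_sd_ms = {mode: float(value) for mode in Mode}
            else:
                raise ConfigError(f"unknown timing parameter {fname!r}")
            continue
        if key in _SETTINGS_KEYS:
            value = m.pop(key)
            if key in ("pulse_ms", "gap_ms"):
                skw[key] = _parse_duration(str(value)) if not isinstance(value, (int, tuple)) else value
            elif key in ("phase_multiplier", "phase_us", "stop_pulses"):
                skw[key] = int(value)
            elif key in ("amplitude_v", "stop_seconds"):
                skw[key] = float(value)
            elif key == "seed":
                skw[key] = value if value == "entropy" else int(value)
            else:
                skw[key] = str(value)

    chamber = ChamberModel(
        electrode_distance_m=float(m.pop("electrode_distance_m", 0.005)),
        voltage_v=float(skw.get("amplitude_v", 9.0)),
    )
    sample_rate = float(m.pop("sample_rate_hz", 1_000_000.0))
    if m:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(m))}")
    try:
        settings = ProtocolSettings(**skw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc))
    return RunConfig(settings=settings, device=device, timing=timing, chamber=chamber, sample_rate_hz=sample_rate)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the run configuration, embedded in outputs."""
    blob = json.dumps(config.snapshot(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
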
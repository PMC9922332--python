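import numpy as np
import pytest

from fieldstim.firmware import TimingModel, run_session
from fieldstim.protocol import DeviceModel, Mode, ProtocolSettings, PulseType


@pytest.fixture(scope="session")
def analog():
    return DeviceModel.analog()


@pytest.fixture(scope="session")
def digital():
    return DeviceModel.digital()


@pytest.fixture()
def quiet_timing():
    """No gap jitter, forced gaps fixed at their means."""
    return TimingModel().quiet()


@pytest.fixture()
def bench_timing():
    """Idealized test-bench timing: deterministic and with no unaccounted
    per-cycle time, so realized spacing equals the set pulse + gap exactly
    (like probing the output directly with an oscilloscope)."""
    t = TimingModel().quiet()
    t.unaccounted_cycle_ms = 0.0
    return t


def simulate(bench, *, mode=Mode.NORMAL, pulse_type=PulseType.BIPHASIC, pulse_ms=5,
             gap_ms=30, n=6, phase_multiplier=None, seed=0, device=None):
    """Small-session helper returning (timeline, log)."""
    settings = ProtocolSettings(
        mode=mode,
        pulse_type=pulse_type,
        pulse_ms=pulse_ms,
        gap_ms=gap_ms,
        phase_multiplier=phase_multiplier,
        stop_pulses=n,
        seed=seed,
    )
    return run_session(settings, device or DeviceModel.analog(), bench)


@pytest.fixture()
def small_session(bench_timing):
    return lambda **kw: simulate(bench_timing, **kw)
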
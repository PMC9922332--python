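"""Phase scheduling, timing-correction, random draws and session accounting."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy import stats

from fieldstim.errors import ConfigError, SchedulingError, UsageError
from fieldstim.firmware import (
    TimingModel,
    accumulated_trim_us,
    draw_intervals,
    manual_session,
    plan_phases,
    realized_gap_ms,
    run_session,
)
from fieldstim.logbook import summarize
from fieldstim.protocol import Mode, ProtocolSettings, PulseType


class TestPlanPhases:
    def test_trim_correction_worked_example(self):
        """10 ms pulse, 1 ms phases, 21.4 µs overhead: last phase commanded
        at 786 µs so the realized pulse ends exactly at 10 ms."""
        plan = plan_phases(10, PulseType.POLYPHASIC, phase_us=1000, repol_overhead_us=21.4)
        assert plan.n_phases == 10
        assert plan.commanded_us[-1] == pytest.approx(786.0, abs=1e-9)
        assert plan.durations_us[-1] == pytest.approx(786.0 + 21.4, abs=1e-9)
        assert plan.total_us == pytest.approx(10_000.0, abs=1e-9)
        assert np.all(plan.durations_us[:-1] == pytest.approx(1021.4))

    def test_biphasic_inverts_at_half(self):
        plan = plan_phases(10, PulseType.BIPHASIC)
        assert plan.durations_us.tolist() == [5000.0, 5000.0]
        assert plan.polarities.tolist() == [1, -1]

    def test_polyphasic_zero_overhead_equal_phases(self):
        plan = plan_phases(10, PulseType.POLYPHASIC, phase_us=1000, repol_overhead_us=0.0)
        assert np.all(plan.durations_us == 1000.0)
        assert plan.n_phases == 10

    def test_monophasic_single_phase(self):
        plan = plan_phases(7, PulseType.MONOPHASIC, base_polarity=-1)
        assert plan.durations_us.tolist() == [7000.0]
        assert plan.polarities.tolist() == [-1]

    def test_unrealizable_trim_raises(self):
        with pytest.raises(SchedulingError):
            plan_phases(1, PulseType.POLYPHASIC, phase_us=250, repol_overhead_us=100.0)

    @hyp_settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        pulse_ms=st.integers(1, 200),
        ptype=st.sampled_from(list(PulseType)),
        phase_frac=st.integers(4, 40),
        overhead=st.floats(0.0, 10.0),
        pol=st.sampled_from([1, -1]),
    )
    def test_conservation_and_alternation(self, pulse_ms, ptype, phase_frac, overhead, pol):
        """Phase durations always sum to the set pulse length exactly, and
        consecutive polarities differ for bi-/polyphasic pulses."""
        from hypothesis import assume

        phase_us = pulse_ms * 1000.0 / phase_frac  # respects the 25% rule
        # realizable: the accumulated trim must not consume the last phase
        assume(ptype is not PulseType.POLYPHASIC or phase_us > phase_frac * overhead)
        plan = plan_phases(pulse_ms, ptype, phase_us=phase_us, repol_overhead_us=overhead, base_polarity=pol)
        assert plan.total_us == pytest.approx(pulse_ms * 1000.0, abs=1e-6)
        if ptype in (PulseType.BIPHASIC, PulseType.POLYPHASIC):
            assert np.all(plan.polarities[1:] != plan.polarities[:-1])
        assert np.all(plan.durations_us > 0)


class TestAccumulatedTrim:
    @pytest.mark.parametrize("n, o, expected", [(10, 21.4, 214.0), (1, 21.4, 21.4), (4, 50.0, 200.0)])
    def test_examples(self, n, o, expected):
        assert accumulated_trim_us(n, o) == pytest.approx(expected)

    def test_zero_phases_rejected(self):
        with pytest.raises(UsageError):
            accumulated_trim_us(0, 21.4)


class TestDrawIntervals:
    def test_normal_mode_fixed(self):
        s = ProtocolSettings(mode=Mode.NORMAL, pulse_ms=5, gap_ms=1000)
        assert draw_intervals(s, np.random.default_rng(0)) == (5, 1000)

    def test_random_draws_stay_in_closed_ranges(self):
        s = ProtocolSettings(mode=Mode.RANDOM, pulse_ms=(5, 40), gap_ms=(40, 95))
        rng = np.random.default_rng(1)
        draws = [draw_intervals(s, rng) for _ in range(500)]
        pulses = {p for p, _ in draws}
        gaps = {g for _, g in draws}
        assert min(pulses) >= 5 and max(pulses) <= 40
        assert min(gaps) >= 40 and max(gaps) <= 95
        # closed ranges: with 500 draws the endpoints are hit
        assert {5, 40} <= pulses and {40, 95} <= gaps

    def test_degenerate_range(self):
        s = ProtocolSettings(mode=Mode.RANDOM, pulse_ms=(7, 7), gap_ms=(40, 40))
        assert draw_intervals(s, np.random.default_rng(2)) == (7, 40)

    def test_inverted_range_rejected(self):
        s = ProtocolSettings(mode=Mode.RANDOM, pulse_ms=(40, 5), gap_ms=(40, 95))
        with pytest.raises(ConfigError):
            draw_intervals(s, np.random.default_rng(0))

    def test_sample_mean_matches_uniform_expectation(self):
        """4852 pulse draws on [1, 200]: sample mean within 3 SE of 100.5."""
        s = ProtocolSettings(mode=Mode.RANDOM, pulse_ms=(1, 200), gap_ms=(34, 2000))
        rng = np.random.default_rng(42)
        pulses = np.array([draw_intervals(s, rng)[0] for _ in range(4852)])
        se = np.sqrt((200**2 - 1) / 12) / np.sqrt(4852)
        assert abs(pulses.mean() - 100.5) < 3 * se

    def test_uniformity_chi_square(self):
        """A chi-square test over 10^4 draws on [1, 200] does not reject."""
        s = ProtocolSettings(mode=Mode.RANDOM, pulse_ms=(1, 200), gap_ms=(34, 2000))
        rng = np.random.default_rng(7)
        pulses = [draw_intervals(s, rng)[0] for _ in range(10_000)]
        counts = np.bincount(pulses, minlength=201)[1:]
        assert stats.chisquare(counts).pvalue > 0.01


class TestRealizedGap:
    def test_deterministic_degenerate(self, quiet_timing):
        quiet_timing.gap_jitter_ms = 0.0
        realized, forced = realized_gap_ms(1000, Mode.NORMAL, quiet_timing, np.random.default_rng(0))
        assert realized == 1000.0
        assert forced == 24.42

    def test_forced_gap_dominates_short_settings(self, quiet_timing):
        realized, forced = realized_gap_ms(24, Mode.NORMAL, quiet_timing, np.random.default_rng(0))
        assert realized >= forced == 24.42

    def test_absorbed_model_mean(self):
        """A 1000 ms setting realizes ≈1000.4 ms on average: the forced gap is
        absorbed, only the positive scheduling jitter remains."""
        timing = TimingModel()
        rng = np.random.default_rng(3)
        draws = np.array([realized_gap_ms(1000, Mode.NORMAL, timing, rng)[0] for _ in range(4000)])
        assert np.all(draws >= 1000.0)
        assert 1000.2 < draws.mean() < 1000.6


class TestRunSession:
    def test_pulse_sum_is_exact(self, bench_timing):
        s = ProtocolSettings(mode=Mode.NORMAL, pulse_ms=5, gap_ms=1000, stop_pulses=100, seed=0)
        _, log = run_session(s, timing=bench_timing)
        assert summarize(log).pulse_sum_s == 0.5

    def test_coverage_band_default_timing(self):
        """Pulse+gap sums cover 99.8–99.95 % of wall time over 1000 cycles."""
        s = ProtocolSettings(mode=Mode.NORMAL, pulse_ms=5, gap_ms=1000, stop_pulses=1000, seed=5)
        _, log = run_session(s)
        summ = summarize(log)
        raw = 100.0 * (summ.pulse_sum_s + summ.gap_sum_s) / summ.wall_time_s
        assert 99.8 <= raw <= 99.95
        assert summ.coverage_percent == 99.9

    def test_unaccounted_cycle_accounting(self, quiet_timing):
        s = ProtocolSettings(mode=Mode.NORMAL, pulse_ms=5, gap_ms=100, stop_pulses=50, seed=1)
        _, log = run_session(s, timing=quiet_timing)
        summ = summarize(log)
        gap_s = (summ.wall_time_s - summ.pulse_sum_s - summ.gap_sum_s)
        assert gap_s == pytest.approx(50 * quiet_timing.unaccounted_cycle_ms / 1000.0, abs=1e-9)

    def test_alternating_polarity_strictly_flips(self, bench_timing):
        s = ProtocolSettings(
            mode=Mode.NORMAL, pulse_type=PulseType.ALTERNATING, pulse_ms=5, gap_ms=30,
            stop_pulses=20, seed=0,
        )
        timeline, _ = run_session(s, timing=bench_timing)
        signs = [int(ev.plan.polarities[0]) for ev in timeline.events]
        assert all(b == -a for a, b in zip(signs, signs[1:]))

    def test_zero_pulses_empty(self, bench_timing):
        s = ProtocolSettings(mode=Mode.NORMAL, pulse_ms=5, gap_ms=1000, stop_pulses=0)
        timeline, log = run_session(s, timing=bench_timing)
        assert timeline.events == [] and len(log) == 0

    def test_duration_stop(self, bench_timing):
        s = ProtocolSettings(mode=Mode.NORMAL, pulse_ms=5, gap_ms=95, stop_seconds=1.0)
        timeline, log = run_session(s, timing=bench_timing)
        assert len(log) == 10  # 100 ms per cycle
        assert timeline.wall_time_us >= 1e6

    def test_seed_determinism(self):
        s = ProtocolSettings(mode=Mode.RANDOM, pulse_ms=(1, 200), gap_ms=(34, 2000), stop_pulses=50, seed=11)
        t1, l1 = run_session(s)
        t2, l2 = run_session(s)
        assert l1.frame.equals(l2.frame)
        assert [e.start_us for e in t1.events] == [e.start_us for e in t2.events]

    def test_events_strictly_increasing_and_spaced(self, bench_timing):
        s = ProtocolSettings(mode=Mode.RANDOM, pulse_ms=(1, 50), gap_ms=(34, 100), stop_pulses=50, seed=2)
        timeline, log = run_session(s, timing=bench_timing)
        starts = np.array([e.start_us for e in timeline.events])
        gaps = log.frame["realized_gap_ms"].to_numpy() * 1000.0
        assert np.all(np.diff(starts) > 0)
        assert np.all(np.diff(starts) >= gaps[:-1])

    def test_invalid_settings_refused(self):
        from fieldstim.errors import ValidationError

        s = ProtocolSettings(mode=Mode.NORMAL, pulse_ms=5, gap_ms=10, stop_pulses=5)
        with pytest.raises(ValidationError):
            run_session(s)


class TestManualSession:
    def test_one_pulse_per_trigger(self, bench_timing):
        timeline, log = manual_session([1.0, 2.0, 3.0], 10, timing=bench_timing)
        assert len(log) == 3
        assert [e.start_us for e in timeline.events] == [1e6, 2e6, 3e6]
        assert log.meta["dropped_triggers"] == 0

    def test_trigger_inside_pulse_or_forced_gap_dropped(self, bench_timing):
        # 5 ms spacing < 10 ms pulse + 24.42 ms forced gap
        timeline, log = manual_session([1.0, 1.005, 1.050], 10, timing=bench_timing)
        assert len(log) == 2
        assert log.meta["dropped_triggers"] == 1

    def test_empty_triggers(self, bench_timing):
        timeline, log = manual_session([], 10, timing=bench_timing)
        assert len(log) == 0 and timeline.events == []

    def test_unsorted_triggers_rejected(self, bench_timing):
        with pytest.raises(ConfigError):
            manual_session([2.0, 1.0], 10, timing=bench_timing)
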
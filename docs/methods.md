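# Methods

This note documents the models behind `fieldstim`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic components do
and do not emulate.

## Device model and limits

Two device generations are modelled. The **analog** build: uniform-mode
pulses 1–100 ms with gaps 24–2000 ms, random-mode pulses 1–200 ms with gaps
34–2000 ms, manual pulses 1–200 ms; polyphasic phase set as an integer
"phase multiplier" in milliseconds, with multiplier 0 meaning the fastest
inversion the controller can drive. The **digital** build: same pulse
ranges, gap floor 20 ms in all modes (set by the host software's 60 Hz frame
period rather than controller speed), phase set directly in microseconds on
30–1000 µs. Validation is pure data: every check returns the offending field
and its allowed range; nothing raises until a session is actually started.

The quoted frequency ranges (0.5–40 Hz uniform, ≈0.45–29 Hz random) are
consequences of the pulse/gap bounds, not independent limits, and are not
enforced separately.

The polyphasic repolarization must not exceed 25 % of the (shortest) pulse;
longer phases are what biphasic pulsing is for. The rule is checked against
the minimum of a random-mode pulse range.

## Phase scheduling and the trim correction

Within a polyphasic pulse each polarity inversion costs the controller a
fixed code overhead *o* (default 21.4 µs analog, 2 µs digital), charged once
per phase. A pulse of length *T* with commanded phase *τ* therefore runs
*n* = ⌈*T*/*τ*⌉ phases whose realized durations are the commanded duration
plus *o*; the firmware compensates by trimming the commanded last phase by
the accumulated error *n·o*, so realized durations always sum to *T*
exactly. `PhasePlan` exposes both schedules: for the canonical 10 ms / 1 ms /
21.4 µs case the commanded last phase is 786 µs, the realized one 807.4 µs,
and the realized total exactly 10 ms. When the trim would consume the last
phase entirely the pulse is unrealizable and scheduling fails loudly.

Multiplier 0 (fast inversion) charges **no** extra overhead: the fast loop's
~31.25 µs period (chosen so the reported AC frequency is 32 kHz) *is* the
overhead-limited rate; charging *o* on top would make every multiplier-0
pulse unrealizable. The fast-inversion period is configurable.

Biphasic pulses invert once via the polarity bridge (~10 µs switching, far
below the millisecond bookkeeping) and are modelled with two exact halves;
bench measurements of such pulses show no systematic phase asymmetry, so no
overhead is charged there either.

"AC frequency" is reported as the polarity-inversion rate 1000/*τ* kHz (not
the full-cycle rate): 1 ms phases are 1 kHz, 30 µs phases 33.33 kHz, and the
10 µs bridge switching floor caps it at 100 kHz.

## Gap realization and session accounting

The controller needs a mode-dependent processing time between pulses — the
*forced gap*, drawn per cycle from a normal truncated at zero (defaults
24.42 ± 0.62 ms uniform, 34.59 ± 0.64 ms random; 20.0 ± 0.2 ms digital). It
is **absorbed** into the user gap — realized = max(user, forced) plus a
half-normal scheduling jitter (scale 0.5 ms) — because a 1000 ms setting
realizes ≈1000.4 ms, not 1024 ms. Pulse durations carry no jitter at all;
that is a deliberate asymmetry the device's own logs show.

Each cycle additionally consumes a fixed unaccounted time (default 1 ms)
attributed to neither pulse nor gap, which reproduces logged pulse+gap sums
covering ≈99.9 % of wall time. Per-row durations are logged at the device's
1 ms resolution while cumulative sums are carried at microsecond precision —
hence exact totals like 47.505 s from 9501 × 5 ms. Reported SDs are sample
(n−1) standard deviations.

Random-mode intervals are independent uniform integers on closed ranges.
Sessions seeded with an integer are bit-reproducible; the `"entropy"` seed
mirrors the hardware's floating-pin seeding and is deliberately not.

## Rendering and analysis

Traces are ideal square waves by default (gaps 0 V, phases ±amplitude) at
1 MHz, which resolves the ~31 µs fast phases with ≥30 samples; the renderer
refuses sample periods above half the shortest phase. A linear slew (the
bench-measured rise is ~4.5 µs) and a linear supply-decay envelope (a 9 V
block battery can sag toward 5 V) are opt-in so the analytic examples stay
exact. Net charge uses the rectangle rule — exact for square traces. An
odd-phase-count polyphasic pulse is *not* charge balanced; the toolkit
surfaces this through the charge metric rather than "fixing" it.

The analyzer quantizes to three levels at ±50 % of peak amplitude with a
3-sample debounce (robust to slew without shifting edges more than one
sample), interpolates edge times linearly between samples, and merges
non-zero segments separated by < 20 µs (twice the bridge switching time) into
one pulse. Classification: one phase → monophasic; two opposite phases equal
within 5 % → biphasic; three or more → polyphasic; "alternating" is a
sequence-level label for runs of single-phase pulses with strictly flipping
signs. Per-pulse AC frequency is 1/(mean phase duration), i.e. phase-count
over duration — exact whenever the phase divides the pulse, which is how a
multiplier is used in practice.

Measured inter-pulse gaps exceed the set gap by the unaccounted cycle time;
round-trip tests therefore either compare against the realized schedule or
use an idealized "bench" timing (no jitter, no unaccounted time), under
which simulate → render → analyze recovers every setting to within one
sample period.

## Synthetic cell

No threshold equation is available for the target preparation, so the cell
uses the standard Lapicque strength–duration law, threshold =
rheobase·(1 + chronaxie/*t*ₚ). Defaults (rheobase 300 V/m, chronaxie 2 ms)
put the usual in-vitro regime (1800 V/m, ≥9 ms biphasic pulses) comfortably
supra-threshold, and the 250 ms absolute refractory period reflects the
observation that cardiomyocytes paced with gaps below ~200 ms stop
following. A stimulus captures iff it is supra-threshold and outside
refractoriness; captures contract after a normal latency (20 ± 5 ms,
truncated at zero), optionally snapped to a 240 fps video frame grid —
modelling the measurement chain, which alone explains sub-percent interval
deviations without any biology. Spontaneous activity is an optional Poisson
stream sharing the refractory state (default off). Refractory bookkeeping
uses true times; quantization affects only reported times. Contractions are
point events — contraction waveform shape is out of scope.

## What the generator does and does not emulate

Synthetic sessions reproduce the *timing* structure of real runs (forced
gaps, trim, coverage, uniform draws) with the characterization-run means as
defaults, so passing tests show the bookkeeping and measurement chain are
faithful. They do not emulate electrode electrochemistry beyond net-charge
accounting, oscilloscope noise floors, analog potentiometer quantization or
"intermediate steps" while knobs are turned, ionic action-potential
dynamics, or biological variability — measured in-vitro deviation ranges
conflate biology with measurement and are represented here only as a
magnitude regime, not target values. The printed gap-sum of the reference
uniform-mode run is internally inconsistent with its own per-gap mean; the
log therefore surfaces raw sums *and* per-record means so the discrepancy
stays inspectable, and no test asserts that total.

## Problem sizes and numerics

Default test and acceptance runs use the reference session sizes (9501 and
4852 pulses) for log bookkeeping — cheap because only events, not samples,
are simulated — and short 4–12-pulse sessions wherever traces are rendered
at 1 MHz. Tolerances: exact identities to 1e-9; trace-derived durations to
one sample period; stochastic checks to 3 standard errors under fixed seeds.
Tie-breaks: sample indices round half to even (numpy); session base polarity
starts at +1; digital clock skew (40 ppm) is exposed only as a host-time
conversion, never applied to the device-side schedule or the fixed-header
log.
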
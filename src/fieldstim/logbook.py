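"""Per-pulse data recording and session summaries.

The device records every pulse it applies: the set and realized durations, the
forced-gap draw, and running totals.  Durations are logged at the device's
1 ms resolution while cumulative sums are kept at microsecond precision in
seconds — which is why a session of 9501 five-millisecond pulses reports a
pulse-sum of exactly 47.505 s.

The log is a TSV table with a fixed header; `PulseLog` wraps a pandas
DataFrame with exactly those columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "LOG_COLUMNS",
    "PulseRecord",
    "PulseLog",
    "SessionSummary",
    "summarize",
    "coverage_percent",
    "write_log",
    "read_log",
]

LOG_COLUMNS = [
    "index",
    "mode",
    "type",
    "set_pulse_ms",
    "realized_pulse_ms",
    "set_gap_ms",
    "realized_gap_ms",
    "forced_gap_ms",
    "phase",
    "cum_pulse_s",
    "cum_gap_s",
    "wall_time_s",
]

# Columns that must never be missing in a well-formed log row.
_REQUIRED = ["index", "mode", "type", "set_pulse_ms", "realized_pulse_ms",
             "cum_pulse_s", "cum_gap_s", "wall_time_s"]


@dataclass
class PulseRecord:
    """One logged pulse.  Durations in integer ms; cumulative sums in s."""

    index: int
    mode: str
    type: str
    set_pulse_ms: int
    realized_pulse_ms: int
    set_gap_ms: float  # NaN for manual pulses
    realized_gap_ms: float
    forced_gap_ms: float
    phase: float  # multiplier (analog) or µs (digital); NaN if not polyphasic
    cum_pulse_s: float
    cum_gap_s: float
    wall_time_s: float


class PulseLog:
    """Session log: one row per applied pulse, in application order."""

    def __init__(self, records=None, meta: dict | None = None):
        if isinstance(records, pd.DataFrame):
            missing = [c for c in LOG_COLUMNS if c not in records.columns]
            if missing:
                raise ParseError(f"missing column(s): {', '.join(missing)}")
            unknown = [c for c in records.columns if c not in LOG_COLUMNS]
            if unknown:
                raise ParseError(f"unknown column(s): {', '.join(unknown)}")
            self.frame = records.loc[:, LOG_COLUMNS].reset_index(drop=True)
        else:
            records = list(records or [])
            if records:
                self.frame = pd.DataFrame([r.__dict__ for r in records], columns=LOG_COLUMNS)
            else:
                self.frame = pd.DataFrame(columns=LOG_COLUMNS)
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield PulseRecord(**row._asdict())


@dataclass
class SessionSummary:
    """Totals and dispersion statistics for one session."""

    n_pulses: int
    pulse_sum_s: float
    gap_sum_s: float
    wall_time_s: float
    coverage_percent: float | None
    pulse_mean_ms: float = float("nan")
    pulse_sd_ms: float = float("nan")
    gap_mean_ms: float = float("nan")
    gap_sd_ms: float = float("nan")
    forced_gap_mean_ms: float = float("nan")
    forced_gap_sd_ms: float = float("nan")

    @property
    def empty(self) -> bool:
        return self.n_pulses == 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["empty"] = self.empty
        return d


def coverage_percent(pulse_sum_s: float, gap_sum_s: float, wall_time_s: float) -> float | None:
    """Share of wall time accounted for by logged pulses and gaps, in percent.

    Rounded to 0.1 %; the remainder is per-cycle processing time that the
    device attributes to neither a pulse nor a gap.  ``None`` when wall time
    is zero (empty session).
    """
    if wall_time_s <= 0:
        return None
    return round(100.0 * (pulse_sum_s + gap_sum_s) / wall_time_s, 1)


def _sd(x: np.ndarray) -> float:
    # sample (n-1) standard deviation; NaN below two observations
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1))


def summarize(log: PulseLog) -> SessionSummary:
    """Reduce a pulse log to session totals, means and SDs.

    Totals are taken from the cumulative-sum columns (µs precision), so they
    are exact even though per-row durations are logged at 1 ms resolution.
    """
    f = log.frame
    if len(f) == 0:
        return SessionSummary(0, 0.0, 0.0, 0.0, None)
    pulses = f["realized_pulse_ms"].to_numpy(dtype=float)
    gaps = f["realized_gap_ms"].to_numpy(dtype=float)
    forced = f["forced_gap_ms"].to_numpy(dtype=float)
    pulse_sum = float(f["cum_pulse_s"].iloc[-1])
    gap_sum = float(f["cum_gap_s"].iloc[-1])
    wall = float(f["wall_time_s"].iloc[-1])
    gaps_ok = gaps[~np.isnan(gaps)]
    forced_ok = forced[~np.isnan(forced)]
    return SessionSummary(
        n_pulses=len(f),
        pulse_sum_s=pulse_sum,
        gap_sum_s=gap_sum,
        wall_time_s=wall,
        coverage_percent=coverage_percent(pulse_sum, gap_sum, wall),
        pulse_mean_ms=float(np.mean(pulses)),
        pulse_sd_ms=_sd(pulses),
        gap_mean_ms=float(np.mean(gaps_ok)) if gaps_ok.size else float("nan"),
        gap_sd_ms=_sd(gaps_ok),
        forced_gap_mean_ms=float(np.mean(forced_ok)) if forced_ok.size else float("nan"),
        forced_gap_sd_ms=_sd(forced_ok),
    )


def write_log(log: PulseLog, path) -> None:
    """Write the log as TSV with the fixed column header."""
    log.frame.to_csv(path, sep="\t", index=False)


def read_log(path) -> PulseLog:
    """Read a TSV log; malformed files raise :class:`ParseError`.

    Unknown columns are named in the error; rows with missing required fields
    (e.g. a truncated last line) are reported with their line number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ParseError("empty log file")
    except pd.errors.ParserError as exc:
        raise ParseError(str(exc))
    log = PulseLog(frame)  # validates the header
    bad = log.frame[_REQUIRED].isna().any(axis=1)
    if bad.any():
        # +2: one header line, 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError("row is missing required fields (truncated?)", line=line)
    return log
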
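"""Sleep scoring: immobility, bout extraction, and sleep quantities.

The field-standard pipeline: an epoch is immobile iff its maximal velocity
is strictly below 1 mm/s; maximal runs of immobile epochs are inactivity
bouts; a bout is sleep under criterion k iff its duration is >= k seconds
(k = 300 s is the standard unitary definition, >= 1500 s marks long-bout
"deep" sleep, and [60 s, 300 s) is the short "active sleep" band).

Analysis windows use a split-and-retest rule: a bout spanning a window
boundary is clipped at the boundary and the clipped fragment is re-tested
against the criterion within its window, which keeps per-day totals
additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError
from .synthetic import VelocityTrace

__all__ = [
    "ScoringConfig",
    "Bout",
    "SleepSummary",
    "immobility_mask",
    "detect_bouts",
    "sleep_time",
    "short_sleep_time",
    "p_doze",
    "p_wake",
    "summarize",
    "dam_sleep",
    "DAMMonitor",
    "read_dam_monitor",
    "write_dam_monitor",
]

STANDARD_CRITERION_S = 300
LONG_BOUT_CRITERION_S = 1500
SHORT_SLEEP_BAND_S = (60, 300)


@dataclass(frozen=True)
class ScoringConfig:
    velocity_threshold: float = 1.0
    criterion_s: int = STANDARD_CRITERION_S
    short_sleep_band_s: tuple[int, int] = SHORT_SLEEP_BAND_S
    long_bout_criterion_s: int = LONG_BOUT_CRITERION_S
    pdoze_bin_s: int = 60
    epoch_length_s: int = 10

    def __post_init__(self) -> None:
        if self.criterion_s <= 0 or self.criterion_s % self.epoch_length_s != 0:
            raise ConfigurationError(
                f"criterion_s must be a positive multiple of {self.epoch_length_s} s")
        lo, hi = self.short_sleep_band_s
        if not 0 < lo < hi:
            raise ConfigurationError("short sleep band must satisfy 0 < low < high")
        if self.pdoze_bin_s % self.epoch_length_s != 0:
            raise ConfigurationError("pdoze_bin_s must be a multiple of the epoch length")


@dataclass(frozen=True)
class Bout:
    """A maximal run of immobile epochs, half-open [start_epoch, end_epoch)."""

    start_epoch: int
    end_epoch: int
    epoch_length_s: int = 10

    def __post_init__(self) -> None:
        if self.end_epoch <= self.start_epoch:
            raise ConfigurationError("bout must span at least one epoch")

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def clipped(self, window: tuple[int, int] | None) -> "Bout | None":
        """Intersect with an epoch window; None if disjoint."""
        if window is None:
            return self
        s = max(self.start_epoch, window[0])
        e = min(self.end_epoch, window[1])
        if e <= s:
            return None
        return Bout(s, e, self.epoch_length_s)


def immobility_mask(trace: VelocityTrace | np.ndarray,
                    cfg: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """Boolean per-epoch mask: True iff maximal velocity < threshold (strict)."""
    values = trace.values if isinstance(trace, VelocityTrace) else np.asarray(trace)
    return values < cfg.velocity_threshold


def detect_bouts(mask: np.ndarray, epoch_length_s: int = 10) -> list[Bout]:
    """Maximal runs of immobile epochs, in order, non-overlapping."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise DataError("mask must be nonempty")
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [Bout(int(s), int(e), epoch_length_s) for s, e in zip(starts, ends)]


def _check_criterion(criterion_s: float, epoch_length_s: int) -> None:
    if criterion_s <= 0 or criterion_s % epoch_length_s != 0:
        raise ConfigurationError(
            f"criterion {criterion_s} s is not a positive multiple of the "
            f"{epoch_length_s}-s epoch")


def sleep_time(bouts: list[Bout], criterion_s: int,
               window: tuple[int, int] | None = None,
               epoch_length_s: int = 10) -> float:
    """Total sleep in minutes: bouts (clipped to window) of >= criterion_s.

    Monotonically non-increasing in ``criterion_s``.
    """
    _check_criterion(criterion_s,
                     bouts[0].epoch_length_s if bouts else epoch_length_s)
    total_s = 0.0
    for b in bouts:
        c = b.clipped(window)
        if c is not None and c.duration_s >= criterion_s:
            total_s += c.duration_s
    return total_s / 60.0


def short_sleep_time(bouts: list[Bout], window: tuple[int, int] | None = None,
                     band_s: tuple[int, int] = SHORT_SLEEP_BAND_S) -> float:
    """Minutes of short ("active") sleep: bouts with 60 s <= duration < 300 s."""
    lo, hi = band_s
    total_s = 0.0
    for b in bouts:
        c = b.clipped(window)
        if c is not None and lo <= c.duration_s < hi:
            total_s += c.duration_s
    return total_s / 60.0


def _activity_bins(mask: np.ndarray, bin_s: int, epoch_length_s: int) -> np.ndarray:
    """Per-bin activity: a bin is active iff any epoch in it is mobile."""
    if bin_s % epoch_length_s != 0:
        raise ConfigurationError("bin_s must be a multiple of the epoch length")
    per = bin_s // epoch_length_s
    mask = np.asarray(mask, dtype=bool)
    n = (mask.size // per) * per
    if n == 0:
        raise DataError("need at least one full bin")
    mobile = ~mask[:n]
    return mobile.reshape(-1, per).any(axis=1)


def p_doze(mask: np.ndarray, bin_s: int = 60, epoch_length_s: int = 10) -> float | None:
    """P(doze): probability that an active bin is followed by an inactive bin.

    A conditional-probability sleep-pressure proxy.  Returns None (undefined)
    when there is no active bin with a successor.
    """
    active = _activity_bins(mask, bin_s, epoch_length_s)
    if active.size < 2:
        raise DataError("need at least two bins")
    cur, nxt = active[:-1], active[1:]
    denom = int(cur.sum())
    if denom == 0:
        return None
    return float(np.sum(cur & ~nxt) / denom)


def p_wake(mask: np.ndarray, bin_s: int = 60, epoch_length_s: int = 10) -> float | None:
    """P(wake): probability that an inactive bin is followed by an active bin."""
    active = _activity_bins(mask, bin_s, epoch_length_s)
    if active.size < 2:
        raise DataError("need at least two bins")
    cur, nxt = active[:-1], active[1:]
    denom = int((~cur).sum())
    if denom == 0:
        return None
    return float(np.sum(~cur & nxt) / denom)


@dataclass
class SleepSummary:
    """Per-fly, per-window sleep totals and bout architecture."""

    fly_id: str
    condition: str
    window: tuple[int, int]
    criterion_s: int
    total_sleep_min: float
    bout_count: int
    mean_bout_min: float | None
    short_sleep_min: float
    p_doze: float | None
    p_wake: float | None


def summarize(trace: VelocityTrace, cfg: ScoringConfig = ScoringConfig(),
              window: tuple[int, int] | None = None) -> SleepSummary:
    """Score one fly over one epoch window."""
    if window is None:
        window = (0, trace.n_epochs)
    mask = immobility_mask(trace, cfg)
    bouts = detect_bouts(mask, cfg.epoch_length_s)
    qualifying = [c for b in bouts
                  if (c := b.clipped(window)) is not None
                  and c.duration_s >= cfg.criterion_s]
    total = sum(c.duration_s for c in qualifying) / 60.0
    mean_bout = (sum(c.duration_s for c in qualifying) / len(qualifying) / 60.0
                 if qualifying else None)
    wmask = mask[window[0]:window[1]]
    return SleepSummary(
        fly_id=trace.fly_id,
        condition=trace.condition,
        window=window,
        criterion_s=cfg.criterion_s,
        total_sleep_min=total,
        bout_count=len(qualifying),
        mean_bout_min=mean_bout,
        short_sleep_min=short_sleep_time(bouts, window, cfg.short_sleep_band_s),
        p_doze=p_doze(wmask, cfg.pdoze_bin_s, cfg.epoch_length_s),
        p_wake=p_wake(wmask, cfg.pdoze_bin_s, cfg.epoch_length_s),
    )


# --------------------------------------------------------------------------
# DAM (TriKinetics) modality
# --------------------------------------------------------------------------

def dam_sleep(counts: np.ndarray, bin_s: int) -> list[Bout]:
    """Inactivity bouts from beam-crossing counts: a bin is immobile iff 0."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise DataError("beam-crossing counts must be non-negative")
    return detect_bouts(counts == 0, epoch_length_s=bin_s)


N_DAM_CHANNELS = 32
_DAM_META_COLS = 10  # index, date, time, status, 5 spare fields, light


@dataclass
class DAMMonitor:
    """Parsed TriKinetics DAM monitor file: 32 channels of counts."""

    times: list[datetime]
    counts: np.ndarray           # (n_rows, 32) int
    status: np.ndarray           # per-row status code (1 == valid)
    flagged_rows: list[tuple[int, str]] = field(default_factory=list)

    def channel(self, ch: int) -> np.ndarray:
        return self.counts[:, ch - 1]


def read_dam_monitor(path: str | Path) -> DAMMonitor:
    """Read a tab-separated TriKinetics monitor file.

    Layout per row: record index, date (``"1 Jan 24"``), time
    (``HH:MM:SS``), status code, five spare fields, light sensor, then 32
    channel counts.  Rows with a status code other than 1 are flagged but
    retained; a row with the wrong column count is a parse error naming the
    line.
    """
    times, rows, statuses, flagged = [], [], [], []
    expected = _DAM_META_COLS + N_DAM_CHANNELS
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != expected:
                raise DataError(
                    f"{path}: line {lineno}: expected {expected} tab-separated "
                    f"columns, found {len(fields)}")
            try:
                when = datetime.strptime(f"{fields[1]} {fields[2]}",
                                         "%d %b %y %H:%M:%S")
                status = int(fields[3])
                counts = [int(x) for x in fields[_DAM_META_COLS:]]
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
            if any(c < 0 for c in counts):
                raise DataError(f"{path}: line {lineno}: negative count")
            if status != 1:
                flagged.append((lineno, f"status {status}"))
            times.append(when)
            statuses.append(status)
            rows.append(counts)
    if not rows:
        raise DataError(f"{path}: no data rows")
    return DAMMonitor(times=times, counts=np.asarray(rows, dtype=np.int64),
                      status=np.asarray(statuses), flagged_rows=flagged)


def write_dam_monitor(mon: DAMMonitor, path: str | Path,
                      lights_on_h: float = 0.0, lights_off_h: float = 12.0) -> None:
    """Write a DAMMonitor back to the TriKinetics text layout."""
    with open(path, "w") as fh:
        for k, (when, row) in enumerate(zip(mon.times, mon.counts), start=1):
            light = 1 if lights_on_h <= (when.hour + when.minute / 60.0) < lights_off_h else 0
            status = int(mon.status[k - 1]) if k <= len(mon.status) else 1
            meta = [str(k), when.strftime("%d %b %y").lstrip("0"),
                    when.strftime("%H:%M:%S"), str(status), "1", "0", "0", "0",
                    "0", str(light)]
            fh.write("\t".join(meta + [str(int(c)) for c in row]) + "\n")


def dam_monitor_from_counts(counts_by_channel: np.ndarray, bin_s: int,
                            start: datetime | None = None) -> DAMMonitor:
    """Assemble a DAMMonitor from per-channel count series (channels x bins)."""
    counts_by_channel = np.atleast_2d(np.asarray(counts_by_channel))
    n_ch, n_bins = counts_by_channel.shape
    if n_ch > N_DAM_CHANNELS:
        raise DataError(f"at most {N_DAM_CHANNELS} channels")
    full = np.zeros((n_bins, N_DAM_CHANNELS), dtype=np.int64)
    full[:, :n_ch] = counts_by_channel.T
    start = start or datetime(2024, 1, 1, 0, 0, 0)
    times = [start + timedelta(seconds=bin_s * k) for k in range(n_bins)]
    return DAMMonitor(times=times, counts=full,
                      status=np.ones(n_bins, dtype=int))
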
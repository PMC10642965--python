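"""Virtual sleep-deprivation engine.

Two stimulation regimes, both coupled to live fly simulators so that every
stimulus alters subsequent behavior:

* ``fixed_interval`` -- monitor-wide vortexing: one 2-s shake at a uniformly
  random offset within every consecutive interval (20, 120, or 220 s),
  delivered to every fly in the monitor simultaneously.
* ``inactivity_triggered`` -- closed-loop tube rotation: a focal fly's tube
  is rotated for 1 s whenever its measured immobility (velocity < 1 mm/s)
  has lasted T seconds (220 s to abolish standard 5-min sleep; 1320 s to
  abolish >= 25-min long-bout sleep while sparing standard sleep).  Each
  focal fly's stimulator is bound to a paired yoked control, which receives
  identical, time-locked rotations regardless of its own state.

Timer semantics: immobile time accumulates over consecutive immobile
epochs; the trigger fires in the epoch where it first reaches T and then
resets, whether or not arousal succeeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DesignError
from .grid import DEFAULT_GRID, EpochGrid
from .synthetic import (FlySimulator, GeneratorParams, PairedDesign,
                        VelocityTrace, fly_rng)

__all__ = [
    "EngineConfig",
    "StimulusLog",
    "YokingReport",
    "run_inactivity_triggered",
    "run_fixed_interval",
    "replay_trigger_epochs",
    "verify_yoking",
]


@dataclass(frozen=True)
class EngineConfig:
    """Stimulation-regime configuration.

    ``window_start_h``/``window_h`` position the deprivation window in hours
    from the start of the simulated span (e.g. start 24 h, duration 24 h for
    one baseline day followed by a full-day deprivation).
    """

    mode: str  # "fixed_interval" | "inactivity_triggered"
    interval_s: int = 220
    shake_s: int = 2
    trigger_threshold_s: int = 220
    stimulus_duration_s: int = 1
    window_start_h: float = 24.0
    window_h: float = 24.0
    velocity_threshold: float = 1.0
    epoch_length_s: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_interval", "inactivity_triggered"):
            raise ConfigurationError(f"unknown engine mode {self.mode!r}")
        if self.mode == "inactivity_triggered":
            t = self.trigger_threshold_s
            if t <= 0 or t % self.epoch_length_s != 0:
                raise ConfigurationError(
                    f"trigger threshold {t} s must be a positive multiple of "
                    f"the {self.epoch_length_s}-s epoch")
        else:
            if self.interval_s < self.shake_s:
                raise ConfigurationError("interval_s must be >= shake_s")
        if self.window_h <= 0 or self.window_start_h < 0:
            raise ConfigurationError("deprivation window must have positive length")

    def window_epochs(self, grid: EpochGrid, n_epochs: int) -> tuple[int, int]:
        start = grid.epochs_for_hours(self.window_start_h)
        end = start + grid.epochs_for_hours(self.window_h)
        if end > n_epochs:
            raise ConfigurationError("deprivation window extends past the simulated span")
        return start, end


@dataclass
class StimulusLog:
    """Ordered stimulation epochs for one fly."""

    fly_id: str
    events: np.ndarray  # strictly increasing epoch indices
    mode: str
    trigger_source: str  # "self" | "paired_focal" | "monitor_wide"

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int64)
        if self.events.size and np.any(np.diff(self.events) <= 0):
            raise ConfigurationError("stimulus events must be strictly increasing")

    @property
    def n_events(self) -> int:
        return int(self.events.size)


def run_inactivity_triggered(
    design: PairedDesign,
    params: GeneratorParams,
    cfg: EngineConfig,
    n_days: int,
    seed: int,
    grid: EpochGrid = DEFAULT_GRID,
) -> tuple[dict[str, VelocityTrace], dict[str, StimulusLog]]:
    """Closed-loop deprivation of the focal flies with yoked binding.

    Each fly runs on its own RNG substream (identical to the one
    :func:`somnoyoke.synthetic.generate_cohort` would use, so a design with
    no stimulation reproduces the undisturbed cohort exactly).  Within the
    deprivation window, a focal fly's measured immobility drives a timer;
    when it reaches the threshold both the focal fly and its yoked partner
    are stimulated in that epoch.  Unperturbed flies receive no events.
    """
    if cfg.mode != "inactivity_triggered":
        raise ConfigurationError("engine config is not inactivity_triggered")
    ids = list(design.all_ids())
    if not ids:
        return {}, {}
    sims = {fid: FlySimulator(params, n_days, fly_rng(seed, fid), grid)
            for fid in ids}
    n_epochs = n_days * grid.epochs_per_day
    win_start, win_end = cfg.window_epochs(grid, n_epochs)
    thresh_epochs = cfg.trigger_threshold_s // cfg.epoch_length_s

    speeds = {fid: np.empty(n_epochs) for fid in ids}
    events: dict[str, list[int]] = {fid: [] for fid in ids}
    timers = {f: 0 for f, _ in design.pairs}

    for e in range(n_epochs):
        for fid in ids:
            speeds[fid][e] = sims[fid].step()
        if win_start <= e < win_end:
            for f, y in design.pairs:
                if speeds[f][e] < cfg.velocity_threshold:
                    timers[f] += 1
                else:
                    timers[f] = 0
                if timers[f] >= thresh_epochs:
                    events[f].append(e)
                    events[y].append(e)
                    timers[f] = 0
                    sims[f].stimulate()
                    sims[y].stimulate()

    traces = {fid: VelocityTrace(fly_id=fid, condition=design.condition_of(fid),
                                 grid=grid, values=speeds[fid])
              for fid in ids}
    logs = {}
    for f, y in design.pairs:
        logs[f] = StimulusLog(f, np.array(events[f]), cfg.mode, "self")
        logs[y] = StimulusLog(y, np.array(events[y]), cfg.mode, "paired_focal")
    for u in design.unperturbed_ids:
        logs[u] = StimulusLog(u, np.array([], dtype=np.int64), cfg.mode, "self")
    return traces, logs


def run_fixed_interval(
    fly_ids: list[str],
    params: GeneratorParams,
    cfg: EngineConfig,
    n_days: int,
    seed: int,
    grid: EpochGrid = DEFAULT_GRID,
    condition: str = "focal",
) -> tuple[dict[str, VelocityTrace], dict[str, StimulusLog]]:
    """Monitor-wide fixed-interval vortexing.

    Exactly one shake lands in every full interval of ``interval_s`` seconds
    inside the window, at a uniformly random offset; all flies in the run
    share the same shake epochs (a shake marks its whole 10-s epoch).
    """
    if cfg.mode != "fixed_interval":
        raise ConfigurationError("engine config is not fixed_interval")
    if len(set(fly_ids)) != len(fly_ids):
        raise DesignError("fly ids must be unique")
    sims = {fid: FlySimulator(params, n_days, fly_rng(seed, fid), grid)
            for fid in fly_ids}
    n_epochs = n_days * grid.epochs_per_day
    win_start, win_end = cfg.window_epochs(grid, n_epochs)

    # monitor-wide shake schedule, one uniform offset per full interval
    shaker = fly_rng(seed, "monitor-shaker")
    window_s = (win_end - win_start) * cfg.epoch_length_s
    n_intervals = window_s // cfg.interval_s
    offsets = shaker.uniform(0.0, cfg.interval_s - cfg.shake_s, int(n_intervals))
    shake_seconds = np.arange(n_intervals) * cfg.interval_s + offsets
    shake_epochs = np.unique(
        win_start + (shake_seconds // cfg.epoch_length_s).astype(np.int64))
    shake_set = set(int(x) for x in shake_epochs)

    speeds = {fid: np.empty(n_epochs) for fid in fly_ids}
    for e in range(n_epochs):
        for fid in fly_ids:
            speeds[fid][e] = sims[fid].step()
        if e in shake_set:
            for fid in fly_ids:
                sims[fid].stimulate()

    traces = {fid: VelocityTrace(fly_id=fid, condition=condition, grid=grid,
                                 values=speeds[fid])
              for fid in fly_ids}
    logs = {fid: StimulusLog(fid, shake_epochs.copy(), cfg.mode, "monitor_wide")
            for fid in fly_ids}
    return traces, logs


def replay_trigger_epochs(values: np.ndarray, cfg: EngineConfig,
                          window: tuple[int, int]) -> np.ndarray:
    """Epochs where the inactivity trigger would fire on a recorded trace.

    Same timer semantics as the live engine, applied post hoc: immobile time
    accumulates within the window over consecutive epochs with velocity
    below threshold, the trigger fires when it reaches the threshold, and
    the timer then resets.  Useful for replaying the closed loop against
    recorded (or already-simulated) velocity series; note a replay cannot
    alter behavior, so it matches the live engine only when arousal and
    arousal-elevation feedback are disabled.
    """
    thresh_epochs = cfg.trigger_threshold_s // cfg.epoch_length_s
    events = []
    timer = 0
    for e in range(window[0], min(window[1], len(values))):
        timer = timer + 1 if values[e] < cfg.velocity_threshold else 0
        if timer >= thresh_epochs:
            events.append(e)
            timer = 0
    return np.asarray(events, dtype=np.int64)


@dataclass
class YokingReport:
    """Regression guard for the focal->yoked stimulator binding."""

    passed: bool
    mismatched_pairs: list[tuple[str, str]] = field(default_factory=list)
    stimulated_unperturbed: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def verify_yoking(logs: dict[str, StimulusLog], design: PairedDesign) -> YokingReport:
    """Check that every pair's event lists match and controls are untouched."""
    bad_pairs = []
    for f, y in design.pairs:
        ef = logs[f].events if f in logs else None
        ey = logs[y].events if y in logs else None
        if ef is None or ey is None or not np.array_equal(ef, ey):
            bad_pairs.append((f, y))
    bad_unpert = [u for u in design.unperturbed_ids
                  if u in logs and logs[u].n_events > 0]
    return YokingReport(passed=not bad_pairs and not bad_unpert,
                        mismatched_pairs=bad_pairs,
                        stimulated_unperturbed=bad_unpert)
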
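"""Homeostatic rebound quantification.

Definitions (all per fly, all at a given inactivity criterion):

* sleep debt   = baseline-day sleep - sleep during the deprivation window;
* daily gain   = (focal post-day sleep - focal baseline sleep)
                 - (mean unperturbed post-day sleep - mean unperturbed
                 baseline sleep), i.e. the raw change corrected for the
                 unperturbed cohort's drift over the same days;
* cumulative recovery fraction on post day d = (sum of gains over days
  1..d) / debt, reported in percent; values above 100% (overshoot) are
  legitimate and expected under strong homeostatic control.

Sweeping the inactivity criterion from 1 to 30 min produces a criterion x
post-day surface of mean recovery; when rebound is concentrated in long
(>= 25 min) bouts, the surface peaks at criteria of 25 min or more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .scoring import Bout, ScoringConfig, detect_bouts, immobility_mask, sleep_time
from .synthetic import VelocityTrace

__all__ = [
    "sleep_debt",
    "normalized_gain",
    "recovery_fraction",
    "bout_architecture",
    "ReboundResult",
    "compute_rebound",
    "SweepSurface",
    "criterion_sweep",
]


def sleep_debt(baseline_min: float, deprivation_min: float) -> float:
    """Sleep lost: baseline-day sleep minus deprivation-window sleep."""
    return baseline_min - deprivation_min


def normalized_gain(focal_pre: float, focal_post: float,
                    unpert_pre: float, unpert_post: float) -> float:
    """Drift-corrected sleep gain in minutes.

    ``(focal_post - focal_pre) - (unpert_post - unpert_pre)``, with the
    unperturbed terms the cohort means for the matching days.
    """
    return (focal_post - focal_pre) - (unpert_post - unpert_pre)


def recovery_fraction(cumulative_gain_min: float, debt_min: float) -> float | None:
    """Cumulative gain as a percentage of debt; None (flagged) if debt <= 0."""
    if debt_min <= 0:
        return None
    return 100.0 * cumulative_gain_min / debt_min


def bout_architecture(bouts: list[Bout], criterion_s: int,
                      window: tuple[int, int] | None = None
                      ) -> tuple[int, float | None]:
    """(count, mean duration in minutes) of qualifying bouts in the window."""
    qual = [c for b in bouts
            if (c := b.clipped(window)) is not None and c.duration_s >= criterion_s]
    if not qual:
        return 0, None
    return len(qual), sum(c.duration_s for c in qual) / len(qual) / 60.0


@dataclass
class ReboundResult:
    """Per-fly rebound bookkeeping at one criterion."""

    fly_id: str
    condition: str
    criterion_s: int
    baseline_sleep_min: float
    deprivation_sleep_min: float
    post_sleep_min: dict[int, float]          # post day (1-based) -> minutes
    debt_min: float
    gain_raw_min: dict[int, float]
    gain_norm_min: dict[int, float]
    cumulative_gain_min: dict[int, float]
    cumulative_recovery_pct: dict[int, float | None]


def _day_sleep(trace: VelocityTrace, day: int, criterion_s: int,
               cfg: ScoringConfig) -> float:
    mask = immobility_mask(trace, cfg)
    bouts = detect_bouts(mask, cfg.epoch_length_s)
    n = trace.grid.epochs_per_day
    return sleep_time(bouts, criterion_s, window=(day * n, (day + 1) * n))


def compute_rebound(traces: dict[str, VelocityTrace], criterion_s: int,
                    baseline_day: int = 0, deprivation_day: int = 1,
                    post_days: int = 3,
                    cfg: ScoringConfig = ScoringConfig()) -> list[ReboundResult]:
    """Rebound bookkeeping for every focal and yoked fly in a cohort.

    Post-day sleep is normalized against the unperturbed cohort's mean
    day-matched change from its own baseline.
    """
    unpert = [t for t in traces.values() if t.condition == "unperturbed"]
    if not unpert:
        raise DataError("cohort contains no unperturbed flies to normalize against")
    n_days = next(iter(traces.values())).n_days
    days_post = [deprivation_day + d for d in range(1, post_days + 1)]
    if days_post and days_post[-1] >= n_days:
        raise ConfigurationError("not enough simulated days for the requested post days")

    u_base = float(np.mean([_day_sleep(t, baseline_day, criterion_s, cfg)
                            for t in unpert]))
    u_post = {d: float(np.mean([_day_sleep(t, day, criterion_s, cfg)
                                for t in unpert]))
              for d, day in enumerate(days_post, start=1)}

    results = []
    for t in traces.values():
        if t.condition == "unperturbed":
            continue
        base = _day_sleep(t, baseline_day, criterion_s, cfg)
        dep = _day_sleep(t, deprivation_day, criterion_s, cfg)
        post = {d: _day_sleep(t, day, criterion_s, cfg)
                for d, day in enumerate(days_post, start=1)}
        debt = sleep_debt(base, dep)
        raw = {d: post[d] - base for d in post}
        norm = {d: normalized_gain(base, post[d], u_base, u_post[d]) for d in post}
        cum, acc = {}, 0.0
        for d in sorted(norm):
            acc += norm[d]
            cum[d] = acc
        rec = {d: recovery_fraction(cum[d], debt) for d in cum}
        results.append(ReboundResult(
            fly_id=t.fly_id, condition=t.condition, criterion_s=criterion_s,
            baseline_sleep_min=base, deprivation_sleep_min=dep,
            post_sleep_min=post, debt_min=debt, gain_raw_min=raw,
            gain_norm_min=norm, cumulative_gain_min=cum,
            cumulative_recovery_pct=rec))
    return results


@dataclass
class SweepSurface:
    """Criterion x post-day surface of mean cumulative recovery (%)."""

    criteria_min: np.ndarray            # sorted criteria, minutes
    post_days: np.ndarray               # 1-based post days
    values: np.ndarray                  # (n_criteria, n_days) mean recovery %
    n_flies: np.ndarray                 # flies contributing per criterion
    n_excluded: np.ndarray              # flies with debt <= 0 per criterion (QC)

    def best_criterion(self, post_day: int) -> float:
        """Criterion (min) maximizing mean recovery on a given post day."""
        col = list(self.post_days).index(post_day)
        return float(self.criteria_min[int(np.nanargmax(self.values[:, col]))])

    def at(self, criterion_min: float, post_day: int) -> float:
        row = list(self.criteria_min).index(criterion_min)
        col = list(self.post_days).index(post_day)
        return float(self.values[row, col])


def criterion_sweep(traces: dict[str, VelocityTrace], criteria_min,
                    post_days: int = 3, baseline_day: int = 0,
                    deprivation_day: int = 1,
                    cfg: ScoringConfig = ScoringConfig(),
                    condition: str = "focal") -> SweepSurface:
    """Mean cumulative recovery fraction over focal flies for each
    (criterion, post day) cell; flies with debt <= 0 are excluded from the
    mean and counted in the QC column."""
    criteria_min = np.asarray(sorted(criteria_min), dtype=float)
    if criteria_min.size == 0:
        raise ConfigurationError("criteria list must be nonempty")
    days = np.arange(1, post_days + 1)
    values = np.full((criteria_min.size, days.size), np.nan)
    n_flies = np.zeros(criteria_min.size, dtype=int)
    n_excl = np.zeros(criteria_min.size, dtype=int)
    for i, cmin in enumerate(criteria_min):
        crit_s = int(round(cmin * 60))
        res = [r for r in compute_rebound(traces, crit_s, baseline_day,
                                          deprivation_day, post_days, cfg)
               if r.condition == condition]
        usable = [r for r in res if r.debt_min > 0]
        n_flies[i] = len(usable)
        n_excl[i] = len(res) - len(usable)
        if usable:
            for j, d in enumerate(days):
                values[i, j] = float(np.mean(
                    [r.cumulative_recovery_pct[int(d)] for r in usable]))
    return SweepSurface(criteria_min=criteria_min, post_days=days, values=values,
                        n_flies=n_flies, n_excluded=n_excl)
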
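"""Synthetic fly activity generator.

A discrete-time two-process-style state machine produces per-epoch maximal
velocities (mm/s, 10-s epochs) with the statistical structure fly sleep
analyses assume:

* bimodal circadian sleep propensity (midday siesta + a roughly 2x stronger
  night peak), so long-bout (>=25 min) sleep is concentrated at night;
* a homeostatic pressure integrator that accrues while awake, discharges
  while asleep, and lengthens inactivity bouts when elevated, so enforced
  waking is followed by multi-cycle rebound concentrated in long bouts;
* a post-stimulation arousal elevation, incremented by each mechanical
  stimulus and decaying exponentially, which raises locomotor speed and
  suppresses sleep onset -- the sleep-independent "masking" effect of
  mechanical perturbation;
* rest-epoch speeds strictly below the 1 mm/s immobility boundary and
  active-epoch speeds strictly above it, so scoring is never knife-edge.

Every fly draws from an independent RNG substream keyed by its id, so
cohort membership changes never perturb an individual trace.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DesignError
from .grid import DEFAULT_GRID, EpochGrid

__all__ = [
    "CircadianPropensity",
    "BoutLengthDist",
    "RestSpeedDist",
    "ActiveSpeedDist",
    "GeneratorParams",
    "VelocityTrace",
    "PairedDesign",
    "FlySimulator",
    "reference_params",
    "generate_trace",
    "generate_cohort",
    "to_dam_counts",
    "MaldiFixtureParams",
    "generate_peak_table",
    "fly_rng",
]


# --------------------------------------------------------------------------
# parameter dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CircadianPropensity:
    """Bimodal per-ZT sleep-onset propensity.

    Two raised-cosine bumps (siesta + night) on a small baseline.  The night
    amplitude should be roughly twice the siesta amplitude to reproduce the
    canonical night-dominant long-bout sleep pattern.
    """

    baseline: float = 0.01
    siesta_peak_zt: float = 6.0
    siesta_amp: float = 0.55
    siesta_halfwidth_h: float = 4.5
    night_peak_zt: float = 18.0
    night_amp: float = 0.80
    night_halfwidth_h: float = 6.5

    def validate(self) -> None:
        for name in ("baseline", "siesta_amp", "night_amp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"circadian {name} must be in [0, 1], got {v}")
        if self.siesta_halfwidth_h <= 0 or self.night_halfwidth_h <= 0:
            raise ConfigurationError("circadian bump half-widths must be positive")

    def at(self, zt: np.ndarray) -> np.ndarray:
        """Propensity in [0, 1] at ZT hours ``zt``."""
        zt = np.asarray(zt, dtype=float)
        out = np.full_like(zt, self.baseline)
        for center, amp, hw in (
            (self.siesta_peak_zt, self.siesta_amp, self.siesta_halfwidth_h),
            (self.night_peak_zt, self.night_amp, self.night_halfwidth_h),
        ):
            d = np.abs(np.mod(zt - center + 12.0, 24.0) - 12.0)  # circular distance
            bump = np.where(d < hw, amp * 0.5 * (1.0 + np.cos(np.pi * d / hw)), 0.0)
            out = out + bump
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class BoutLengthDist:
    """Heavy-tailed (lognormal) inactivity-bout duration distribution.

    Separate day/night medians put the night mode above the 25-min deep-sleep
    boundary; ``pressure_boost`` lengthens bouts drawn while homeostatic
    pressure exceeds 1, which concentrates rebound sleep in long bouts.
    """

    day_median_min: float = 7.0
    night_median_min: float = 13.5
    day_sigma_log: float = 0.75
    night_sigma_log: float = 0.60
    pressure_boost: float = 0.35
    boost_onset_pressure: float = 1.3
    max_min: float = 300.0

    def validate(self) -> None:
        if self.day_median_min < 0 or self.night_median_min < 0:
            raise ConfigurationError("bout medians must be non-negative")
        if self.day_sigma_log < 0 or self.night_sigma_log < 0:
            raise ConfigurationError("bout sigma_log values must be non-negative")
        if self.pressure_boost < 0:
            raise ConfigurationError("pressure_boost must be non-negative")


@dataclass(frozen=True)
class RestSpeedDist:
    """Speeds while inactive: uniform strictly below the 1 mm/s boundary."""

    low: float = 0.0
    high: float = 0.85

    def validate(self) -> None:
        if not 0.0 <= self.low < self.high:
            raise ConfigurationError("rest speed range must satisfy 0 <= low < high")
        if self.high >= 1.0:
            raise ConfigurationError(
                "rest speeds must lie strictly below the 1 mm/s immobility boundary"
            )


@dataclass(frozen=True)
class ActiveSpeedDist:
    """Speeds while active: 1 mm/s + a lognormal, so support is strictly >1."""

    median_excess: float = 1.5
    sigma_log: float = 0.5

    def validate(self) -> None:
        if self.median_excess <= 0:
            raise ConfigurationError("active median_excess must be positive")
        if self.sigma_log < 0:
            raise ConfigurationError("active sigma_log must be non-negative")


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic fly.

    Homeostatic pressure P is dimensionless and clipped to [0, pressure_max].
    Only *restorative* sleep discharges it: epochs of an inactivity bout
    beyond its first ``restorative_min_bout_min`` minutes, mirroring the
    premise that fragmented sub-criterion rest is not restorative.  Awake
    epochs accrue ``homeostatic_gain``; resting epochs inside a
    not-yet-consolidated bout accrue the reduced rate
    ``fragment_gain_fraction * homeostatic_gain``, so deprivation severity
    orders continuous agitation > fragmented rest > consolidated sleep.
    Sleep-onset probability per awake epoch is
    ``min(onset_cap, circadian(zt) * min(P, onset_pressure_sat))`` -- onset
    responds to pressure only up to a saturation, so severe deprivation
    expresses its rebound chiefly through longer bouts -- divided by
    ``(1 + hyperactivity_onset_penalty * h * circadian(zt))`` where h is the
    decaying, saturating (at ``hyperactivity_max``) post-stimulation
    elevation; gating the suppression by circadian drive concentrates its
    behavioral footprint at the light-to-dark transition.
    """

    circadian_propensity: CircadianPropensity = field(default_factory=CircadianPropensity)
    homeostatic_gain: float = 0.0015
    homeostatic_decay: float = 0.0014
    restorative_min_bout_min: float = 5.0
    fragment_gain_fraction: float = 0.5
    pressure_init: float = 0.9
    pressure_max: float = 12.0
    onset_cap: float = 0.10
    onset_pressure_sat: float = 1.5
    bout_length_dist: BoutLengthDist = field(default_factory=BoutLengthDist)
    rest_speed_dist: RestSpeedDist = field(default_factory=RestSpeedDist)
    active_speed_dist: ActiveSpeedDist = field(default_factory=ActiveSpeedDist)
    arousal_prob: float = 1.0
    hyperactivity_gain: float = 0.010
    hyperactivity_max: float = 2.0
    hyperactivity_halflife_h: float = 8.0
    hyperactivity_onset_penalty: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        self.circadian_propensity.validate()
        self.bout_length_dist.validate()
        self.rest_speed_dist.validate()
        self.active_speed_dist.validate()
        for name in ("arousal_prob",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if not 0.0 < self.onset_cap <= 1.0:
            raise ConfigurationError("onset_cap must be in (0, 1]")
        if self.onset_pressure_sat <= 0:
            raise ConfigurationError("onset_pressure_sat must be positive")
        if self.restorative_min_bout_min < 0:
            raise ConfigurationError("restorative_min_bout_min must be non-negative")
        if not 0.0 <= self.fragment_gain_fraction <= 1.0:
            raise ConfigurationError("fragment_gain_fraction must be in [0, 1]")
        if self.hyperactivity_max <= 0:
            raise ConfigurationError("hyperactivity_max must be positive")
        for name in ("homeostatic_gain", "homeostatic_decay", "hyperactivity_gain",
                     "hyperactivity_onset_penalty"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.pressure_max <= 0 or not 0.0 <= self.pressure_init <= self.pressure_max:
            raise ConfigurationError("pressure_init must be in [0, pressure_max]")
        if self.hyperactivity_halflife_h <= 0:
            raise ConfigurationError("hyperactivity_halflife_h must be positive")


def reference_params(**overrides) -> GeneratorParams:
    """The frozen reference parameter set used throughout tests and designs.

    These defaults were calibrated once so that unperturbed flies show a
    bimodal sleep profile with a night/day long-bout ratio near 2, and so
    that a 22-min inactivity trigger fires 12-14 times per fly per 24 h.
    """
    p = GeneratorParams(**overrides) if overrides else GeneratorParams()
    p.validate()
    return p


# --------------------------------------------------------------------------
# trace container and design
# --------------------------------------------------------------------------

CONDITIONS = ("focal", "yoked", "unperturbed")


@dataclass
class VelocityTrace:
    """Per-fly maximal-velocity series on a ZT-anchored epoch grid."""

    fly_id: str
    condition: str
    grid: EpochGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}")
        if self.values.ndim != 1:
            raise ConfigurationError("trace values must be one-dimensional")
        if len(self.values) % self.grid.epochs_per_day != 0:
            raise ConfigurationError("trace length must be a whole number of days")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ConfigurationError("velocities must be finite and >= 0")

    @property
    def n_days(self) -> int:
        return len(self.values) // self.grid.epochs_per_day

    @property
    def n_epochs(self) -> int:
        return len(self.values)

    def day_slice(self, day: int) -> slice:
        n = self.grid.epochs_per_day
        return slice(day * n, (day + 1) * n)


@dataclass(frozen=True)
class PairedDesign:
    """Focal/yoked pair assignment plus unperturbed controls."""

    pairs: tuple[tuple[str, str], ...]
    unperturbed_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = list(self.all_ids())
        if len(ids) != len(set(ids)):
            raise DesignError("fly ids must be unique across the design")

    @classmethod
    def balanced(cls, n_pairs: int, n_unperturbed: int = 0) -> "PairedDesign":
        pairs = tuple((f"focal{i:03d}", f"yoked{i:03d}") for i in range(n_pairs))
        unp = tuple(f"unpert{i:03d}" for i in range(n_unperturbed))
        return cls(pairs=pairs, unperturbed_ids=unp)

    def all_ids(self):
        for f, y in self.pairs:
            yield f
            yield y
        yield from self.unperturbed_ids

    def condition_of(self, fly_id: str) -> str:
        for f, y in self.pairs:
            if fly_id == f:
                return "focal"
            if fly_id == y:
                return "yoked"
        if fly_id in self.unperturbed_ids:
            return "unperturbed"
        raise DesignError(f"unknown fly id {fly_id!r}")


def fly_rng(master_seed: int, fly_id: str) -> np.random.Generator:
    """Independent, order-insensitive RNG substream for one fly.

    Keyed by a CRC32 of the fly id, so adding or reordering flies in a
    cohort never changes any individual fly's stream.
    """
    key = zlib.crc32(str(fly_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(key,)))


# --------------------------------------------------------------------------
# simulator
# --------------------------------------------------------------------------

class FlySimulator:
    """Steppable single-fly simulator.

    The deprivation engine drives instances epoch by epoch: :meth:`step`
    emits the next epoch's maximal velocity, and :meth:`stimulate` applies a
    mechanical stimulus whose effects (forced arousal, elevated activity)
    begin at the following epoch -- so stimuli genuinely alter subsequent
    behavior rather than being painted on post hoc.
    """

    def __init__(self, params: GeneratorParams, n_days: int,
                 rng: np.random.Generator, grid: EpochGrid = DEFAULT_GRID):
        params.validate()
        if n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        self.params = params
        self.grid = grid
        self.n_epochs = n_days * grid.epochs_per_day
        self._rng = rng
        zt = grid.zt_hours(self.n_epochs)
        self._night = grid.is_night(zt)
        self._circ = params.circadian_propensity.at(zt)
        # pre-drawn variates keep the per-epoch Python loop cheap
        self._u_onset = rng.random(self.n_epochs)
        self._rest = rng.uniform(params.rest_speed_dist.low,
                                 params.rest_speed_dist.high, self.n_epochs)
        a = params.active_speed_dist
        self._active = 1.0 + rng.lognormal(np.log(a.median_excess), a.sigma_log,
                                           self.n_epochs)
        self._hyper_decay = 0.5 ** (grid.epoch_length_s /
                                    (params.hyperactivity_halflife_h * 3600.0))
        self._restorative_epochs = int(round(
            params.restorative_min_bout_min * 60.0 / grid.epoch_length_s))
        # state
        self.i = 0
        self.awake = True
        self.pressure = params.pressure_init
        self.bout_remaining = 0
        self.bout_elapsed = 0
        self.hyper = 0.0

    # -- internals ---------------------------------------------------------

    def _draw_bout_epochs(self, epoch: int) -> int:
        d = self.params.bout_length_dist
        if self._night[epoch]:
            median, sigma = d.night_median_min, d.night_sigma_log
        else:
            median, sigma = d.day_median_min, d.day_sigma_log
        scale = 1.0 + d.pressure_boost * max(0.0, self.pressure - d.boost_onset_pressure)
        minutes = self._rng.lognormal(np.log(max(median, 1e-9)), sigma) * scale
        minutes = min(minutes, d.max_min)
        return max(1, int(round(minutes * 60.0 / self.grid.epoch_length_s)))

    @property
    def _day_median(self) -> float:
        return self.params.bout_length_dist.day_median_min

    @property
    def _night_median(self) -> float:
        return self.params.bout_length_dist.night_median_min

    # -- public stepping interface -----------------------------------------

    def step(self) -> float:
        """Advance one epoch; return its maximal velocity in mm/s."""
        if self.i >= self.n_epochs:
            raise IndexError("simulation exhausted")
        p = self.params
        i = self.i
        if self.awake:
            speed = self._active[i] + self.hyper
            self.pressure = min(p.pressure_max, self.pressure + p.homeostatic_gain)
            onset = min(p.onset_cap,
                        self._circ[i] * min(self.pressure, p.onset_pressure_sat))
            if p.hyperactivity_onset_penalty and self.hyper:
                # suppression is gated by circadian sleep drive, so the
                # behavioral footprint of stimulation concentrates at the
                # evening transition where controls fall asleep
                onset /= 1.0 + p.hyperactivity_onset_penalty * self.hyper * self._circ[i]
            if self._u_onset[i] < onset and self._day_or_night_median_positive(i):
                self.awake = False
                self.bout_remaining = self._draw_bout_epochs(i)
                self.bout_elapsed = 0
        else:
            speed = self._rest[i]
            self.bout_elapsed += 1
            if self.bout_elapsed > self._restorative_epochs:
                # consolidated sleep discharges pressure
                self.pressure = max(0.0, self.pressure - p.homeostatic_decay)
            else:
                # fragmented rest is only partly restorative: reduced accrual
                self.pressure = min(
                    p.pressure_max,
                    self.pressure + p.fragment_gain_fraction * p.homeostatic_gain)
            self.bout_remaining -= 1
            if self.bout_remaining <= 0:
                self.awake = True
        self.hyper *= self._hyper_decay
        self.i += 1
        return speed

    def _day_or_night_median_positive(self, epoch: int) -> bool:
        m = self._night_median if self._night[epoch] else self._day_median
        return m > 0.0

    def stimulate(self) -> bool:
        """Apply one mechanical stimulus; effects start at the next epoch.

        With probability ``arousal_prob`` the fly is forced awake (any
        ongoing inactivity bout ends).  The arousal elevation is always
        incremented.  Returns whether arousal occurred.
        """
        p = self.params
        if p.arousal_prob >= 1.0:
            aroused = True
        elif p.arousal_prob <= 0.0:
            aroused = False
        else:
            aroused = bool(self._rng.random() < p.arousal_prob)
        if aroused and not self.awake:
            self.awake = True
            self.bout_remaining = 0
        # saturating increment: repeated stimulation cannot elevate arousal
        # beyond hyperactivity_max, so masking is comparable across widely
        # different stimulation frequencies
        self.hyper += p.hyperactivity_gain * max(0.0, 1.0 - self.hyper / p.hyperactivity_max)
        return aroused

    def run(self) -> np.ndarray:
        """Run to completion with no external stimulation."""
        out = np.empty(self.n_epochs - self.i)
        for k in range(out.size):
            out[k] = self.step()
        return out


# --------------------------------------------------------------------------
# generation entry points
# --------------------------------------------------------------------------

def generate_trace(params: GeneratorParams, n_days: int, seed: int,
                   fly_id: str = "fly000", condition: str = "unperturbed",
                   grid: EpochGrid = DEFAULT_GRID) -> VelocityTrace:
    """Simulate one undisturbed fly for ``n_days`` days.

    Identical ``(params, n_days, seed, fly_id)`` yield bit-identical traces.
    """
    sim = FlySimulator(params, n_days, fly_rng(seed, fly_id), grid)
    return VelocityTrace(fly_id=fly_id, condition=condition, grid=grid,
                         values=sim.run())


def generate_cohort(design: PairedDesign, params: GeneratorParams, n_days: int,
                    seed: int, grid: EpochGrid = DEFAULT_GRID) -> dict[str, VelocityTrace]:
    """Simulate every fly in ``design`` undisturbed, on per-id substreams."""
    out: dict[str, VelocityTrace] = {}
    for fid in design.all_ids():
        out[fid] = generate_trace(params, n_days, seed, fly_id=fid,
                                  condition=design.condition_of(fid), grid=grid)
    return out


def to_dam_counts(trace: VelocityTrace, bin_s: int, seed: int = 0,
                  rate_per_speed: float = 0.6,
                  deterministic: bool = False) -> np.ndarray:
    """Emulate DAM infrared beam-crossing counts from a velocity trace.

    Counts per bin are Poisson with rate ``rate_per_speed`` times the bin's
    mean supra-threshold speed (epochs below the 1 mm/s immobility boundary
    contribute nothing: an immobile fly never crosses the beam), so fully
    immobile bins are exactly zero.  ``deterministic=True`` replaces the
    Poisson draw with the ceiling of the rate, guaranteeing a nonzero count
    for any bin with mobile epochs -- the noise-free conversion used for
    cross-modality consistency checks.
    """
    el = trace.grid.epoch_length_s
    if bin_s % el != 0:
        raise ConfigurationError(f"bin_s must be a multiple of the {el}-s epoch")
    if 86_400 % bin_s != 0:
        raise ConfigurationError("bin_s must divide 86400")
    per_bin = bin_s // el
    v = trace.values
    eff = np.where(v >= 1.0, v, 0.0)
    rates = rate_per_speed * eff.reshape(-1, per_bin).mean(axis=1)
    if deterministic:
        return np.ceil(rates).astype(np.int64)
    rng = fly_rng(seed, f"dam:{trace.fly_id}")
    counts = np.zeros(rates.size, dtype=np.int64)
    nz = rates > 0
    counts[nz] = rng.poisson(rates[nz])
    return counts


# --------------------------------------------------------------------------
# MALDI fixture generator
# --------------------------------------------------------------------------

MALDI_CATEGORIES = ("NS", "mechanical", "sleep_pressure", "sleep_absence", "other")


@dataclass(frozen=True)
class MaldiFixtureParams:
    """Planted-truth generator for three-condition peak-intensity tables.

    Per-category multiplicative condition effects (relative to the
    unperturbed mean, ``e`` = ``effect_size``):

    ========================  =======  ===========  ============
    category                  focal    yoked        unperturbed
    ========================  =======  ===========  ============
    NS                        1        1            1
    mechanical                e        e            1
    sleep_pressure            e        sqrt(e)      1
    sleep_absence             e        1            1
    other (lower in focal)    1/e      1            1
    ========================  =======  ===========  ============
    """

    n_peaks_per_category: dict[str, int] = field(
        default_factory=lambda: {"NS": 80, "mechanical": 73,
                                 "sleep_pressure": 8, "sleep_absence": 9,
                                 "other": 2})
    n_sections: dict[str, int] = field(
        default_factory=lambda: {"focal": 6, "yoked": 3, "unperturbed": 4})
    baseline_log_mean: float = np.log(1000.0)
    baseline_log_sd: float = 1.0
    noise_log_sd: float = 0.2
    effect_size: float = 4.0
    mz_range: tuple[float, float] = (100.0, 1300.0)
    seed: int = 0

    def validate(self) -> None:
        for cat in self.n_peaks_per_category:
            if cat not in MALDI_CATEGORIES:
                raise ConfigurationError(f"unknown planted category {cat!r}")
        if any(n < 0 for n in self.n_peaks_per_category.values()):
            raise ConfigurationError("peak counts must be non-negative")
        if any(n < 2 for n in self.n_sections.values()):
            raise ConfigurationError("need >= 2 sections per condition")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.noise_log_sd < 0 or self.baseline_log_sd < 0:
            raise ConfigurationError("log-sds must be non-negative")


_CONDITION_MULT = {
    "NS": lambda e: (1.0, 1.0, 1.0),
    "mechanical": lambda e: (e, e, 1.0),
    "sleep_pressure": lambda e: (e, float(np.sqrt(e)), 1.0),
    "sleep_absence": lambda e: (e, 1.0, 1.0),
    "other": lambda e: (1.0 / e if e > 0 else 1.0, 1.0, 1.0),
}


def generate_peak_table(fix: MaldiFixtureParams):
    """Generate a (PeakTable, truth-labels) pair with planted categories.

    Intensities are lognormal around category-structured means.  With
    ``effect_size == 1`` every condition mean is identical, so all peaks are
    generated as NS regardless of the requested labels; a warning is raised
    and the returned truth reflects the actual (null) generating process.
    """
    from .maldi import PeakTable  # local import to avoid a cycle

    fix.validate()
    rng = np.random.default_rng(np.random.SeedSequence(fix.seed, spawn_key=(0x3A1D,)))
    null_effect = fix.effect_size == 1.0
    if null_effect and any(n > 0 and c != "NS"
                           for c, n in fix.n_peaks_per_category.items()):
        warnings.warn("effect_size == 1: all planted categories collapse to NS",
                      UserWarning, stacklevel=2)

    cats: list[str] = []
    for cat in MALDI_CATEGORIES:
        cats.extend([cat] * fix.n_peaks_per_category.get(cat, 0))
    n_peaks = len(cats)
    if n_peaks == 0:
        raise ConfigurationError("fixture must contain at least one peak")
    mz = np.sort(rng.uniform(*fix.mz_range, n_peaks)).round(1)
    # keep labels unique at one-decimal resolution
    for k in range(1, n_peaks):
        if mz[k] <= mz[k - 1]:
            mz[k] = mz[k - 1] + 0.1
    order = rng.permutation(n_peaks)
    cats = [cats[k] for k in order]

    conditions = ("focal", "yoked", "unperturbed")
    section_ids, section_conditions = [], []
    for cond in conditions:
        for s in range(fix.n_sections[cond]):
            section_ids.append(f"{cond}_s{s:02d}")
            section_conditions.append(cond)

    intensities = np.empty((n_peaks, len(section_ids)))
    for p, cat in enumerate(cats):
        base = float(np.exp(rng.normal(fix.baseline_log_mean, fix.baseline_log_sd)))
        mult = dict(zip(conditions, _CONDITION_MULT[cat](fix.effect_size)))
        for s, cond in enumerate(section_conditions):
            mean = base * mult[cond]
            intensities[p, s] = mean * np.exp(rng.normal(0.0, fix.noise_log_sd))

    truth = ["NS"] * n_peaks if null_effect else list(cats)
    table = PeakTable(mz=mz, section_ids=tuple(section_ids),
                      section_conditions=tuple(section_conditions),
                      intensities=intensities)
    return table, truth
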
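# Methods

## The behavioral model

`somnoyoke` simulates single flies on a fixed 10-s epoch grid (8640 epochs
per 24-h day, anchored to Zeitgeber time with lights-on at ZT0 and
lights-off at ZT12). Each fly is a two-state (awake/asleep) discrete-time
state machine driven by two interacting processes, in the spirit of the
classical two-process account of sleep regulation:

**Circadian propensity** `C(zt) ∈ [0, 1]` is the sum of two raised-cosine
bumps on a small baseline: a midday siesta (peak ZT6, amplitude 0.55,
half-width 4.5 h) and a night peak (ZT18, amplitude 0.80, half-width
6.5 h). The night bump is deliberately stronger so that long inactivity
bouts concentrate in the dark phase.

**Homeostatic pressure** `P ∈ [0, pressure_max]` integrates sleep need.
Crucially, only *consolidated* sleep discharges it: epochs of an inactivity
bout beyond its first `restorative_min_bout_min` (default 5 min) subtract
`homeostatic_decay` (0.0014/epoch). Awake epochs add `homeostatic_gain`
(0.0015/epoch), and resting epochs inside a not-yet-consolidated bout add
the reduced rate `fragment_gain_fraction × gain` (0.5×). This ordering —
continuous agitation accrues fastest, fragmented rest accrues at half rate,
consolidated sleep discharges — is what makes the paradigm's severity
hierarchy emerge: a closed-loop-deprived focal fly (rest chopped into
sub-criterion fragments) ends a 24-h deprivation markedly more pressured
than its yoked partner (which sleeps in consolidated bouts whenever the
focal fly is active), and both more than unperturbed controls. The ceiling
`pressure_max = 12` is high enough that neither condition saturates, so the
severity difference survives to the recovery days.

**Sleep onset.** Per awake epoch the probability of initiating sleep is
`min(onset_cap, C(zt) · min(P, onset_pressure_sat))`. Pressure raises onset
probability only up to a saturation (`onset_pressure_sat = 1.5`), so severe
deprivation expresses its rebound mainly through *longer bouts* rather than
wall-to-wall sleep onset — matching the empirical picture in which rebound
is carried by long-bout ("deep") sleep. The cap (`onset_cap = 0.10`/epoch)
sets waking-run lengths; its value was chosen so that focal flies produce
wake runs long enough for yoked partners to attain consolidated sleep
during deprivation.

**Bout durations** are drawn at onset from a lognormal with day/night
medians of 7 and 13.5 min (σ_log 0.75 and 0.60) — heavy-tailed, with the
night tail carrying substantial mass above the 25-min deep-sleep boundary.
While `P` exceeds `boost_onset_pressure` (1.3) the draw is scaled by
`1 + pressure_boost · (P − 1.3)` (boost 0.35), which concentrates rebound
sleep in ≥ 25-min bouts after deprivation.

**Speeds.** Rest epochs emit uniform speeds on [0, 0.85] mm/s and active
epochs `1 + lognormal` mm/s, so the distributions sit strictly on either
side of the field's 1 mm/s immobility threshold and scoring is never
knife-edge.

**Post-stimulation arousal (masking).** Every mechanical stimulus
increments a per-fly elevation `h` with a saturating step
(`gain 0.01` toward `hyperactivity_max = 2`), decaying with an 8-h
half-life. `h` is added to active-epoch speeds and divides the sleep-onset
probability by `1 + 3·h·C(zt)`. Gating the suppression by circadian drive
concentrates its behavioral footprint where sleep drive gates behavior —
around the light-to-dark transition — and the saturation keeps the masking
comparable across stimulation frequencies that differ by an order of
magnitude. This elevation is the mechanism by which the pipeline reproduces
rebound masking: focal minus unperturbed sleep gain is attenuated when the
elevation is enabled, while focal minus yoked comparisons are immune
because both members of a pair receive identical stimuli.

### Randomness

All randomness flows from one master seed. Each fly draws from an
independent `numpy` `SeedSequence` substream keyed by a CRC-32 of its id,
so adding, removing, or reordering flies in a cohort never changes any
individual fly's trace, and a deprived fly can be compared against its
bit-identical undisturbed twin by re-simulating the same id without an
engine attached.

## The deprivation engine

The engine is coupled to live simulators — a stimulus alters behavior from
the next epoch — never painted onto finished traces.

* *Inactivity-triggered mode*: per focal fly, a timer accumulates
  consecutive epochs with measured velocity < 1 mm/s inside the deprivation
  window; when it reaches the threshold (220 s = 22 epochs, or 1320 s = 132
  epochs) the engine records an event for the focal fly **and its yoked
  partner**, resets the timer, and stimulates both (arousal forces the next
  epoch awake with probability `arousal_prob`, default 1; the elevation
  increments regardless). The re-arm rule — fire at the epoch where
  accumulated immobility first reaches T, then reset — makes a permanently
  immobile fly receive exactly ⌊8640/22⌋ = 392 events per day at T = 220 s.
* *Fixed-interval mode*: one 2-s shake at a uniformly random offset inside
  every full interval of the window; all flies in the run share the shake
  schedule (`trigger_source = monitor_wide`). A shake marks its whole 10-s
  epoch (epochs are half-open `[t, t+10)`).

With `arousal_prob = 1`, T = 220 s caps every in-window immobility run at
22 epochs, so standard (≥ 5 min) sleep during the window is exactly zero;
T = 1320 s caps runs at 22 min, abolishing ≥ 25-min long-bout sleep while
leaving standard sleep largely intact. `replay_trigger_epochs` applies the
same timer semantics post hoc to a recorded trace (it matches the live
engine exactly when arousal and elevation feedback are disabled, and serves
as the oracle for the timer tests).

## Scoring conventions

* Immobility is *strictly* below 1 mm/s; the sleep criterion is closed
  (duration ≥ k).
* Bouts spanning an analysis-window boundary are split at the boundary and
  each fragment re-tested against the criterion within its window; this
  keeps per-day totals additive at the cost of occasionally dropping a
  boundary fragment that only qualifies whole.
* P(doze) = P(next bin inactive | bin active) and P(wake) symmetric, on
  60-s bins, a bin counting active if any epoch in it is mobile; undefined
  denominators are reported as `None`, never coerced to 0.
* DAM (TriKinetics) immobility is a zero-count bin, no debouncing. The
  monitor file layout used is the 42-column variant: record index, date,
  time, status code (1 = valid; others flagged), five spare fields, a light
  sensor field, then 32 channel counts.
* The DAM emulation emits Poisson counts with rate proportional to a bin's
  mean supra-threshold speed; sub-threshold epochs contribute nothing, so
  fully immobile bins are exactly zero. A deterministic mode (count =
  ⌈rate⌉) supports noise-free cross-modality checks.

## Rebound bookkeeping

Debt = baseline-day sleep − deprivation-window sleep, per fly, at the
chosen criterion. Daily gain is normalized against the unperturbed cohort:
`(F_post − F_pre) − (Ū_post − Ū_pre)`, with the unperturbed terms the
day-matched cohort means (they are not per-fly paired). Cumulative recovery
fraction on post day *d* sums normalized gains over days 1..d and divides
by debt, in percent; overshoot beyond 100% is legitimate. Flies with
debt ≤ 0 are excluded from criterion-sweep cell means and counted in a QC
column, and cells with no usable flies are NaN, never silent zeros.

## Statistics

Two groups are compared with the two-sided Mann–Whitney/Wilcoxon rank-sum
test; the reported W is the first-named group's U statistic (the convention
of R's `wilcox.test`), always accompanied by the group medians to fix
direction. Three or more groups use Kruskal–Wallis with
Bonferroni-corrected pairwise rank-sum tests. The vortex-frequency analysis
is a two-way fixed-factor ANOVA (treatment × trigger frequency) read off
the interaction term. These standard steps are delegated to
`scipy.stats` and `statsmodels`; the test suite cross-checks the rank-sum
path against exhaustive enumeration of all C(n₁+n₂, n₁) assignments for
small groups, and Benjamini–Hochberg q-values against the hand-computed
step-up rule.

## The MALDI screen

The peak screen runs per peak: an omnibus test (Kruskal–Wallis across
focal/yoked/unperturbed in `yoked` mode; rank-sum focal-vs-unperturbed in
`no_yoking` mode), Benjamini–Hochberg correction across the whole peak
family, and — for gated peaks only — Bonferroni-corrected pairwise rank-sum
tests within the peak, with directions taken from group medians. Category
logic: mechanical iff F–Y NS and both F and Y significantly above U;
sleep-pressure iff all three pairwise comparisons significant with
U < Y < F; sleep-absence iff F above both and Y–U NS; NS iff the omnibus q
fails; anything else (including peaks *lower* in focal flies) is "other".
Two conventions deserve emphasis: the omnibus-then-posthoc cascade is the
most conservative reading of a published recipe that names all three
corrections without fixing their combination, and "indistinguishable" is
operationalized as pairwise non-significance after correction — an
accept-the-null convention that becomes anti-conservative at tiny section
counts. At study-scale sections (6/3/4 per condition) the exact rank-sum
floors (2/C(n₁+n₂, n₁)) already exceed the Bonferroni-adjusted pairwise
threshold for some pairs; the screen therefore reports these attainable-p
floors in its QC output rather than pretending the calls are well-powered.
M+H adduct annotation adds one proton mass (1.00728 Da) and matches peaks
within ±0.2 Da — serotonin (average mass 176.2) annotates peaks near 177.2.

## The synthetic MALDI fixture

Peak tables are lognormal around category-structured means: with effect
size *e*, mechanical peaks use (focal, yoked, unperturbed) multipliers
(e, e, 1), sleep-pressure (e, √e, 1), sleep-absence (e, 1, 1), "other"
(1/e, 1, 1). Planted truth labels are returned alongside for recovery
testing; a unit effect size collapses every category to NS and warns. The
default noise (0.2 natural-log units between sections) and effect 4× give
the screen ≥ 90% label recovery at 10 sections per condition.

## Calibration of the reference parameters

The frozen defaults in `reference_params()` were calibrated once against
the joint behavioral structure the analyses assume, then frozen: night/day
long-bout sleep ratio ≈ 2.3 (band 1.5–2.5) with ~1015 min of standard sleep
per day in unperturbed flies; complete standard-sleep deprivation under the
220-s trigger with yoked partners keeping roughly half their sleep; a mean
of ~13 trigger engagements per focal fly per 24 h under the 22-min trigger;
focal > yoked normalized gains on recovery days; and a criterion-sweep
recovery surface that peaks at 25–30-min criteria by recovery day 3 while
the standard 5-min criterion shows little payback. Typical problem sizes in
the shipped tests and acceptance script — cohorts of 20–100 pairs simulated
for 2–5 days — were chosen to make these cohort-level contrasts stable
across seeds at roughly a minute of simulation per check.

## What the generator does and does not emulate

The synthetic fly reproduces the *statistical* structure the pipeline
tests: bimodal sleep timing, night-dominant long bouts, homeostatic rebound
that accumulates over multiple cycles and concentrates in long bouts,
partial yoked sleep loss, and stimulation masking. It does not attempt
biomechanical realism (no positional tracking, no micro-movements, no
grooming), death or escape censoring, inter-individual parameter variation
beyond RNG noise, or sex/genotype differences; velocities are exchangeable
within state rather than autocorrelated. Passing tests therefore validate
the *analysis chain* — scoring, deprivation logic, normalization,
statistics — not any claim about real fly physiology. Two known
magnitude-level departures from the in-vivo picture: the simulated
long-bout rebound repays a larger share of debt than real flies are
reported to, and the post-stimulation activity elevation of a deprived fly
is visible mainly as *reduced masking* near the light-to-dark transition
rather than as an absolute activity excess over controls (the rebound
dominates mornings). Directional contrasts, not magnitudes, are what the
test suite asserts.

## Numerical and degenerate-input conventions

Criteria must be positive multiples of the epoch length (errors otherwise);
undefined ratios (recovery with debt ≤ 0, mean bout with no qualifying
bouts, P(doze) with an empty denominator) are flagged `None`/NaN rather
than defaulted; all-constant peak intensities short-circuit to p = 1 rather
than passing degenerate data to rank tests; stimulus logs require strictly
increasing epochs; trace lengths must be whole days. The timer fires on the
epoch at which accumulated immobility first reaches the threshold and
re-arms immediately, whether or not arousal succeeds.
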
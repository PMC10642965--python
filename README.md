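# somnoyoke

Yoked-control sleep deprivation for *Drosophila*, as a simulated, tested,
reusable analysis pipeline.

Mechanical sleep deprivation — the workhorse of fly sleep research — has a
built-in confound: everything measured after deprivation mixes the response
to sleep *loss* with the response to the mechanical *insult* used to prevent
sleep. The yoked-control design separates the two by pairing every
closed-loop-deprived **focal** fly with a **yoked** partner that receives
identical, time-locked tube rotations regardless of its own behavior: both
flies experience the same perturbation, but only the focal fly loses all of
its sleep. `somnoyoke` implements that paradigm end to end on synthetic
flies, so the full analysis chain is testable without hardware or animals:

* **synthetic flies** — a discrete-time two-process-style state machine
  emitting maximal velocity per 10-s epoch, with bimodal circadian sleep
  propensity (night long-bout sleep ≈ 2× daytime), a homeostatic pressure
  integrator discharged only by consolidated sleep, and a decaying
  post-stimulation arousal elevation (the sleep-independent "masking"
  effect);
* **deprivation engine** — fixed-interval vortexing (one 2-s shake per 20,
  120, or 220 s interval, monitor-wide) and closed-loop inactivity-triggered
  rotation (fires when measured immobility reaches T = 220 s or 1320 s),
  with focal→yoked stimulus binding and a yoking verifier;
* **sleep scoring** — immobility at the strict `< 1 mm/s` threshold, bout
  extraction, sleep under any inactivity criterion *k* (standard *k* = 5 min;
  long-bout "deep" sleep *k* ≥ 25 min; short sleep 1–5 min), P(doze)/P(wake)
  conditional sleep-pressure metrics, and TriKinetics DAM monitor file I/O;
* **rebound analysis** — sleep debt, drift-corrected gain
  `(F_post − F_pre) − (U_post − U_pre)`, multi-day cumulative recovery
  fraction, and the 1–30-min criterion-sweep recovery surface;
* **MALDI screen** — classify m/z peaks from focal/yoked/unperturbed brain
  ROI intensity tables into mechanical-tracking (F ≈ Y > U),
  sleep-pressure-tracking (U < Y < F, all distinguishable), sleep-absence
  (F > Y ≈ U), NS, and other, via Kruskal–Wallis gating, Benjamini–Hochberg
  control across the peak family, and Bonferroni-corrected pairwise
  rank-sum tests.

## Worked example

```python
import numpy as np
from somnoyoke import ExperimentConfig, run_experiment

cfg = ExperimentConfig(design="yoked-220", n_pairs=10, n_unperturbed=6)
res = run_experiment(cfg, seed=1)

print("yoking ok:", res.yoking_ok)
focal = [r for r in res.rebound if r.condition == "focal"]
yoked = [r for r in res.rebound if r.condition == "yoked"]
print("mean focal debt:", round(np.mean([r.debt_min for r in focal]), 1))
print("mean yoked sleep kept during deprivation:",
      round(np.mean([r.deprivation_sleep_min for r in yoked]), 1))
for d in (1, 2, 3):
    print(f"post day {d}: focal gain "
          f"{np.mean([r.gain_norm_min[d] for r in focal]):.0f} min, yoked "
          f"{np.mean([r.gain_norm_min[d] for r in yoked]):.0f} min")
```

prints

```
yoking ok: True
mean focal debt: 1045.6
mean yoked sleep kept during deprivation: 475.6
post day 1: focal gain 342 min, yoked 278 min
post day 2: focal gain 128 min, yoked 80 min
post day 3: focal gain 12 min, yoked 15 min
```

Reading: with a 220-s trigger the focal flies lose their entire baseline
sleep (~1046 min of debt; their sleep during the window is exactly 0 at the
standard 5-min criterion), while yoked partners — identical mechanical
experience — keep ~476 min. On the recovery days the focal flies' sleep
gain (normalized to the unperturbed cohort's drift) exceeds the yoked
flies', the signature of a genuine homeostatic response that a comparison
against unperturbed controls alone would understate.

The same pipeline runs from a shell:

```bash
somnoyoke run --design yoked-220 --n-pairs 10 --seed 1 --out-dir out/
somnoyoke score out/traces.csv --criterion-min 25
somnoyoke maldi peaks.csv sections.csv --mode yoked --alpha 0.05
```

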
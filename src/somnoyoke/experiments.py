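"""End-to-end experiment designs and the pipeline runner.

Built-in designs mirror the study's three behavioral paradigms:

* ``yoked-220``   -- one baseline day, a 24-h closed-loop deprivation with a
                     220-s inactivity trigger (abolishes standard 5-min
                     sleep in focal flies) plus yoked and unperturbed
                     controls, three recovery days;
* ``yoked-1320``  -- same layout with a 1320-s (22-min) trigger, which
                     abolishes only >= 25-min long-bout sleep;
* ``vortex-grid`` -- 24-h monitor-wide vortexing at 20/120/220-s intervals
                     with matched unperturbed monitors, feeding a treatment
                     x trigger-frequency interaction ANOVA.

One master seed flows through named per-fly substreams; re-running a design
with the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .deprivation import (EngineConfig, StimulusLog, run_fixed_interval,
                          run_inactivity_triggered, verify_yoking)
from .errors import ConfigurationError
from .io import params_to_toml, write_stimulus_logs, write_traces
from .rebound import SweepSurface, compute_rebound, criterion_sweep
from .scoring import ScoringConfig, summarize
from .stats import AnovaResult, interaction_anova
from .synthetic import (GeneratorParams, MaldiFixtureParams, PairedDesign,
                        VelocityTrace, generate_cohort, reference_params,
                        generate_peak_table)
from .maldi import ScreenResult, screen

__all__ = ["ExperimentConfig", "ExperimentResult", "RunManifest",
           "run_experiment", "BUILTIN_DESIGNS"]

BUILTIN_DESIGNS = ("yoked-220", "yoked-1320", "vortex-grid")


@dataclass(frozen=True)
class ExperimentConfig:
    design: str = "yoked-220"
    n_pairs: int = 20
    n_unperturbed: int = 12
    n_per_vortex_group: int = 12
    baseline_days: int = 1
    post_days: int = 3
    params: GeneratorParams = field(default_factory=reference_params)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    sweep_criteria_min: tuple[int, ...] = tuple(range(1, 31))
    run_sweep: bool = False
    run_maldi: bool = False
    maldi: MaldiFixtureParams = field(default_factory=MaldiFixtureParams)

    def __post_init__(self) -> None:
        if self.design not in BUILTIN_DESIGNS:
            raise ConfigurationError(
                f"unknown design {self.design!r}; built-ins: {BUILTIN_DESIGNS}")

    @property
    def n_days(self) -> int:
        return self.baseline_days + 1 + self.post_days

    @property
    def deprivation_day(self) -> int:
        return self.baseline_days


@dataclass
class RunManifest:
    design: str
    seed: int
    package_version: str
    config_toml: str
    file_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed: int
    traces: dict[str, VelocityTrace]
    logs: dict[str, StimulusLog]
    design_obj: PairedDesign | None
    yoking_ok: bool | None
    rebound: list
    sweep: SweepSurface | None
    anova: AnovaResult | None
    gain_table: pd.DataFrame | None
    maldi_screen: ScreenResult | None
    maldi_truth: list[str] | None
    manifest: RunManifest


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _run_yoked(cfg: ExperimentConfig, seed: int, threshold_s: int):
    design = PairedDesign.balanced(cfg.n_pairs, cfg.n_unperturbed)
    engine = EngineConfig(mode="inactivity_triggered",
                          trigger_threshold_s=threshold_s,
                          window_start_h=24.0 * cfg.deprivation_day,
                          window_h=24.0)
    traces, logs = run_inactivity_triggered(design, cfg.params, engine,
                                            cfg.n_days, seed)
    return design, traces, logs


def _run_vortex_grid(cfg: ExperimentConfig, seed: int):
    """2 (treatment) x 3 (interval) grid of 24-h vortex deprivation."""
    intervals = (20, 120, 220)
    all_traces: dict[str, VelocityTrace] = {}
    all_logs: dict[str, StimulusLog] = {}
    rows = []
    crit = cfg.scoring.criterion_s
    for interval in intervals:
        ids = [f"vortex{interval:03d}_{i:03d}" for i in range(cfg.n_per_vortex_group)]
        engine = EngineConfig(mode="fixed_interval", interval_s=interval,
                              window_start_h=24.0 * cfg.deprivation_day,
                              window_h=24.0)
        traces, logs = run_fixed_interval(ids, cfg.params, engine, cfg.n_days, seed)
        all_traces.update(traces)
        all_logs.update(logs)
        # matched unperturbed monitor for this interval
        u_design = PairedDesign(
            pairs=(), unperturbed_ids=tuple(
                f"unpert{interval:03d}_{i:03d}" for i in range(cfg.n_per_vortex_group)))
        u_traces = generate_cohort(u_design, cfg.params, cfg.n_days, seed)
        all_traces.update(u_traces)
        n = next(iter(traces.values())).grid.epochs_per_day
        base_day, post_day = cfg.deprivation_day - 1, cfg.deprivation_day + 1
        for group, trs in (("disturbed", traces), ("unperturbed", u_traces)):
            for t in trs.values():
                s_base = summarize(t, cfg.scoring,
                                   (base_day * n, (base_day + 1) * n)).total_sleep_min
                s_post = summarize(t, cfg.scoring,
                                   (post_day * n, (post_day + 1) * n)).total_sleep_min
                rows.append({"fly_id": t.fly_id, "treatment": group,
                             "frequency": f"{interval}s",
                             "gain": s_post - s_base, "criterion_s": crit})
    gain_table = pd.DataFrame(rows)
    anova = interaction_anova(gain_table)
    return all_traces, all_logs, gain_table, anova


def run_experiment(cfg: ExperimentConfig, seed: int,
                   out_dir: str | Path | None = None) -> ExperimentResult:
    """Run a built-in design end to end; optionally persist stage outputs."""
    design_obj = None
    yoking_ok = None
    rebound: list = []
    sweep = None
    anova = None
    gain_table = None
    maldi_result = None
    maldi_truth = None

    if cfg.design in ("yoked-220", "yoked-1320"):
        threshold = 220 if cfg.design == "yoked-220" else 1320
        design_obj, traces, logs = _run_yoked(cfg, seed, threshold)
        yoking_ok = bool(verify_yoking(logs, design_obj))
        crit = cfg.scoring.criterion_s
        rebound = compute_rebound(traces, crit, baseline_day=0,
                                  deprivation_day=cfg.deprivation_day,
                                  post_days=cfg.post_days, cfg=cfg.scoring)
        if cfg.run_sweep:
            sweep = criterion_sweep(traces, cfg.sweep_criteria_min,
                                    post_days=cfg.post_days,
                                    deprivation_day=cfg.deprivation_day,
                                    cfg=cfg.scoring)
    else:
        traces, logs, gain_table, anova = _run_vortex_grid(cfg, seed)

    if cfg.run_maldi:
        fix = dataclasses.replace(cfg.maldi, seed=seed)
        table, maldi_truth = generate_peak_table(fix)
        maldi_result = screen(table, mode="yoked")

    manifest = RunManifest(design=cfg.design, seed=seed,
                           package_version=_version,
                           config_toml=params_to_toml(cfg.params, seed))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_traces(traces, out / "traces.csv")
        write_stimulus_logs(logs, out / "stimulus_logs.csv")
        (out / "params.toml").write_text(manifest.config_toml)
        if sweep is not None:
            pd.DataFrame(sweep.values, index=sweep.criteria_min,
                         columns=[f"post{d}" for d in sweep.post_days]
                         ).to_csv(out / "sweep_surface.csv")
        if gain_table is not None:
            gain_table.to_csv(out / "gain_table.csv", index=False)
        if maldi_result is not None:
            maldi_result.to_csv(out / "maldi_classification.csv")
        for f in sorted(out.iterdir()):
            if f.is_file():
                manifest.file_digests[f.name] = _digest(f)
        (out / "manifest.json").write_text(manifest.to_json())

    return ExperimentResult(config=cfg, seed=seed, traces=traces, logs=logs,
                            design_obj=design_obj, yoking_ok=yoking_ok,
                            rebound=rebound, sweep=sweep, anova=anova,
                            gain_table=gain_table, maldi_screen=maldi_result,
                            maldi_truth=maldi_truth, manifest=manifest)
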
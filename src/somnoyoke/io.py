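"""Plain-text persistence: trace CSVs, stimulus logs, flat TOML configs."""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .deprivation import StimulusLog
from .errors import DataError
from .grid import DEFAULT_GRID, EpochGrid
from .synthetic import (ActiveSpeedDist, BoutLengthDist, CircadianPropensity,
                        GeneratorParams, RestSpeedDist, VelocityTrace)

__all__ = [
    "traces_to_frame", "write_traces", "read_traces",
    "write_stimulus_logs", "read_stimulus_logs",
    "params_to_toml", "params_from_toml",
]


def traces_to_frame(traces: dict[str, VelocityTrace]) -> pd.DataFrame:
    """Long-format frame: fly_id, condition, epoch_index, zt_seconds, velocity."""
    frames = []
    for t in traces.values():
        n = t.n_epochs
        frames.append(pd.DataFrame({
            "fly_id": t.fly_id,
            "condition": t.condition,
            "epoch_index": np.arange(n),
            "zt_seconds": t.grid.zt_seconds(n),
            "max_velocity_mm_s": t.values,
        }))
    return pd.concat(frames, ignore_index=True)


def write_traces(traces: dict[str, VelocityTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path: str | Path,
                grid: EpochGrid = DEFAULT_GRID) -> dict[str, VelocityTrace]:
    df = pd.read_csv(path)
    required = {"fly_id", "condition", "epoch_index", "max_velocity_mm_s"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"trace CSV missing columns: {sorted(missing)}")
    out = {}
    for fid, g in df.groupby("fly_id", sort=False):
        g = g.sort_values("epoch_index")
        if not np.array_equal(g["epoch_index"].to_numpy(), np.arange(len(g))):
            raise DataError(f"fly {fid!r}: epoch indices are not contiguous from 0")
        out[str(fid)] = VelocityTrace(
            fly_id=str(fid), condition=str(g["condition"].iloc[0]), grid=grid,
            values=g["max_velocity_mm_s"].to_numpy())
    return out


def write_stimulus_logs(logs: dict[str, StimulusLog], path: str | Path,
                        grid: EpochGrid = DEFAULT_GRID) -> None:
    rows = []
    for log in logs.values():
        for e in log.events:
            rows.append({"fly_id": log.fly_id, "epoch_index": int(e),
                         "zt_seconds": float(e) * grid.epoch_length_s
                         + grid.t0 * 3600.0,
                         "mode": log.mode, "trigger_source": log.trigger_source})
    pd.DataFrame(rows, columns=["fly_id", "epoch_index", "zt_seconds", "mode",
                                "trigger_source"]).to_csv(path, index=False)


def read_stimulus_logs(path: str | Path) -> dict[str, StimulusLog]:
    df = pd.read_csv(path)
    out = {}
    for fid, g in df.groupby("fly_id", sort=False):
        g = g.sort_values("epoch_index")
        out[str(fid)] = StimulusLog(
            fly_id=str(fid), events=g["epoch_index"].to_numpy(),
            mode=str(g["mode"].iloc[0]),
            trigger_source=str(g["trigger_source"].iloc[0]))
    return out


# --------------------------------------------------------------------------
# flat TOML config for GeneratorParams
# --------------------------------------------------------------------------

_NESTED = {
    "circadian_propensity": CircadianPropensity,
    "bout_length_dist": BoutLengthDist,
    "rest_speed_dist": RestSpeedDist,
    "active_speed_dist": ActiveSpeedDist,
}


def params_to_toml(params: GeneratorParams, master_seed: int | None = None) -> str:
    """Flatten a GeneratorParams to dotted-key TOML text."""
    lines = []
    if master_seed is not None:
        lines.append(f"master_seed = {int(master_seed)}")
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if f.name in _NESTED:
            for sub in dataclasses.fields(v):
                lines.append(f"{f.name}.{sub.name} = {getattr(v, sub.name)!r}")
        else:
            lines.append(f"{f.name} = {v!r}")
    return "\n".join(lines).replace("'", '"') + "\n"


def params_from_toml(text_or_path: str | Path) -> tuple[GeneratorParams, int | None]:
    """Parse flat TOML back to (GeneratorParams, master_seed or None)."""
    p = Path(text_or_path) if isinstance(text_or_path, Path) else None
    if p is None and "\n" not in str(text_or_path) and Path(text_or_path).exists():
        p = Path(text_or_path)
    text = p.read_text() if p is not None else str(text_or_path)
    data = tomllib.loads(text)
    seed = data.pop("master_seed", None)
    kwargs = {}
    for key, val in data.items():
        if key in _NESTED:
            if not isinstance(val, dict):
                raise DataError(f"{key} must be a table of fields")
            # tuple-typed fields are not present in nested dists; plain kwargs
            kwargs[key] = _NESTED[key](**val)
        else:
            kwargs[key] = val
    params = GeneratorParams(**kwargs)
    params.validate()
    return params, seed
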
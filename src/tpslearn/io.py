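"""Plain-text persistence: CSV tables with JSON sidecar manifests.

Everything a run produces is diffable text — trajectories and training sets
as CSV, manifests, scaling records and expression constants as JSON,
expressions as prefix-notation strings — so any run is reproducible from
its manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .committor import ShootingRecord, TrainingSet
from .dynamics import EngineParams, Trajectory
from .symreg import Expression, parse_prefix
from .validation import ValidationLedger

__all__ = [
    "load_expression",
    "load_training_set",
    "read_manifest",
    "save_expression",
    "save_ledger",
    "save_trajectory",
    "save_training_set",
    "write_manifest",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_manifest(path: str | FsPath, manifest: dict) -> None:
    FsPath(path).write_text(json.dumps(manifest, indent=2, default=_jsonable) + "\n")


def read_manifest(path: str | FsPath) -> dict:
    return json.loads(FsPath(path).read_text())


def save_trajectory(path: str | FsPath, traj: Trajectory,
                    engine: EngineParams | None = None,
                    terminal_state: str | None = None,
                    seed: int | None = None) -> None:
    """One row per frame: time, x0..xd-1 (and v0..vd-1 if present), plus a
    JSON sidecar with engine parameters, seed and terminal state."""
    d = traj.positions.shape[1]
    cols = {"time": traj.times}
    for k in range(d):
        cols[f"x{k}"] = traj.positions[:, k]
    if traj.velocities is not None:
        for k in range(d):
            cols[f"v{k}"] = traj.velocities[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    manifest = {"n_frames": len(traj), "dim": d, "timestep": traj.timestep,
                "stride": traj.stride, "terminal_state": terminal_state, "seed": seed}
    if engine is not None:
        manifest["engine"] = asdict(engine)
    write_manifest(str(path) + ".json", manifest)


def save_training_set(path: str | FsPath, data: TrainingSet) -> None:
    """Columns: chain_id, step_index, s, x_0..x_{d-1}."""
    rows = []
    for r in data:
        if r.outcome is None:
            raise ValueError("only per-trial records are serialized; unroll counts first")
        rows.append({"chain_id": r.chain_id, "step_index": r.step_index,
                     "s": r.outcome,
                     **{f"x_{i}": v for i, v in enumerate(r.features)}})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def load_training_set(path: str | FsPath) -> TrainingSet:
    df = pd.read_csv(path, dtype={"chain_id": str})
    feat_cols = [c for c in df.columns if c.startswith("x_")]
    ts = TrainingSet()
    for _, row in df.iterrows():
        ts.append(ShootingRecord(row[feat_cols].to_numpy(float),
                                 outcome=int(row["s"]),
                                 step_index=int(row["step_index"]),
                                 chain_id=str(row["chain_id"])))
    return ts


def save_ledger(path: str | FsPath, ledger: ValidationLedger) -> None:
    gen, exp, diff = ledger.cumulative_curves()
    pd.DataFrame({"step": ledger.steps, "p_pred": ledger.p_pred,
                  "generated": ledger.generated, "cum_generated": gen,
                  "cum_expected": exp, "cum_abs_diff": diff}).to_csv(path, index=False)


def save_expression(path: str | FsPath, expr: Expression) -> None:
    FsPath(path).write_text(expr.to_prefix() + "\n")
    write_manifest(str(path) + ".json", {
        "var_names": list(expr.var_names),
        "constants": expr.get_constant_values().tolist(),
        "complexity": expr.complexity,
        "infix": str(expr),
    })


def load_expression(path: str | FsPath) -> Expression:
    meta = read_manifest(str(path) + ".json")
    return parse_prefix(FsPath(path).read_text().strip(), tuple(meta["var_names"]))
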
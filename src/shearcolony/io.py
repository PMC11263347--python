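"""File formats: CSV tables, multi-page TIFF stacks, YAML configs, JSON results.

All tabular artifacts are plain CSV so fixtures stay diffable; images are
16-bit multi-page grayscale TIFF; scalar results are JSON.  Readers validate
the column dictionary and name the missing columns on mismatch.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from shearcolony.track import Trajectory

__all__ = [
    "SchemaError",
    "write_tiff_stack", "read_tiff_stack",
    "write_table", "read_table",
    "write_trajectories", "read_trajectories",
    "write_json", "read_json",
    "load_yaml_config", "dump_config",
]

TRAJECTORY_COLUMNS = ["traj_id", "time", "x", "y", "pole_ax", "pole_ay",
                      "pole_bx", "pole_by", "length", "eccentricity",
                      "end_reason", "agent_id"]
DETECTION_COLUMNS = ["frame", "x", "y", "pole_ax", "pole_ay", "pole_bx",
                     "pole_by"]


class SchemaError(ValueError):
    def __init__(self, path, missing):
        self.missing = list(missing)
        super().__init__(f"{path}: missing required columns {self.missing}")


def write_tiff_stack(path, frames: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(frames), photometric="minisblack")


def read_tiff_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path, required_columns=()) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in required_columns if c not in table.columns]
    if missing:
        raise SchemaError(path, missing)
    return table


def write_trajectories(path, trajectories: list[Trajectory]) -> None:
    from shearcolony.track import trajectories_to_frame
    write_table(path, trajectories_to_frame(trajectories))


def read_trajectories(path) -> list[Trajectory]:
    table = read_table(path, required_columns=TRAJECTORY_COLUMNS)
    out = []
    for tid, grp in table.groupby("traj_id", sort=True):
        grp = grp.sort_values("time")
        agent = int(grp["agent_id"].iloc[0])
        out.append(Trajectory(
            traj_id=int(tid),
            times=grp["time"].to_numpy(),
            xy=grp[["x", "y"]].to_numpy(),
            pole_a=grp[["pole_ax", "pole_ay"]].to_numpy(),
            pole_b=grp[["pole_bx", "pole_by"]].to_numpy(),
            length=grp["length"].to_numpy(),
            eccentricity=grp["eccentricity"].to_numpy(),
            end_reason=str(grp["end_reason"].iloc[0]),
            agent_id=None if agent < 0 else agent,
        ))
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2,
                                     sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {} if data is None else data


def dump_config(path, config) -> None:
    """Write a config echo (dataclass or dict) next to the outputs."""
    payload = _jsonable(config)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
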
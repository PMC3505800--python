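"""Dataset readers and serializable result records for the command line."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .assoc import CaseControlData

__all__ = ["read_dataset", "write_dataset", "ResultRecord"]


def read_dataset(path, delimiter: str | None = None) -> tuple[CaseControlData, int]:
    """Read a delimited text dataset with columns ``y``, ``z`` and ``x`` (or ``x1``, ``x2``).

    Rows with missing values in the used columns are dropped and counted;
    returns ``(data, n_dropped)``.  Missing required columns raise a schema
    error naming the column; phenotype values outside {0, 1} are rejected.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python")
    for col in ("y", "z"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if "x" in df.columns:
        cols = ["y", "z", "x"]
    elif {"x1", "x2"}.issubset(df.columns):
        cols = ["y", "z", "x1", "x2"]
    else:
        raise ValueError("missing required column 'x' (or the pair 'x1', 'x2')")
    sub = df[cols]
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    yv = kept["y"].to_numpy()
    if not np.isin(yv, (0, 1)).all():
        bad = sorted(set(yv) - {0, 1})
        raise ValueError(f"phenotype y must be 0/1; found {bad}")
    if "x" in cols:
        data = CaseControlData(y=yv, z=kept["z"].to_numpy(), x=kept["x"].to_numpy(float))
    else:
        data = CaseControlData(y=yv, z=kept["z"].to_numpy(),
                               x=kept["x1"].to_numpy(float), x2=kept["x2"].to_numpy(float))
    return data, n_dropped


def write_dataset(data: CaseControlData, path) -> None:
    cols = {"y": data.y.astype(int), "z": data.z, "x": data.x}
    if data.x2 is not None:
        cols = {"y": data.y.astype(int), "z": data.z, "x1": data.x, "x2": data.x2}
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class ResultRecord:
    """One command invocation and its outputs, serializable to JSON.

    The timestamp lives in a single field so records from repeated runs with
    the same parameters and seed are diffable.
    """

    command: str
    parameters: dict
    outputs: dict
    seed: int | None = None
    version: str = ""
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def to_json(self, indent: int = 1) -> str:
        from . import __version__

        payload = {
            "command": self.command,
            "parameters": _jsonable(self.parameters),
            "seed": self.seed,
            "version": self.version or __version__,
            "outputs": _jsonable(self.outputs),
            "timestamp": self.timestamp,
        }
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "ResultRecord":
        obj = json.loads(text)
        return cls(command=obj["command"], parameters=obj["parameters"],
                   outputs=obj["outputs"], seed=obj.get("seed"),
                   version=obj.get("version", ""), timestamp=obj["timestamp"])
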
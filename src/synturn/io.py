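"""CSV / JSON serialization for distributions, trajectories and MI curves."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .information import MICurve
from .model_core import DistributionTrajectory, StationaryDistribution

__all__ = [
    "distribution_to_csv",
    "trajectory_to_csv",
    "micurve_to_csv",
    "write_json",
]


def write_json(path: str | Path, payload: dict[str, Any]) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


def distribution_to_csv(
    dist: StationaryDistribution | np.ndarray,
    path: str | Path,
    meta_path: str | Path | None = None,
    **meta: Any,
) -> None:
    """One row per synapse count S; optional JSON sidecar with parameters."""
    p = dist.p if isinstance(dist, StationaryDistribution) else np.asarray(dist, float)
    pd.DataFrame({"S": np.arange(p.size), "p": p}).to_csv(path, index=False)
    if meta_path is not None:
        if isinstance(dist, StationaryDistribution):
            meta.setdefault("condition", dist.condition)
        write_json(meta_path, meta)


def trajectory_to_csv(traj: DistributionTrajectory, path: str | Path) -> None:
    """Wide table: one row per recorded time, one column per synapse count."""
    cols = {f"p{s}": traj.dists[:, s] for s in range(traj.dists.shape[1])}
    df = pd.DataFrame({"time": traj.times, **cols})
    if traj.condition_schedule:
        df.insert(1, "condition", traj.condition_schedule)
    df.to_csv(path, index=False)


def micurve_to_csv(
    curve: MICurve,
    path: str | Path,
    meta_path: str | Path | None = None,
    **meta: Any,
) -> None:
    pd.DataFrame({"time": curve.times, "mi_bits": curve.mi}).to_csv(path, index=False)
    if meta_path is not None:
        write_json(meta_path, meta)
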
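"""Tabular run output: CSV with a commented JSON metadata header.

Every run artefact is a plain CSV whose first line carries the effective
parameters, the seed and the package version as one JSON document behind a
``# `` comment, so any published table can be regenerated from the file
alone and the format stays diffable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["write_trajectory", "read_trajectory"]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_trajectory(obj: Any, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a Trajectory, PopulationSeries or DataFrame to annotated CSV.

    ``obj`` may be anything with a ``to_frame()`` method or a DataFrame.
    Metadata defaults to the object's own (seed and stored metadata) and is
    merged with the caller's.
    """
    path = Path(path)
    frame = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
    meta: dict[str, Any] = {"version": __version__}
    for attr in ("seed", "dt", "exploded", "explosion_step", "extinction_step"):
        if hasattr(obj, attr):
            meta[attr] = getattr(obj, attr)
    if getattr(obj, "metadata", None):
        meta.update(obj.metadata)
    if metadata:
        meta.update(metadata)
    with path.open("w") as fh:
        fh.write("# " + json.dumps(_jsonable(meta)) + "\n")
        frame.to_csv(fh, index=False)
    return path


def read_trajectory(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read an annotated CSV back into (DataFrame, metadata)."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        metadata = json.loads(first[1:].strip()) if first.startswith("#") else {}
        rest = fh.read()
    if not rest.strip():
        return pd.DataFrame(), metadata
    from io import StringIO

    return pd.read_csv(StringIO(rest)), metadata
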
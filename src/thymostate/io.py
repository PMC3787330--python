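"""CSV/JSONL writers and readers for trajectories, counts, and event logs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .abm import ABMResult
from .ode import Trajectory


def _frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    if isinstance(obj, Trajectory):
        data = {"time": obj.times}
        for j, nm in enumerate(obj.state_names):
            data[nm] = obj.values[:, j]
        if obj.channels is not None:
            for j, nm in enumerate(obj.channel_names):
                data[nm] = obj.channels[:, j]
        return pd.DataFrame(data)
    if isinstance(obj, ABMResult):
        data = {"time": obj.times}
        for j, nm in enumerate(obj.state_names):
            data[nm] = obj.counts[:, j]
        for j, nm in enumerate(obj.channel_names):
            data[nm] = obj.channels[:, j]
        return pd.DataFrame(data)
    raise TypeError(f"cannot write {type(obj).__name__} as a time series")


def write_timeseries(obj, path) -> None:
    """Lossless CSV ('.' decimal, ',' separator, exact float repr)."""
    df = _frame(obj)
    if not np.all(np.isfinite(df.select_dtypes("number").to_numpy())):
        raise ValueError("time series contains non-finite values")
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_event_log(log: list[tuple], path) -> None:
    """JSON-lines: one {t, id, event, detail} record per line."""
    with open(path, "w") as fh:
        for (t, aid, event, detail) in log:
            fh.write(json.dumps({"t": t, "id": aid, "event": event,
                                 "detail": detail}) + "\n")


def read_event_log(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def read_model_file(path):
    from .statechart import parse_model

    return parse_model(Path(path).read_text())
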
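"""Minimal reader/writer for the OpenSim-style .sto/.mot time-series dialect.

Header lines of ``key=value`` pairs terminated by an ``endheader`` sentinel,
then a tab-separated column-name row with ``time`` first, then the data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError


def write_sto(path, time: np.ndarray, data: pd.DataFrame, name: str = "series") -> None:
    time = np.asarray(time, dtype=float)
    if len(time) != len(data):
        raise InputError("time vector and data must have equal length")
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write(f"nRows={len(data)}\n")
        fh.write(f"nColumns={data.shape[1] + 1}\n")
        fh.write("version=1\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(map(str, data.columns)) + "\n")
        arr = np.column_stack([time, data.to_numpy(dtype=float)])
        for row in arr:
            fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


def read_sto(path):
    """Return ``(name, time, DataFrame)`` from a .sto/.mot file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, l in enumerate(lines) if l.strip().lower() == "endheader")
    except StopIteration:
        raise InputError(f"{path}: missing 'endheader' sentinel") from None
    name = lines[0].split("=")[0].strip() if lines else "series"
    cols = lines[end + 1].split("\t")
    if not cols or cols[0].strip() != "time":
        raise InputError(f"{path}: first column must be 'time'")
    body = [l.split("\t") for l in lines[end + 2:] if l.strip()]
    arr = np.asarray(body, dtype=float)
    df = pd.DataFrame(arr[:, 1:], columns=[c.strip() for c in cols[1:]])
    return name, arr[:, 0], df
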
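"""Tab-delimited motion-storage time-series files.

The dialect is compatible with common musculoskeletal motion files: a header
block of ``key=value`` lines including ``nRows``/``nColumns``, closed by an
``endheader`` sentinel, then a tab-separated table whose first column is
``time`` (seconds, strictly increasing).  Floats are written with repr-round-
trip precision so ``read(write(x))`` is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MotionTable", "read_motion", "write_motion", "MotionParseError"]


class MotionParseError(ValueError):
    def __init__(self, message, line=None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass
class MotionTable:
    """A named time-series table with provenance metadata."""

    name: str
    columns: list                 # column names, first is "time"
    data: np.ndarray              # (n_rows, n_cols)
    units: dict = field(default_factory=dict)   # column -> unit string
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.columns):
            raise ValueError("data shape does not match column count")
        if self.data.shape[0] == 0:
            raise ValueError("motion table must contain at least one row")
        if self.columns[0] != "time":
            raise ValueError("first column must be 'time'")
        t = self.data[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time column must be strictly increasing")

    @property
    def time(self):
        return self.data[:, 0]

    def column(self, name):
        return self.data[:, self.columns.index(name)]

    @classmethod
    def from_dict(cls, name, time, series: dict, units=None, metadata=None):
        cols = ["time"] + list(series)
        data = np.column_stack([np.asarray(time)] +
                               [np.asarray(series[c]) for c in series])
        return cls(name=name, columns=cols, data=data,
                   units=units or {}, metadata=metadata or {})


def write_motion(table: MotionTable, path):
    """Write a table in the canonical dialect."""
    n_rows, n_cols = table.data.shape
    with open(path, "w") as fh:
        fh.write(f"{table.name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={n_rows}\n")
        fh.write(f"nColumns={n_cols}\n")
        fh.write("inDegrees=no\n")
        for k, v in table.metadata.items():
            fh.write(f"{k}={v}\n")
        if table.units:
            fh.write("units=" + ",".join(f"{c}:{u}" for c, u in table.units.items()) + "\n")
        fh.write("endheader\n")
        fh.write("\t".join(table.columns) + "\n")
        for row in table.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_motion(path) -> MotionTable:
    """Read a motion-storage file; raises :class:`MotionParseError` with the
    offending line number on malformed input."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MotionParseError("empty file", 1)
    name = lines[0].strip()
    meta = {}
    units = {}
    n_rows = n_cols = None
    i = 1
    found_end = False
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if line == "endheader":
            found_end = True
            break
        if "=" not in line:
            raise MotionParseError(f"expected key=value in header, got {line!r}", i)
        key, _, value = line.partition("=")
        if key == "nRows":
            n_rows = int(value)
        elif key == "nColumns":
            n_cols = int(value)
        elif key == "units":
            units = dict(p.split(":") for p in value.split(",") if p)
        elif key in ("version", "inDegrees"):
            meta[key] = value
        else:
            meta[key] = value
    if not found_end:
        raise MotionParseError("missing 'endheader' sentinel", len(lines))
    if n_rows is None or n_cols is None:
        raise MotionParseError("header must declare nRows and nColumns", i)
    if i >= len(lines):
        raise MotionParseError("missing column header row", i + 1)
    columns = lines[i].rstrip("\n").split("\t")
    if len(columns) != n_cols:
        raise MotionParseError(
            f"declared nColumns={n_cols} but found {len(columns)} names", i + 1)
    rows = []
    for j in range(n_rows):
        k = i + 1 + j
        if k >= len(lines):
            raise MotionParseError(f"expected {n_rows} data rows, found {j}", k)
        parts = lines[k].split("\t")
        if len(parts) != n_cols:
            raise MotionParseError(f"row has {len(parts)} fields, expected {n_cols}", k + 1)
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise MotionParseError(str(exc), k + 1)
    meta.pop("version", None)
    meta.pop("inDegrees", None)
    return MotionTable(name=name, columns=columns, data=np.array(rows),
                       units=units, metadata=meta)
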
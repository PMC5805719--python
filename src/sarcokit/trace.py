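"""Uniformly sampled time series and their on-disk CSV form.

A :class:`Trace` is the common container for force (fractional occupancy),
NADH absorbance, free-calcium and sarcomere-length records.  On disk a trace
is a two-column CSV (``t,y``) preceded by ``# key: value`` metadata lines, so
files remain plain text and self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecificationError

__all__ = ["Trace", "read_trace_csv", "write_trace_csv"]


@dataclass
class Trace:
    t: np.ndarray
    y: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1 or len(self.t) != len(self.y):
            raise InvalidSpecificationError("t and y must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise InvalidSpecificationError("t must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise InvalidSpecificationError("t must be uniformly sampled")

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise InvalidSpecificationError("trace too short to define dt")
        return float(self.t[1] - self.t[0])

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t0 <= t <= t1 (inclusive)."""
        m = (self.t >= t0) & (self.t <= t1)
        return Trace(self.t[m], self.y[m], units=self.units, meta=dict(self.meta))

    def __len__(self) -> int:
        return len(self.t)


def write_trace_csv(path, trace: Trace) -> None:
    with open(path, "w") as fh:
        for key, val in trace.meta.items():
            fh.write(f"# {key}: {val}\n")
        if trace.units:
            fh.write(f"# units: {trace.units}\n")
        fh.write("t,y\n")
        for ti, yi in zip(trace.t, trace.y):
            fh.write(f"{ti:.9g},{yi:.9g}\n")


def read_trace_csv(path) -> Trace:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    units = meta.pop("units", "")
    return Trace(df["t"].to_numpy(), df["y"].to_numpy(), units=units, meta=meta)
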
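"""Uniformly sampled trace container and CSV/HDF5 trace I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trace:
    """A uniformly sampled time series (voltage or current).

    Attributes
    ----------
    y : ndarray
        Signal samples, mV for voltage or pA for current.
    dt : float
        Sampling interval in ms.
    t0 : float
        Time of the first sample in ms.
    site : str
        Recording-site label (e.g. ``"soma"``, ``"AIS"``).
    units : str
        ``"mV"`` or ``"pA"``.
    """

    y: np.ndarray
    dt: float
    t0: float = 0.0
    site: str = ""
    units: str = "mV"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.y.ndim != 1:
            raise ValueError("trace signal must be one-dimensional")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("trace contains non-finite values")

    @property
    def t(self) -> np.ndarray:
        """Time axis in ms."""
        return self.t0 + self.dt * np.arange(self.y.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.y.size - 1)

    def index_at(self, time_ms: float) -> int:
        """Index of the sample nearest ``time_ms`` (clipped to range)."""
        i = int(round((time_ms - self.t0) / self.dt))
        return min(max(i, 0), self.y.size - 1)

    def window(self, t_start: float, t_stop: float) -> "Trace":
        """Sub-trace between two times (inclusive of boundary samples)."""
        i0, i1 = self.index_at(t_start), self.index_at(t_stop)
        return Trace(self.y[i0 : i1 + 1], self.dt, self.t0 + i0 * self.dt, self.site, self.units)


def write_trace_csv(trace: Trace, path) -> None:
    header = f"t_ms,{trace.units} site={trace.site} dt={trace.dt!r}"
    np.savetxt(path, np.column_stack([trace.t, trace.y]), delimiter=",", header=header)


def read_trace_csv(path) -> Trace:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = header.split(",", 1)[1].split()
    units = fields[0]
    meta = dict(f.split("=", 1) for f in fields[1:])
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, y = data[:, 0], data[:, 1]
    dt = float(meta.get("dt", t[1] - t[0] if t.size > 1 else 1.0))
    return Trace(y, dt, t0=float(t[0]), site=meta.get("site", ""), units=units)


def write_traces_h5(traces: dict, path) -> None:
    """Write ``{site: Trace}`` to HDF5, one dataset per site with dt/t0/units attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        for site, tr in traces.items():
            ds = f.create_dataset(site, data=tr.y)
            ds.attrs["dt"] = tr.dt
            ds.attrs["t0"] = tr.t0
            ds.attrs["units"] = tr.units


def read_traces_h5(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for site in f:
            ds = f[site]
            out[site] = Trace(
                ds[...],
                float(ds.attrs["dt"]),
                t0=float(ds.attrs.get("t0", 0.0)),
                site=site,
                units=str(ds.attrs.get("units", "mV")),
            )
    return out
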
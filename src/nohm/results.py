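"""Space-time simulation results and their on-disk formats (HDF5 / CSV)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["SimulationResult", "save_hdf5", "load_hdf5", "save_csv", "load_csv"]


@dataclass(eq=False)
class SimulationResult:
    """Transmembrane potential v(x, t) on a uniform strand grid.

    ``times`` in ms (monotone), ``positions`` in mm (monotone), ``v`` in mV
    with shape ``(len(times), len(positions))``.  ``meta`` carries the full
    run configuration for provenance; ``status`` is the solver's exit code
    (0 completed, 1 stopped early after distal activation, 2 stopped early
    after decay to rest).
    """

    times: np.ndarray
    positions: np.ndarray
    v: np.ndarray
    meta: dict = field(default_factory=dict)
    status: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (self.times.size, self.positions.size):
            raise ValueError(
                f"v shape {self.v.shape} does not match "
                f"(n_times={self.times.size}, n_positions={self.positions.size})"
            )
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.positions) <= 0):
            raise ValueError("times and positions must be strictly increasing")

    @property
    def L(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def trace_at(self, x: float) -> np.ndarray:
        """v(t) at the grid site nearest ``x`` (mm)."""
        return self.v[:, self.site_index(x)]

    def site_index(self, x: float) -> int:
        return int(np.argmin(np.abs(self.positions - x)))


def save_hdf5(result: SimulationResult, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_ms", data=result.times)
        fh.create_dataset("x_mm", data=result.positions)
        fh.create_dataset("v_mV", data=result.v)
        fh.attrs["status"] = result.status
        fh.attrs["meta_json"] = json.dumps(result.meta)


def load_hdf5(path) -> SimulationResult:
    with h5py.File(path, "r") as fh:
        return SimulationResult(
            times=fh["time_ms"][:],
            positions=fh["x_mm"][:],
            v=fh["v_mV"][:],
            meta=json.loads(fh.attrs["meta_json"]),
            status=int(fh.attrs["status"]),
        )


def save_csv(result: SimulationResult, path) -> None:
    """Wide CSV: header row of positions, then one row ``t, v(x0), v(x1), ...``.

    Metadata is embedded in ``#``-prefixed header lines.
    """
    with open(path, "w") as fh:
        fh.write("# meta " + json.dumps(result.meta) + "\n")
        fh.write(f"# status {result.status}\n")
        fh.write("time_ms," + ",".join("%.17g" % x for x in result.positions) + "\n")
        for t, row in zip(result.times, result.v):
            fh.write("%.17g," % t + ",".join("%.17g" % u for u in row) + "\n")


def load_csv(path) -> SimulationResult:
    meta: dict = {}
    status = 0
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta "):
                meta = json.loads(line[len("# meta "):])
            elif line.startswith("# status "):
                status = int(line[len("# status "):])
            elif line.startswith("time_ms"):
                positions = np.array([float(x) for x in line.strip().split(",")[1:]])
            elif line.strip():
                rows.append([float(x) for x in line.strip().split(",")])
    data = np.asarray(rows)
    return SimulationResult(
        times=data[:, 0], positions=positions, v=data[:, 1:], meta=meta, status=status
    )
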
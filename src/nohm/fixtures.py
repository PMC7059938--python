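"""Synthetic space-time fixtures for testing the analysis stage.

A translating sigmoidal wavefront with known speed exercises the
activation/CV estimators without running any solver.
"""

from __future__ import annotations

import numpy as np

from .results import SimulationResult

__all__ = ["make_fixture"]


def make_fixture(kind: str = "travelling_wave", *, speed: float = 0.5,
                 L: float = 6.4, h: float = 0.1, t_end: float = 30.0,
                 dt: float = 0.1, v_rest: float = -84.0, v_peak: float = 20.0,
                 width: float = 0.25, x0: float | None = None) -> SimulationResult:
    """Synthetic traveling wave ``v(x, t) = f(x - c t)``.

    ``speed`` in mm/ms (positive: left-to-right; negative: retrograde,
    starting from the right end; zero: standing front that never reaches the
    measurement sites).  ``width`` is the upstroke length scale in mm.
    """
    if kind != "travelling_wave":
        raise ValueError(f"unknown fixture kind {kind!r}")
    x = np.arange(0.0, L + 0.5 * h, h)
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    if x0 is None:
        x0 = 0.0 if speed >= 0.0 else L
    front = x0 + speed * t
    amp = v_peak - v_rest
    if speed >= 0.0:
        phase = (front[:, None] - x[None, :]) / width  # depolarized behind front
    else:
        phase = (x[None, :] - front[:, None]) / width
    v = v_rest + amp / (1.0 + np.exp(-phase))
    direction = "normal" if speed >= 0.0 else "retrograde"
    return SimulationResult(
        times=t, positions=x, v=v,
        meta={"model": "fixture", "direction": direction,
              "speed_mm_ms": speed, "width_mm": width},
    )
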
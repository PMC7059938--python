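"""Experiment drivers and wavefront analysis.

Conduction velocity (CV) is estimated from activation times — first upward
0 mV crossings, linearly interpolated between samples — at interior sites
placed at 20% and 80% of the strand (ordered along the propagation
direction), which avoids both the stimulus artifact and the sealed-end
boundary effect.  A run is classified *blocked* when the strand end distal
to the pacing site never activates.

Drivers reproduce the standard experiments: CV versus coupling fraction
(beta sweeps), block-threshold search, CV restitution under progressively
faster pacing, and the mesh-refinement study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cellmodel, continuum
from .config import MODELS, Stimulus
from .results import SimulationResult

__all__ = [
    "CVResult",
    "activation_time",
    "conduction_velocity",
    "distal_activated",
    "build_config",
    "run_model",
    "cv_beta_sweep",
    "block_threshold",
    "restitution",
    "mesh_study",
    "default_restitution_schedule",
]


def activation_time(times, values, threshold: float = 0.0):
    """Time of the first upward crossing of ``threshold``, or None.

    Linear interpolation between samples; an initial sample already above
    threshold does not count (the wave must arrive, not start there).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0 or v.size != t.size:
        raise ValueError("empty or mismatched trace")
    below = v < threshold
    crossings = np.flatnonzero(below[:-1] & ~below[1:])
    if crossings.size == 0:
        return None
    i = int(crossings[0])
    frac = (threshold - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


@dataclass(frozen=True)
class CVResult:
    """Activation times (ms) at the two measurement sites and the CV (cm/s)."""

    x1: float
    x2: float
    t1: float | None
    t2: float | None
    cv: float | None
    blocked: bool


def _measurement_sites(result: SimulationResult, x1, x2):
    L = result.positions[-1]
    direction = result.meta.get("direction", "normal")
    if x1 is None or x2 is None:
        lo, hi = 0.2 * L, 0.8 * L
        x1, x2 = (lo, hi) if direction == "normal" else (hi, lo)
    return float(x1), float(x2)


def conduction_velocity(result: SimulationResult, x1=None, x2=None,
                        threshold: float = 0.0,
                        t_window=None) -> CVResult:
    """CV between two sites (default 20%/80% of the strand, ordered along
    the propagation direction recorded in the result metadata).

    ``cv = (|x2 - x1| mm) / (t2 - t1 ms)`` in cm/s; blocked when either site
    never activates or activation order contradicts the propagation
    direction.  ``t_window = (ta, tb)`` restricts the analysis (used for
    per-beat measurements in paced trains).
    """
    x1, x2 = _measurement_sites(result, x1, x2)
    # snap to the actual grid sites so distance and timing agree
    x1 = float(result.positions[result.site_index(x1)])
    x2 = float(result.positions[result.site_index(x2)])
    times, vmat = result.times, result.v
    if t_window is not None:
        sel = (times >= t_window[0]) & (times < t_window[1])
        times, vmat = times[sel], vmat[sel]
    t1 = t2 = None
    if times.size >= 2:
        t1 = activation_time(times, vmat[:, result.site_index(x1)], threshold)
        t2 = activation_time(times, vmat[:, result.site_index(x2)], threshold)
    if t1 is None or t2 is None or t2 <= t1:
        return CVResult(x1=x1, x2=x2, t1=t1, t2=t2, cv=None, blocked=True)
    cv = abs(x2 - x1) / (t2 - t1) * 100.0  # mm/ms -> cm/s
    return CVResult(x1=x1, x2=x2, t1=t1, t2=t2, cv=cv, blocked=False)


def distal_activated(result: SimulationResult, threshold: float = 0.0,
                     t_window=None) -> bool:
    """Did the strand end distal to the pacing site activate?"""
    direction = result.meta.get("direction", "normal")
    x_end = result.positions[-1] if direction == "normal" else result.positions[0]
    times, trace = result.times, result.trace_at(x_end)
    if t_window is not None:
        sel = (times >= t_window[0]) & (times < t_window[1])
        times, trace = times[sel], trace[sel]
    if times.size < 2:
        return False
    return activation_time(times, trace, threshold) is not None


def build_config(model: str, *, channel: str = "Cx43-Cx43",
                 regime: str = "instantaneous", beta: float = 1.0,
                 direction: str = "normal", h: float = 0.1, n_div: int = 10,
                 L: float = 6.4, dt=None, t_end=None, stimulus: Stimulus | None = None,
                 early_stop: bool = True, record_dt: float = 0.05):
    """Build the solver configuration for one of the four conduction models."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; valid: {', '.join(MODELS)}")
    stimulus = stimulus if stimulus is not None else Stimulus()
    if model in ("cm-clamped", "cm-gated"):
        geom = cellmodel.StrandGeometry(L=L, n_div=n_div)
        return cellmodel.CellularConfig(
            geometry=geom,
            variant="clamped" if model == "cm-clamped" else "voltage_gated",
            channel=channel, regime=regime, beta=beta, dt=dt,
            stimulus=stimulus, direction=direction, record_dt=record_dt,
            t_end=t_end, early_stop=early_stop,
        )
    return continuum.ContinuumConfig(
        model=model, mesh=continuum.Mesh1D(L=L, h=h), channel=channel,
        regime=regime, beta=beta, dt=dt, stimulus=stimulus,
        direction=direction, record_dt=record_dt, t_end=t_end,
        early_stop=early_stop,
    )


def simulate_config(config, state=None) -> SimulationResult:
    if isinstance(config, cellmodel.CellularConfig):
        return cellmodel.simulate(config, state)
    return continuum.simulate(config, state)


def run_model(model: str, *, t_end: float = 800.0, **kwargs) -> SimulationResult:
    """One paced episode of the chosen model, stopping early once the wave
    reaches the distal end or dies out."""
    return simulate_config(build_config(model, t_end=t_end, **kwargs))


def cv_beta_sweep(model: str, betas, *, channel="Cx43-Cx43",
                  regime="instantaneous", direction="normal",
                  t_end: float = 800.0, **kwargs) -> pd.DataFrame:
    """CV (cm/s) and block flag for each coupling fraction in ``betas``."""
    rows = []
    for beta in betas:
        res = run_model(model, channel=channel, regime=regime, beta=float(beta),
                        direction=direction, t_end=t_end, **kwargs)
        cvr = conduction_velocity(res)
        blocked = not distal_activated(res)
        rows.append({
            "model": model, "channel": channel, "regime": regime,
            "direction": direction, "beta": float(beta),
            "cv_cm_s": cvr.cv if not blocked else np.nan,
            "blocked": bool(blocked),
        })
    return pd.DataFrame(rows)


def block_threshold(model: str, beta_grid, *, channel="Cx43-Cx43",
                    regime="steady_state", direction="normal",
                    t_end: float = 800.0, **kwargs):
    """Largest coupling fraction in ``beta_grid`` whose run is blocked
    (no distal-end activation); None when every run propagates."""
    betas = sorted((float(b) for b in beta_grid), reverse=True)
    table = cv_beta_sweep(model, betas, channel=channel, regime=regime,
                          direction=direction, t_end=t_end, **kwargs)
    blocked = table.loc[table["blocked"], "beta"]
    return None if blocked.empty else float(blocked.max())


def default_restitution_schedule() -> list[float]:
    """Pacing cycle lengths (ms): coarse steps down to 400 ms, then 10 ms
    decrements until loss of propagation."""
    return [800.0, 600.0, 500.0, 450.0, 400.0] + list(np.arange(390.0, 249.0, -10.0))


def restitution(model: str, *, channel="Cx43-Cx45", regime="instantaneous",
                beta: float = 1.0, direction="normal", cl_schedule=None,
                n_beats: int = 5, record_dt: float = 0.25,
                **kwargs) -> pd.DataFrame:
    """CV restitution under a progressively faster continuous pacing train.

    Cycle lengths must decrease; ``n_beats`` pulses are delivered at each
    cycle length with the membrane state carried over, and CV is measured on
    the last beat of each train.  The schedule stops at the first cycle
    length whose last beat fails to activate the distal site (loss of
    propagation); that cycle length is recorded with ``captured = False``.
    """
    schedule = list(cl_schedule) if cl_schedule is not None else default_restitution_schedule()
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("cycle lengths must be strictly decreasing")
    state = None
    rows = []
    for cl in schedule:
        stim = Stimulus(cycle_length=float(cl), n_beats=n_beats)
        config = build_config(model, channel=channel, regime=regime, beta=beta,
                              direction=direction, stimulus=stim,
                              t_end=n_beats * float(cl), early_stop=False,
                              record_dt=record_dt, **kwargs)
        t0 = 0.0 if state is None else state.t
        res = simulate_config(config, state)
        state = res.final_state  # type: ignore[attr-defined]
        window = (t0 + (n_beats - 1) * cl, t0 + n_beats * cl)
        cvr = conduction_velocity(res, t_window=window)
        L = res.positions[-1]
        distal_site = 0.8 * L if direction == "normal" else 0.2 * L
        captured = (
            activation_time(
                res.times[(res.times >= window[0]) & (res.times < window[1])],
                res.trace_at(distal_site)[
                    (res.times >= window[0]) & (res.times < window[1])
                ],
            )
            is not None
        )
        rows.append({
            "model": model, "channel": channel, "regime": regime,
            "direction": direction, "beta": beta, "cl_ms": float(cl),
            "cv_cm_s": cvr.cv if captured else np.nan,
            "captured": bool(captured),
        })
        if not captured:
            break
    return pd.DataFrame(rows)


def loss_of_propagation_cl(table: pd.DataFrame):
    """First (largest) cycle length with failed distal activation, or None."""
    lost = table.loc[~table["captured"], "cl_ms"]
    return None if lost.empty else float(lost.max())


def mesh_study(model: str, h_list, *, channel="Cx43-Cx43",
               regime="instantaneous", beta: float = 1.0,
               t_end: float = 100.0, **kwargs) -> pd.DataFrame:
    """CV per mesh size.  For cellular models ``h`` is the sub-cellular
    segment length and must divide the cell length; incompatible sizes are
    skipped."""
    eps = cellmodel.StrandGeometry().eps
    rows = []
    for h in h_list:
        h = float(h)
        if model in ("cm-clamped", "cm-gated"):
            ratio = eps / h
            if h > eps + 1e-12 or abs(ratio - round(ratio)) > 1e-9:
                continue
            res = run_model(model, channel=channel, regime=regime, beta=beta,
                            n_div=int(round(ratio)), t_end=t_end, **kwargs)
        else:
            res = run_model(model, channel=channel, regime=regime, beta=beta,
                            h=h, t_end=t_end, **kwargs)
        cvr = conduction_velocity(res)
        rows.append({"model": model, "h_mm": h,
                     "cv_cm_s": cvr.cv, "blocked": cvr.blocked})
    return pd.DataFrame(rows)
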
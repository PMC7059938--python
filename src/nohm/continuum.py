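"""Tissue-scale 1-D monodomain solvers: NOHM and LHM.

Both models integrate the cable equation

.. math::

   \\partial_x(\\hat\\sigma(\\partial_x v)\\, \\partial_x v)
   = A_m (C_m \\partial_t v + I_{ion}(v, w))

on a coarse uniform mesh (default h = 100 um) with Luo-Rudy I kinetics.
The **LHM** uses the constant linear-homogenization conductivity; the
**NOHM** evaluates the gradient-dependent effective conductivity
``sigma_hat(y)`` per element (lagged one step, keeping the scheme fully
explicit) from a precomputed table.  With voltage-insensitive junctions
(``clamped`` regime) the NOHM table is constant and the two models produce
bit-identical trajectories.

Spatial discretization is standard Galerkin linear elements with a
consistent mass matrix (a tridiagonal solve per explicit step); pacing
enters as a boundary current flux at the paced end and the opposite end is
sealed (zero flux).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ionic_lr1
from .config import Stimulus
from .gapjunction import make_channel
from .homogenize import (
    EffectiveConductivityMap,
    Microstructure,
    effective_conductivity_map,
    lhm_sigma,
)
from .results import SimulationResult

__all__ = ["Mesh1D", "ContinuumConfig", "CableState", "sigma_table",
           "initial_state", "step", "simulate"]


@dataclass(frozen=True)
class Mesh1D:
    """Uniform 1-D mesh: ``round(L/h) + 1`` nodes over [0, L]."""

    L: float = 6.4
    h: float = 0.1

    def __post_init__(self) -> None:
        if self.h <= 0 or self.L <= 0:
            raise ValueError("mesh sizes must be positive")

    @property
    def n_nodes(self) -> int:
        return int(round(self.L / self.h)) + 1

    @property
    def positions(self) -> np.ndarray:
        return self.h * np.arange(self.n_nodes)


@dataclass
class ContinuumConfig:
    """One homogenized-model run."""

    model: str = "nohm"                    # nohm | lhm
    mesh: Mesh1D = field(default_factory=Mesh1D)
    channel: str = "Cx43-Cx43"
    regime: str = "instantaneous"          # instantaneous | steady_state | clamped
    beta: float = 1.0
    micro: Microstructure | None = None    # None -> built from channel/regime/beta
    r_cell: float = 0.011
    RCG: float = 2.0
    C_m: float = 0.01
    dt: float | None = None
    stimulus: Stimulus = field(default_factory=Stimulus)
    direction: str = "normal"
    record_dt: float = 0.05
    t_end: float | None = None
    early_stop: bool = False
    block_floor: float = -60.0
    disable_ionic: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("nohm", "lhm"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.direction not in ("normal", "retrograde"):
            raise ValueError(f"unknown direction {self.direction!r}")
        make_channel(self.channel)
        if self.micro is None:
            self.micro = Microstructure(
                beta=self.beta, regime=self.regime, channel=self.channel
            )
        bound = self.dt_stability_bound()
        if self.dt is None:
            self.dt = min(0.005, 0.9 * bound)
        elif self.dt > bound:
            raise ValueError(
                f"dt = {self.dt} ms violates the explicit stability bound "
                f"{bound:.3e} ms at h = {self.mesh.h} mm"
            )

    @property
    def A_m(self) -> float:
        return 2.0 * self.RCG / self.r_cell

    def dt_stability_bound(self) -> float:
        """Explicit limit h^2 Am Cm / (6 sigma_c) of the consistent-mass
        scheme (sigma_hat never exceeds sigma_c)."""
        return self.mesh.h**2 * self.A_m * self.C_m / (6.0 * self.micro.sigma_c)

    def meta(self) -> dict:
        return {
            "model": self.model,
            "channel": self.channel,
            "regime": self.regime,
            "beta": self.beta,
            "direction": self.direction,
            "dt_ms": self.dt,
            "h_mm": self.mesh.h,
            "n_nodes": self.mesh.n_nodes,
            "stimulus": {
                "amplitude_uA_mm2": self.stimulus.amplitude,
                "duration_ms": self.stimulus.duration,
                "cycle_length_ms": self.stimulus.cycle_length,
                "n_beats": self.stimulus.n_beats,
            },
        }


@dataclass
class CableState:
    v: np.ndarray
    w: np.ndarray
    t: float = 0.0

    def copy(self) -> "CableState":
        return CableState(v=self.v.copy(), w=self.w.copy(), t=self.t)


def sigma_table(config: ContinuumConfig) -> tuple[float, float, np.ndarray]:
    """(y0, 1/dy, sigma) table the kernel interpolates.

    LHM and the clamped-regime NOHM share a constant two-entry table, which
    makes their trajectories identical by construction.
    """
    if config.model == "lhm" or config.regime == "clamped":
        const = lhm_sigma(config.micro)
        return -2000.0, 1.0 / 4000.0, np.array([const, const])
    cmap: EffectiveConductivityMap = effective_conductivity_map(config.micro)
    dy = cmap.y[1] - cmap.y[0]
    return float(cmap.y[0]), float(1.0 / dy), cmap.sigma


def initial_state(config: ContinuumConfig) -> CableState:
    v0, w0 = ionic_lr1.rest_state()
    n = config.mesh.n_nodes
    return CableState(v=np.full(n, v0), w=np.tile(w0.as_array(), (n, 1)), t=0.0)


def _kernel_args(config: ContinuumConfig, state: CableState, n_steps: int,
                 rec_stride: int, early: bool):
    from . import _kernels

    n = config.mesh.n_nodes
    y0, inv_dy, tab = sigma_table(config)
    stim_node = 0 if config.direction == "normal" else n - 1
    watch = (n - 1 if config.direction == "normal" else 0) if early else -1
    starts = config.stimulus.start_times(t0=state.t)
    block_after = (starts[-1] + config.stimulus.duration + 50.0) if early else -1.0
    n_rec = n_steps // rec_stride + 1
    out_v = np.empty((n_rec, n))
    out_t = np.empty(n_rec)
    args = (
        state.v, state.w, y0, inv_dy, tab, config.mesh.h, config.dt, state.t,
        n_steps, config.A_m, config.C_m, stim_node, config.stimulus.amplitude,
        starts, config.stimulus.duration, rec_stride, out_v, out_t, watch,
        config.block_floor, block_after, 0 if config.disable_ionic else 1,
        _kernels.TAB,
    )
    return _kernels.run_cable, args, out_v, out_t


def step(state: CableState, config: ContinuumConfig) -> CableState:
    """One explicit update: lagged per-element sigma_hat, lumped mass."""
    from . import _kernels

    out = state.copy()
    run, args, _, _ = _kernel_args(config, out, n_steps=1, rec_stride=10**9,
                                   early=False)
    status, _, _ = run(*args)
    if status == _kernels.STATUS_NAN:
        raise FloatingPointError(f"solution lost finiteness at t = {state.t} ms")
    out.t = state.t + config.dt
    return out


def simulate(config: ContinuumConfig, state: CableState | None = None) -> SimulationResult:
    """Run the configured pacing episode and record v(x, t)."""
    from . import _kernels

    if state is None:
        state = initial_state(config)
    else:
        state = state.copy()
    t_end = (
        config.t_end
        if config.t_end is not None
        else config.stimulus.cycle_length * max(config.stimulus.n_beats, 1)
    )
    n_steps = int(round(t_end / config.dt))
    rec_stride = max(1, int(round(config.record_dt / config.dt)))
    run, args, out_v, out_t = _kernel_args(config, state, n_steps, rec_stride,
                                           early=config.early_stop)
    status, rows, t_stop = run(*args)
    if status == _kernels.STATUS_NAN:
        raise FloatingPointError(
            f"solution lost finiteness near t = {t_stop:.3f} ms "
            f"(dt = {config.dt} ms, h = {config.mesh.h} mm)"
        )
    state.t += n_steps * config.dt
    result = SimulationResult(
        times=out_t[:rows],
        positions=config.mesh.positions,
        v=out_v[:rows],
        meta=config.meta(),
        status=status,
    )
    result.final_state = state  # type: ignore[attr-defined]
    return result
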
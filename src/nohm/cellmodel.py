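"""Discrete cellular circuit models of the myocyte strand (CM).

A chain of cylindrical cells of length ``eps`` is discretized at
sub-cellular resolution: ``n_div`` segments per cell, segment length
``dx = eps/n_div``.  Neighboring nodes are connected by resistive links —
myoplasmic links of conductivity ``sigma_c`` inside a cell, and a
gap-junction link between cells whose conductivity is
``dx * beta * g_jo * g_j(Vj) / A_cell`` (so the link *conductance* equals
``beta g_jo g_j``).  Two variants:

* **CM clamped** — voltage-insensitive junctions, ``g_j ≡ 1``;
* **CM voltage-gated** — ``g_j`` evaluated each step at the transjunctional
  voltage ``Vj``, sampled one full cell away on each side of the junction,
  mimicking the dual-voltage-clamp measurement:
  ``Vj = v[i+1+(n_div-1)] - v[i-(n_div-1)]`` for the junction link (i, i+1).

Membrane dynamics at every node follow the Luo-Rudy I kinetics; the nodal
current balance is integrated with forward Euler at a time step bounded by
the explicit diffusion stability limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ionic_lr1
from .config import Stimulus
from .gapjunction import make_channel, normalized_conductance
from .results import SimulationResult

__all__ = [
    "StrandGeometry",
    "CellularConfig",
    "StrandState",
    "junction_links",
    "vj_sample_nodes",
    "junction_vj",
    "local_conductivity",
    "initial_state",
    "step",
    "simulate",
]

_REGIME_CODE = {"clamped": 0, "instantaneous": 1, "steady_state": 2}


@dataclass(frozen=True)
class StrandGeometry:
    """Geometry and membrane constants of the strand (mm, mS/mm, uF/mm^2)."""

    L: float = 6.4                  # strand length (mm)
    eps: float = 0.1                # cell length (mm)
    n_div: int = 10                 # segments per cell
    r_cell: float = 0.011           # cell radius (mm)
    delta: float = 1.0e-4           # intercalated-disc length ratio
    RCG: float = 2.0                # capacitive-to-geometric area ratio
    C_m: float = 0.01               # membrane capacitance (uF/mm^2 = 1 uF/cm^2)
    sigma_c: float = 0.667          # cytoplasmic conductivity (mS/mm)
    g_jo: float = 2.534e-3          # junction conductance (mS = 2.534 uS)

    def __post_init__(self) -> None:
        if self.n_div < 1:
            raise ValueError("need at least one segment per cell")
        n_cells = self.L / self.eps
        if abs(n_cells - round(n_cells)) > 1e-9:
            raise ValueError("strand length must be an integer number of cells")

    @property
    def n_cells(self) -> int:
        return int(round(self.L / self.eps))

    @property
    def dx(self) -> float:
        return self.eps / self.n_div

    @property
    def n_nodes(self) -> int:
        return self.n_cells * self.n_div + 1

    @property
    def A_cell(self) -> float:
        """Cross-sectional area pi r^2 (mm^2)."""
        return float(np.pi * self.r_cell**2)

    @property
    def A_m(self) -> float:
        """Surface-to-volume ratio 2 RCG / r_cell (1/mm)."""
        return 2.0 * self.RCG / self.r_cell

    @property
    def positions(self) -> np.ndarray:
        return self.dx * np.arange(self.n_nodes)


def junction_links(geom: StrandGeometry) -> np.ndarray:
    """Indices of the intercellular links (link j joins nodes j and j+1)."""
    k = np.arange(geom.n_cells - 1)
    return k * geom.n_div + geom.n_div - 1


def vj_sample_nodes(geom: StrandGeometry, link: int) -> tuple[int, int]:
    """Nodes (a, b) used to sample Vj = v[b] - v[a] for a junction link.

    Each lies one full cell away from the junction; boundary cells fall back
    to the nearest existing node.
    """
    a = max(link - (geom.n_div - 1), 0)
    b = min(link + 1 + (geom.n_div - 1), geom.n_nodes - 1)
    return a, b


def junction_vj(link: int, v: np.ndarray, geom: StrandGeometry) -> float:
    """Transjunctional voltage (mV) across an intercellular link."""
    if link not in set(junction_links(geom).tolist()):
        raise ValueError(f"link {link} is not an intercellular link")
    a, b = vj_sample_nodes(geom, link)
    return float(v[b] - v[a])


@dataclass
class CellularConfig:
    """One cellular-model run: variant, channel/regime/coupling, pacing."""

    geometry: StrandGeometry = field(default_factory=StrandGeometry)
    variant: str = "voltage_gated"         # voltage_gated | clamped
    channel: str = "Cx43-Cx43"
    regime: str = "instantaneous"          # instantaneous | steady_state | clamped
    beta: float = 1.0
    dt: float | None = None                # ms; None -> 0.9x the stability bound
    stimulus: Stimulus = field(default_factory=Stimulus)
    direction: str = "normal"              # normal (paced at x=0) | retrograde
    record_dt: float = 0.05                # output sampling interval (ms)
    t_end: float | None = None             # ms; None -> n_beats * cycle_length
    early_stop: bool = False               # stop on distal activation / decay
    block_floor: float = -60.0             # mV: "everything at rest" level
    disable_ionic: bool = False            # diagnostic: pure diffusion

    def __post_init__(self) -> None:
        if self.variant not in ("voltage_gated", "clamped"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.direction not in ("normal", "retrograde"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        make_channel(self.channel)
        if self.regime not in _REGIME_CODE:
            raise ValueError(f"unknown regime {self.regime!r}")
        bound = self.dt_stability_bound()
        if self.dt is None:
            self.dt = 0.9 * bound
        elif self.dt > bound:
            raise ValueError(
                f"dt = {self.dt} ms violates the explicit stability bound "
                f"{bound:.3e} ms at dx = {self.geometry.dx} mm"
            )

    @property
    def regime_code(self) -> int:
        return 0 if self.variant == "clamped" else _REGIME_CODE[self.regime]

    def junction_sigma_scale(self) -> float:
        """dx * beta * g_jo / A_cell: junction-link conductivity per unit g_j."""
        g = self.geometry
        return g.dx * self.beta * g.g_jo / g.A_cell

    def max_junction_g(self) -> float:
        """Upper bound of g_j over the physiological Vj range (for stability)."""
        if self.regime_code == 0:
            return 1.0
        vj = np.linspace(-300.0, 300.0, 1201)
        return float(np.max(normalized_conductance(vj, self.channel, self.regime)))

    def dt_stability_bound(self) -> float:
        """Explicit diffusion limit dx^2 Am Cm / (sigma_l + sigma_r), worst node."""
        g = self.geometry
        sig_gap = self.junction_sigma_scale() * self.max_junction_g()
        worst = 2.0 * max(g.sigma_c, sig_gap) if g.n_div == 1 else max(
            2.0 * g.sigma_c, g.sigma_c + sig_gap
        )
        if worst <= 0.0:
            return float("inf")  # fully decoupled chain: no diffusion limit
        return g.dx**2 * g.A_m * g.C_m / worst

    def meta(self) -> dict:
        return {
            "model": "cm-clamped" if self.variant == "clamped" else "cm-gated",
            "variant": self.variant,
            "channel": self.channel,
            "regime": self.regime,
            "beta": self.beta,
            "direction": self.direction,
            "dt_ms": self.dt,
            "dx_mm": self.geometry.dx,
            "n_nodes": self.geometry.n_nodes,
            "stimulus": {
                "amplitude_uA_mm2": self.stimulus.amplitude,
                "duration_ms": self.stimulus.duration,
                "cycle_length_ms": self.stimulus.cycle_length,
                "n_beats": self.stimulus.n_beats,
            },
        }


@dataclass
class StrandState:
    """Nodal potentials, gating/calcium state and the current model time."""

    v: np.ndarray           # (n_nodes,) mV
    w: np.ndarray           # (n_nodes, 7): m, h, j, d, f, X, Cai
    t: float = 0.0

    def copy(self) -> "StrandState":
        return StrandState(v=self.v.copy(), w=self.w.copy(), t=self.t)


def initial_state(config: CellularConfig) -> StrandState:
    """Uniform resting state on the strand."""
    v0, w0 = ionic_lr1.rest_state()
    n = config.geometry.n_nodes
    return StrandState(
        v=np.full(n, v0),
        w=np.tile(w0.as_array(), (n, 1)),
        t=0.0,
    )


def _gj_param_array(config: CellularConfig) -> np.ndarray:
    spec = make_channel(config.channel)
    p = np.zeros(8)
    if config.regime_code == 1:
        p[:5] = [spec.inst.G_neg, spec.inst.G_pos, spec.inst.VH_neg,
                 spec.inst.VH_pos, spec.inst.norm]
    elif config.regime_code == 2:
        ss = spec.ss
        p[:] = [ss.p, ss.d, ss.gmin_neg, ss.gmin_pos, ss.A_neg, ss.A_pos,
                ss.Vj0_neg, ss.Vj0_pos]
    return p


def _link_sigma(config: CellularConfig, v: np.ndarray) -> np.ndarray:
    """Per-link conductivities at the given nodal potentials."""
    g = config.geometry
    sig = np.full(g.n_nodes - 1, g.sigma_c)
    scale = config.junction_sigma_scale()
    for link in junction_links(g):
        if config.regime_code == 0:
            sig[link] = scale
        else:
            a, b = vj_sample_nodes(g, link)
            gj = normalized_conductance(
                float(v[b] - v[a]), config.channel, config.regime
            )
            sig[link] = scale * gj
    return sig


def local_conductivity(link: int, Vj: float, config: CellularConfig) -> float:
    """Conductivity (mS/mm) of one link: sigma_c inside a cell, the scaled
    junction conductance dx/(R_j A_cell) with R_j = 1/(beta g_jo g_j(Vj))
    across cells."""
    g = config.geometry
    if link not in set(junction_links(g).tolist()):
        return g.sigma_c
    gj = 1.0 if config.regime_code == 0 else float(
        normalized_conductance(Vj, config.channel, config.regime)
    )
    return config.junction_sigma_scale() * gj


def _kernel_args(config: CellularConfig, state: StrandState, n_steps: int,
                 rec_stride: int, early: bool):
    from . import _kernels

    g = config.geometry
    links = junction_links(g)
    ab = np.array([vj_sample_nodes(g, int(l)) for l in links], dtype=np.int64)
    junc_a = ab[:, 0] if ab.size else np.zeros(0, dtype=np.int64)
    junc_b = ab[:, 1] if ab.size else np.zeros(0, dtype=np.int64)
    sig = _link_sigma(config, state.v)
    stim_node = 0 if config.direction == "normal" else g.n_nodes - 1
    watch = (g.n_nodes - 1 if config.direction == "normal" else 0) if early else -1
    starts = config.stimulus.start_times(t0=state.t)
    block_after = (starts[-1] + config.stimulus.duration + 50.0) if early else -1.0
    n_rec = n_steps // rec_stride + 1
    out_v = np.empty((n_rec, g.n_nodes))
    out_t = np.empty(n_rec)
    args = (
        state.v, state.w, sig, links.astype(np.int64), junc_a, junc_b,
        config.regime_code, _gj_param_array(config),
        config.junction_sigma_scale(), g.dx, config.dt, state.t, n_steps,
        g.A_m, g.C_m, stim_node, config.stimulus.amplitude, starts,
        config.stimulus.duration, rec_stride, out_v, out_t, watch,
        config.block_floor, block_after, 0 if config.disable_ionic else 1,
        _kernels.TAB,
    )
    return _kernels.run_strand, args, out_v, out_t


def step(state: StrandState, config: CellularConfig) -> StrandState:
    """One forward-Euler update of all nodal potentials and ionic states."""
    from . import _kernels

    out = state.copy()
    run, args, _, _ = _kernel_args(config, out, n_steps=1, rec_stride=10**9,
                                   early=False)
    status, _, _ = run(*args)
    if status == _kernels.STATUS_NAN:
        raise FloatingPointError(f"solution lost finiteness at t = {state.t} ms")
    out.t = state.t + config.dt
    return out


def simulate(config: CellularConfig, state: StrandState | None = None) -> SimulationResult:
    """Run the configured pacing episode and record v(x, t).

    ``state`` continues a previous run (its ``t`` offsets only the recorded
    clock; pacing restarts at the current time).
    """
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
            f"(dt = {config.dt} ms, dx = {config.geometry.dx} mm)"
        )
    state.t += n_steps * config.dt
    result = SimulationResult(
        times=out_t[:rows],
        positions=config.geometry.positions,
        v=out_v[:rows],
        meta=config.meta(),
        status=status,
    )
    result.final_state = state  # type: ignore[attr-defined]
    return result
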
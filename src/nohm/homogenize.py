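"""Effective tissue conductivity from the periodic cell/junction lattice.

A strand of myocytes is modeled as a 1-D periodic microstructure: cytoplasm
of conductivity ``sigma_c`` over a fraction ``1 - delta`` of each period
``eps`` (the cell length), and a thin gap-junction region of nominal
conductivity ``delta * sigma_g`` over the remaining fraction ``delta``.
Asymptotic upscaling of this laminate yields an effective conductivity:

* linear (Ohmic junctions): the harmonic combination
  ``sigma_hat = [(1 - delta)/sigma_c + 1/(beta sigma_g)]^-1``, independent
  of the local field;
* non-Ohmic (voltage-gated junctions): ``sigma_hat(y)`` solves the implicit
  scalar problem

  .. math::

     \\hat\\sigma = \\sigma_c B / (\\sigma_c/\\sigma_g + (1-\\delta) B),
     \\qquad B = \\beta\\, g_j(S\\,\\varepsilon\\, [N](y)),

  with the junction jump ``[N](y) = (1 - delta)(1 - sigma_hat/sigma_c) y``
  (mV/mm) and ``y = dv/dx`` the macroscopic potential gradient.  Because
  ``g_j`` is bell-shaped in the steady-state regime, the map can admit
  multiple fixed points at large ``|y|``; the physical branch is selected by
  continuation from ``y = 0``.

A resistor-chain steady-state solver over the explicit microstructure
(:func:`micro_steady_oracle`) provides an independent check of the
homogenized limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .gapjunction import ChannelSpec, make_channel, normalized_conductance

__all__ = [
    "Microstructure",
    "EffectiveConductivityMap",
    "lhm_sigma",
    "nohm_sigma",
    "tabulate_sigma",
    "default_y_grid",
    "effective_conductivity_map",
    "micro_steady_oracle",
    "MicroOracleResult",
]


@dataclass(frozen=True)
class Microstructure:
    """Geometric and electrical constants of the periodic lattice.

    Units: mm, mS, mS/mm.  ``g_jo`` is the representative junction
    conductance (2.534 uS); the derived nominal gap conductivities are
    ``delta_sigma_g = g_jo * delta * eps / A_cell`` and
    ``sigma_g = delta_sigma_g / delta``.
    """

    eps: float = 0.1                 # cell length (mm)
    delta: float = 1.0e-4            # intercalated-disc length ratio
    sigma_c: float = 0.667           # cytoplasmic conductivity (mS/mm)
    g_jo: float = 2.534e-3           # junction conductance (mS = 1000 uS)
    r_cell: float = 0.011            # cell radius (mm)
    S: float = 2.0                   # jump scaling factor (dimensionless)
    beta: float = 1.0                # gap-junctional coupling fraction
    regime: str = "steady_state"     # clamped | instantaneous | steady_state
    channel: str = "Cx43-Cx43"

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        make_channel(self.channel)  # validates the name

    @property
    def A_cell(self) -> float:
        """Cross-sectional area pi r_cell^2 (mm^2; 380 um^2 for r = 11 um)."""
        return float(np.pi * self.r_cell**2)

    @property
    def delta_sigma_g(self) -> float:
        """Nominal gap-region conductivity g_jo*delta*eps/A_cell (mS/mm)."""
        return self.g_jo * self.delta * self.eps / self.A_cell

    @property
    def sigma_g(self) -> float:
        """Junction conductivity scale delta_sigma_g/delta (mS/mm)."""
        return self.delta_sigma_g / self.delta

    @property
    def channel_spec(self) -> ChannelSpec:
        return make_channel(self.channel)

    def g_j(self, Vj):
        """Normalized junction conductance law of this microstructure."""
        return normalized_conductance(Vj, self.channel, self.regime)


def lhm_sigma(micro: Microstructure) -> float:
    """Effective conductivity of the linear (Ohmic-junction) laminate, mS/mm.

    Harmonic combination of the cytoplasm and junction conductivities,
    weighted by their length fractions:
    ``[(1 - delta)/sigma_c + 1/(beta sigma_g)]^-1``.  This is exactly the
    non-Ohmic map with ``g_j`` replaced by 1.  Returns 0 for ``beta = 0``
    (fully uncoupled, degenerate).
    """
    if micro.beta == 0.0:
        return 0.0
    return 1.0 / ((1.0 - micro.delta) / micro.sigma_c + 1.0 / (micro.beta * micro.sigma_g))


def _sigma_map(sigma_hat: float, y: float, micro: Microstructure) -> float:
    """One application of the implicit map F(sigma_hat; y)."""
    jump = (1.0 - micro.delta) * (1.0 - sigma_hat / micro.sigma_c) * y
    B = micro.beta * float(micro.g_j(micro.S * micro.eps * jump))
    if B <= 0.0:
        return 0.0
    return micro.sigma_c * B / (micro.sigma_c / micro.sigma_g + (1.0 - micro.delta) * B)


def nohm_sigma(y: float, micro: Microstructure, x0: float | None = None,
               tol_factor: float = 1.0e-10, max_iter: int = 200) -> float:
    """Effective non-Ohmic conductivity sigma_hat(y) at gradient ``y`` (mV/mm).

    Solves the implicit fixed point by damped iteration seeded at the
    linear value (or ``x0`` for continuation), with a bisection fallback on
    the residual over (0, sigma_c].  Residual tolerance ``tol_factor *
    sigma_c``.
    """
    if not np.isfinite(y):
        raise ValueError("gradient y must be finite")
    if micro.beta == 0.0:
        return 0.0
    if micro.regime == "clamped":
        return lhm_sigma(micro)
    tol = tol_factor * micro.sigma_c
    s = lhm_sigma(micro) if x0 is None else float(x0)
    prev_step = 0.0
    damping = 1.0
    for _ in range(max_iter):
        s_new = _sigma_map(s, y, micro)
        step = s_new - s
        if step * prev_step < 0.0:
            damping = 0.5  # oscillation: damp permanently
        s = s + damping * step
        prev_step = step
        if abs(step) < tol:
            if abs(s - _sigma_map(s, y, micro)) < 10.0 * tol:
                return float(min(max(s, 0.0), micro.sigma_c))
            break
    # fallback: bracket all residual roots on (0, sigma_c] and take the one
    # closest to the continuation seed
    seed = lhm_sigma(micro) if x0 is None else float(x0)
    grid = np.linspace(1e-8 * micro.sigma_c, micro.sigma_c, 2001)
    res = np.array([g - _sigma_map(g, y, micro) for g in grid])
    roots = []
    for i in range(grid.size - 1):
        if res[i] == 0.0:
            roots.append(grid[i])
        elif res[i] * res[i + 1] < 0.0:
            roots.append(
                brentq(lambda s_: s_ - _sigma_map(s_, y, micro), grid[i], grid[i + 1],
                       xtol=tol)
            )
    if not roots:
        raise RuntimeError(
            f"effective-conductivity solve failed at y = {y} mV/mm "
            f"(beta = {micro.beta}, channel = {micro.channel}, regime = {micro.regime}): "
            "no residual sign change on (0, sigma_c]"
        )
    roots = np.asarray(roots)
    return float(roots[np.argmin(np.abs(roots - seed))])


def default_y_grid(y_max: float = 2000.0, dy: float = 1.0) -> np.ndarray:
    """Symmetric uniform gradient grid (mV/mm) for tabulation."""
    n = int(round(y_max / dy))
    return np.linspace(-y_max, y_max, 2 * n + 1)


@dataclass(frozen=True)
class EffectiveConductivityMap:
    """Tabulated sigma_hat(y) with linear interpolation.

    Queries outside the tabulated range fall back to a direct implicit
    solve seeded from the nearest table edge.
    """

    micro: Microstructure
    y: np.ndarray
    sigma: np.ndarray

    def __call__(self, y):
        yq = np.asarray(y, dtype=float)
        out = np.interp(yq, self.y, self.sigma)
        lo, hi = self.y[0], self.y[-1]
        if np.any(yq < lo) or np.any(yq > hi):
            flat = np.atleast_1d(out)
            yflat = np.atleast_1d(yq)
            for idx in np.flatnonzero((yflat < lo) | (yflat > hi)):
                edge = self.sigma[0] if yflat[idx] < lo else self.sigma[-1]
                flat[idx] = nohm_sigma(float(yflat[idx]), self.micro, x0=float(edge))
            out = flat.reshape(np.shape(yq))
        return float(out) if np.isscalar(y) else out


def tabulate_sigma(micro: Microstructure, y_grid=None) -> EffectiveConductivityMap:
    """Tabulate sigma_hat on ``y_grid`` by continuation outward from y = 0.

    The grid should be symmetric about 0 and cover the gradients expected
    during propagation (default +-2000 mV/mm at 1 mV/mm).
    """
    y = default_y_grid() if y_grid is None else np.asarray(y_grid, dtype=float)
    if y.size == 0:
        raise ValueError("empty gradient grid")
    sigma = np.empty_like(y)
    i0 = int(np.argmin(np.abs(y)))
    sigma[i0] = nohm_sigma(float(y[i0]), micro)
    for i in range(i0 + 1, y.size):
        sigma[i] = nohm_sigma(float(y[i]), micro, x0=sigma[i - 1])
    for i in range(i0 - 1, -1, -1):
        sigma[i] = nohm_sigma(float(y[i]), micro, x0=sigma[i + 1])
    return EffectiveConductivityMap(micro=micro, y=y, sigma=sigma)


@lru_cache(maxsize=32)
def _cached_map(micro: Microstructure) -> EffectiveConductivityMap:
    return tabulate_sigma(micro)


def effective_conductivity_map(micro: Microstructure) -> EffectiveConductivityMap:
    """Memoized default-grid tabulation for a given microstructure."""
    return _cached_map(micro)


@dataclass(frozen=True)
class MicroOracleResult:
    """Steady state of the explicit resistor-chain microstructure."""

    x: np.ndarray          # node positions (mm): period edges + cytoplasm ends
    u: np.ndarray          # nodal potentials (mV)
    current: float         # series current (uA)
    sigma_eff: float       # I L / (A_cell dV), mS/mm
    Vj: float              # per-junction voltage drop (mV)
    blocked: bool          # no junction root found on the continuation branch


def _junction_current(Vj: float, micro: Microstructure) -> float:
    """Junction I-V law: I = A_cell (sigma_g/eps) beta g_j(S Vj) Vj (uA)."""
    g = float(micro.g_j(micro.S * Vj))
    return micro.A_cell * micro.sigma_g / micro.eps * micro.beta * g * Vj


def micro_steady_oracle(micro: Microstructure, dV: float, n_cells: int,
                        n_current: int = 400) -> MicroOracleResult:
    """Steady conduction through ``n_cells`` explicit periods under drop ``dV``.

    Each period is a cytoplasmic resistor (length ``(1-delta) eps``,
    conductivity ``sigma_c``) in series with one nonlinear junction.  In
    steady state the current ``I`` is uniform; the junction drop ``Vj(I)``
    is found by 1-D root finding with continuation from ``I = 0`` (the
    junction I-V curve is non-monotone in the steady-state regime, and the
    branch through the origin is the physical one).  The outer equation
    ``n_cells (I R_cyt + Vj(I)) = dV`` is solved by bracketing and bisection
    on ``I``.  If ``dV`` demands more current than the junction branch can
    carry, the result is flagged ``blocked`` instead of raising.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if micro.beta == 0.0:
        raise ValueError("beta = 0 carries no current")
    sign = 1.0 if dV >= 0.0 else -1.0
    dv = abs(dV)
    A = micro.A_cell
    R_cyt = (1.0 - micro.delta) * micro.eps / (micro.sigma_c * A)  # kOhm-ish (mV/uA)

    # Peak current the junction branch through the origin can carry: walk the
    # I-V curve until it turns over (or far past the relevant voltage range).
    vj_grid = np.linspace(0.0, 500.0, 20001) * sign
    iv = np.array([_junction_current(vj, micro) for vj in vj_grid])
    iv_s = iv * sign
    # the physical branch continued from the origin ends at the first local
    # maximum of the I-V curve (bell-shaped g makes it N-shaped)
    drops = np.flatnonzero(np.diff(iv_s) < 0.0)
    turn = int(drops[0]) if drops.size else iv_s.size - 1
    i_max = iv_s[turn]

    def vj_of_current(i_signed: float) -> float:
        """Invert the junction I-V on the branch continued from the origin."""
        target = abs(i_signed)
        idx = int(np.searchsorted(iv_s[: turn + 1], target))
        if idx == 0:
            return 0.0
        lo, hi = vj_grid[idx - 1], vj_grid[idx]
        return brentq(
            lambda vj: sign * _junction_current(vj, micro) - target, min(lo, hi),
            max(lo, hi), xtol=1e-12,
        )

    def total_drop(i_abs: float) -> float:
        return n_cells * (i_abs * R_cyt + abs(vj_of_current(i_abs)))

    blocked = False
    if total_drop(i_max * (1.0 - 1e-12)) < dv:
        blocked = True
        i_sol = i_max
    else:
        i_sol = brentq(lambda i_: total_drop(i_) - dv, 0.0, i_max * (1.0 - 1e-12),
                       xtol=1e-14 * max(i_max, 1.0))
    vj = abs(vj_of_current(i_sol))

    # nodal potentials: u(0) = dV, u(L) = 0, sampled at each cytoplasm end
    # and each period boundary
    xs, us = [0.0], [dV]
    u = dV
    for k in range(n_cells):
        u -= sign * i_sol * R_cyt
        xs.append(k * micro.eps + (1.0 - micro.delta) * micro.eps)
        us.append(u)
        u -= sign * vj
        xs.append((k + 1) * micro.eps)
        us.append(u)
    L = n_cells * micro.eps
    sigma_eff = i_sol * L / (A * dv) if dv > 0 else float("nan")
    return MicroOracleResult(
        x=np.asarray(xs), u=np.asarray(us), current=sign * i_sol,
        sigma_eff=float(sigma_eff), Vj=sign * vj, blocked=blocked,
    )
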
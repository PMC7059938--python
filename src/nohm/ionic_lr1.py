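"""Luo–Rudy phase-I (1991 guinea-pig ventricular) membrane kinetics.

Supplies the transmembrane ionic current ``I_ion(v, w)`` and the gating
dynamics for the strand solvers.  Six currents are modeled: fast sodium
(m, h, j gates), slow inward calcium (d, f gates and intracellular Ca),
time-dependent potassium (X gate with inward rectification Xi),
time-independent potassium (K1, instantaneously rectifying), plateau
potassium, and a linear background current.  The standard published
parameter set with [K]o = 5.4 mM is used.

Units at this module's surface follow the original publication: voltages in
mV, time in ms, current densities in uA/cm^2, [Ca]i in mM.  The strand
solvers convert currents once to uA/mm^2 at their boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "IonicState",
    "IonicConstants",
    "LR1",
    "GATE_NAMES",
    "rate_constants",
    "gate_steady_state",
    "ionic_current",
    "step_gates",
    "rest_state",
]

GATE_NAMES = ("m", "h", "j", "d", "f", "X")


@dataclass(frozen=True)
class IonicConstants:
    """Maximal conductances (mS/cm^2), reversal potentials (mV) and fixed
    ionic concentrations (mM) of the six LR-I currents."""

    R: float = 8314.0        # mJ/(mol K)
    T: float = 310.0         # K
    F: float = 96484.6       # C/mol
    K_o: float = 5.4
    K_i: float = 145.0
    Na_o: float = 140.0
    Na_i: float = 18.0
    PR_NaK: float = 0.01833  # Na/K permeability ratio entering E_K
    g_Na: float = 23.0
    g_si: float = 0.09
    g_K_max: float = 0.282   # scaled by sqrt(K_o/5.4)
    g_K1_max: float = 0.6047 # scaled by sqrt(K_o/5.4)
    g_Kp: float = 0.0183
    g_b: float = 0.03921
    E_b: float = -59.87

    @property
    def RTF(self) -> float:
        return self.R * self.T / self.F

    @property
    def E_Na(self) -> float:
        return self.RTF * np.log(self.Na_o / self.Na_i)

    @property
    def E_K(self) -> float:
        return self.RTF * np.log(
            (self.K_o + self.PR_NaK * self.Na_o) / (self.K_i + self.PR_NaK * self.Na_i)
        )

    @property
    def E_K1(self) -> float:
        return self.RTF * np.log(self.K_o / self.K_i)

    @property
    def g_K(self) -> float:
        return self.g_K_max * np.sqrt(self.K_o / 5.4)

    @property
    def g_K1(self) -> float:
        return self.g_K1_max * np.sqrt(self.K_o / 5.4)


LR1 = IonicConstants()


@dataclass(frozen=True)
class IonicState:
    """Gating variables (dimensionless, in [0, 1]) and [Ca]i (mM) at one node."""

    m: float = 0.0017
    h: float = 0.983
    j: float = 0.995
    d: float = 0.003
    f: float = 0.999
    X: float = 0.0057
    Cai: float = 2.0e-4

    def __post_init__(self) -> None:
        for name in GATE_NAMES:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"gate {name} = {value} outside [0, 1]")
        if self.Cai <= 0.0:
            raise ValueError("Cai must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.h, self.j, self.d, self.f, self.X, self.Cai])

    @classmethod
    def from_array(cls, arr) -> "IonicState":
        m, h, j, d, f, X, cai = (float(x) for x in arr)
        return cls(m=m, h=h, j=j, d=d, f=f, X=X, Cai=cai)


def _safe_ratio(num, den, limit):
    """num/den with the analytic limit substituted where den ~ 0."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-9
    out = np.where(small, limit, np.asarray(num, dtype=float) / np.where(small, 1.0, den))
    return out


def rate_constants(v):
    """Voltage-dependent opening/closing rates of the six gates (1/ms).

    Returns a dict ``{gate: (alpha, beta)}``.  Vectorized over ``v``.
    """
    v = np.asarray(v, dtype=float)
    a_m = 0.32 * _safe_ratio(v + 47.13, 1.0 - np.exp(-0.1 * (v + 47.13)), 10.0)
    b_m = 0.08 * np.exp(-v / 11.0)

    lo = v < -40.0
    a_h = np.where(lo, 0.135 * np.exp(-(80.0 + v) / 6.8), 0.0)
    b_h = np.where(
        lo,
        3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
        1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
    )
    a_j = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78)
        / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0,
    )
    b_j = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
    )

    a_d = 0.095 * np.exp(-0.01 * (v - 5.0)) / (1.0 + np.exp(-0.072 * (v - 5.0)))
    b_d = 0.07 * np.exp(-0.017 * (v + 44.0)) / (1.0 + np.exp(0.05 * (v + 44.0)))
    a_f = 0.012 * np.exp(-0.008 * (v + 28.0)) / (1.0 + np.exp(0.15 * (v + 28.0)))
    b_f = 0.0065 * np.exp(-0.02 * (v + 30.0)) / (1.0 + np.exp(-0.2 * (v + 30.0)))
    a_X = 0.0005 * np.exp(0.083 * (v + 50.0)) / (1.0 + np.exp(0.057 * (v + 50.0)))
    b_X = 0.0013 * np.exp(-0.06 * (v + 20.0)) / (1.0 + np.exp(-0.04 * (v + 20.0)))
    return {
        "m": (a_m, b_m),
        "h": (a_h, b_h),
        "j": (a_j, b_j),
        "d": (a_d, b_d),
        "f": (a_f, b_f),
        "X": (a_X, b_X),
    }


def gate_steady_state(v):
    """Closed-form steady state alpha/(alpha+beta) of each gate at voltage v."""
    rates = rate_constants(v)
    return {name: a / (a + b) for name, (a, b) in rates.items()}


def xi_factor(v, constants: IonicConstants = LR1):
    """Inward-rectification factor Xi(v) of the time-dependent K current."""
    v = np.asarray(v, dtype=float)
    num = np.exp(0.04 * (v + 77.0)) - 1.0
    den = (v + 77.0) * np.exp(0.04 * (v + 35.0))
    lim = 0.04 / np.exp(0.04 * (v + 35.0))
    xi = 2.837 * _safe_ratio(num, den, lim)
    return np.where(v > -100.0, xi, 1.0)


def _k1_inf(v, constants: IonicConstants):
    dv = np.asarray(v, dtype=float) - constants.E_K1
    a = 1.02 / (1.0 + np.exp(0.2385 * (dv - 59.215)))
    b = (
        0.49124 * np.exp(0.08032 * (dv + 5.476))
        + np.exp(0.06175 * (dv - 594.31))
    ) / (1.0 + np.exp(-0.5143 * (dv + 4.753)))
    return a / (a + b)


def current_components(v, w: IonicState, constants: IonicConstants = LR1):
    """The six LR-I current densities (uA/cm^2) at (v, w), as a dict."""
    c = constants
    E_si = 7.7 - 13.0287 * np.log(w.Cai)
    i_Na = c.g_Na * w.m**3 * w.h * w.j * (v - c.E_Na)
    i_si = c.g_si * w.d * w.f * (v - E_si)
    i_K = c.g_K * w.X * xi_factor(v, c) * (v - c.E_K)
    i_K1 = c.g_K1 * _k1_inf(v, c) * (v - c.E_K1)
    Kp = 1.0 / (1.0 + np.exp((7.488 - v) / 5.98))
    i_Kp = c.g_Kp * Kp * (v - c.E_K1)
    i_b = c.g_b * (v - c.E_b)
    return {"Na": i_Na, "si": i_si, "K": i_K, "K1": i_K1, "Kp": i_Kp, "b": i_b}


def ionic_current(v, w: IonicState, constants: IonicConstants = LR1) -> float:
    """Total transmembrane ionic current density (uA/cm^2) at (v, w)."""
    return float(sum(current_components(v, w, constants).values()))


def step_gates(v, w: IonicState, dt: float, constants: IonicConstants = LR1) -> IonicState:
    """One forward-Euler update of the gating variables and [Ca]i.

    Gates are clipped to [0, 1] after the update.  ``dt`` in ms.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    rates = rate_constants(v)
    updates = {}
    for name in GATE_NAMES:
        a, b = rates[name]
        g = getattr(w, name)
        updates[name] = float(np.clip(g + dt * (a * (1.0 - g) - b * g), 0.0, 1.0))
    i_si = current_components(v, w, constants)["si"]
    cai = w.Cai + dt * (-1.0e-4 * i_si + 0.07 * (1.0e-4 - w.Cai))
    return replace(w, Cai=float(max(cai, 1.0e-12)), **updates)


@lru_cache(maxsize=4)
def _rest_state_cached(relax_ms: float, dt: float):
    from . import _kernels  # deferred: numba compilation is slow at import

    v, gates, cai = _kernels.relax_0d(-84.0, IonicState().as_array(), relax_ms, dt)
    arr = np.concatenate([gates, [cai]])
    return float(v), IonicState.from_array(arr)


def rest_state(relax_ms: float = 10_000.0, dt: float = 0.01):
    """Unstimulated fixed point ``(v, w)`` of the 0-D membrane model.

    Obtained by relaxing the same tabulated dynamics the strand solvers
    integrate, so the returned state is a numerical fixed point of the
    solver kernels.  The result is cached.
    """
    v, w = _rest_state_cached(relax_ms, dt)
    if not (-90.0 <= v <= -80.0):
        raise RuntimeError(f"rest-state relaxation did not converge: v = {v:.3f} mV")
    return v, w
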
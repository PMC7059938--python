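"""Voltage-dependent gap-junction conductance laws.

Gap junctions are intercellular channels built from paired connexin
hemichannels.  Their conductance depends on the transjunctional voltage
``Vj`` (the potential difference across the junction, in mV).  Two limiting
regimes bracket the dynamic behavior:

* ``instantaneous`` — the conductance right after a voltage step, before any
  gating relaxation (Vogel–Weingart-type law, nearly flat in ``Vj``);
* ``steady_state`` — the conductance after full gating relaxation, a
  Boltzmann-shaped bell that closes toward a residual conductance
  ``g_min`` at large ``|Vj|``;
* ``clamped`` — voltage-insensitive junctions, ``g ≡ 1`` (the Ohmic
  reference).

Three channel types are parameterized: the homotypic Cx43-Cx43 and
Cx45-Cx45 channels (symmetric conductance curves) and the heterotypic
Cx43-Cx45 channel, whose asymmetric curve makes conduction velocity depend
on the direction of propagation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KT_MEV",
    "CHANNELS",
    "REGIMES",
    "InstParams",
    "SSParams",
    "ChannelSpec",
    "make_channel",
    "g_inst",
    "g_ss",
    "normalized_conductance",
    "junctional_conductance",
    "write_registry",
    "read_registry",
    "export_conductance_table",
]

#: Boltzmann factor kT at physiological temperature, in meV.  The gating
#: valence z is converted to an exponential slope A = z/kT in 1/mV.
KT_MEV = 25.7

REGIMES = ("clamped", "instantaneous", "steady_state")


@dataclass(frozen=True)
class InstParams:
    """Parameters of the instantaneous (Vogel–Weingart) conductance law.

    ``G_neg``/``G_pos`` are dimensionless scale factors for the negative and
    positive ``Vj`` branches; ``VH_neg``/``VH_pos`` are the corresponding
    voltage scales in mV (``VH_neg < 0 < VH_pos``).
    """

    G_neg: float
    G_pos: float
    VH_neg: float
    VH_pos: float

    def __post_init__(self) -> None:
        if not (self.G_neg > 0 and self.G_pos > 0):
            raise ValueError("instantaneous scale factors G must be positive")
        if not (self.VH_neg < 0 < self.VH_pos):
            raise ValueError("expected VH_neg < 0 < VH_pos")

    @property
    def norm(self) -> float:
        """Normalization constant: the law's raw value averaged over the two
        branches at Vj = 0, so that the normalized conductance is ~1 there."""
        return 0.5 * (self.G_neg + self.G_pos)


@dataclass(frozen=True)
class SSParams:
    """Parameters of the steady-state (Boltzmann) conductance law.

    ``Vj0``: half-inactivation voltages (mV); ``gmin``: residual normalized
    conductances in (0, 1); ``z``: gating valences (``z_neg < 0 < z_pos``);
    ``p`` and ``d`` (mV) are the modified-Boltzmann shape parameters used by
    the heterotypic channel (``p = 1``, ``d = 0`` for homotypic channels).
    """

    Vj0_neg: float
    Vj0_pos: float
    gmin_neg: float
    gmin_pos: float
    z_neg: float
    z_pos: float
    p: float = 1.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gmin_neg < 1.0 and 0.0 < self.gmin_pos < 1.0):
            raise ValueError("gmin must lie in (0, 1)")
        if not (self.z_neg < 0.0 < self.z_pos):
            raise ValueError("expected z_neg < 0 < z_pos")
        if self.p <= 0.0:
            raise ValueError("p must be positive")

    @property
    def A_neg(self) -> float:
        """Exponential slope of the negative branch, z_neg/kT (1/mV)."""
        return self.z_neg / KT_MEV

    @property
    def A_pos(self) -> float:
        """Exponential slope of the positive branch, z_pos/kT (1/mV)."""
        return self.z_pos / KT_MEV


@dataclass(frozen=True)
class ChannelSpec:
    """Named bundle of instantaneous and steady-state parameters."""

    name: str
    inst: InstParams
    ss: SSParams


# Published dual-voltage-clamp fits for the three channel types.
_TABLE = {
    "Cx43-Cx43": dict(
        inst=InstParams(G_neg=1.99, G_pos=2.01, VH_neg=-175.8, VH_pos=318.4),
        ss=SSParams(Vj0_neg=-60.8, Vj0_pos=62.9, gmin_neg=0.26, gmin_pos=0.25,
                    z_neg=-3.4, z_pos=2.9, p=1.0, d=0.0),
    ),
    "Cx45-Cx45": dict(
        inst=InstParams(G_neg=1.99, G_pos=2.02, VH_neg=-112.7, VH_pos=135.0),
        ss=SSParams(Vj0_neg=-38.9, Vj0_pos=38.5, gmin_neg=0.16, gmin_pos=0.17,
                    z_neg=-2.5, z_pos=2.7, p=1.0, d=0.0),
    ),
    "Cx43-Cx45": dict(
        inst=InstParams(G_neg=1.93, G_pos=2.0, VH_neg=-130.0, VH_pos=404.0),
        ss=SSParams(Vj0_neg=-15.9, Vj0_pos=149.3, gmin_neg=0.05, gmin_pos=0.05,
                    z_neg=-2.1, z_pos=0.7, p=0.73, d=25.0),
    ),
}

CHANNELS = tuple(_TABLE)


def make_channel(name: str) -> ChannelSpec:
    """Return the :class:`ChannelSpec` for one of the known channel types.

    Raises ``ValueError`` for unknown names, listing the valid ones.
    """
    try:
        row = _TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown channel {name!r}; valid channels: {', '.join(CHANNELS)}"
        ) from None
    return ChannelSpec(name=name, inst=row["inst"], ss=row["ss"])


def g_inst(Vj, params: InstParams):
    """Normalized instantaneous conductance at transjunctional voltage ``Vj``.

    Each polarity branch evaluates ``G^s * (2*cosh(Vj/VH^s) - 1)`` and the
    result is divided by the Vj = 0 raw value ``(G_neg + G_pos)/2`` so the
    normalized conductance is ~1 at rest.  The tie at Vj = 0 uses the
    negative branch.  Accepts scalars or arrays.
    """
    vj = np.asarray(Vj, dtype=float)
    if not np.all(np.isfinite(vj)):
        raise ValueError("Vj must be finite")
    neg = vj <= 0.0
    vh = np.where(neg, params.VH_neg, params.VH_pos)
    scale = np.where(neg, params.G_neg, params.G_pos)
    g = scale * (2.0 * np.cosh(vj / vh) - 1.0) / params.norm
    return float(g) if np.isscalar(Vj) else g


def g_ss(Vj, params: SSParams):
    """Normalized steady-state conductance at transjunctional voltage ``Vj``.

    Boltzmann law ``(1 - gmin^s)/(p + exp(A^s (Vj - Vj0^s))) + gmin^s`` with
    the negative-polarity parameters on the ``Vj <= d`` branch and the
    positive-polarity ones on ``Vj > d``.  Accepts scalars or arrays.
    """
    vj = np.asarray(Vj, dtype=float)
    if not np.all(np.isfinite(vj)):
        raise ValueError("Vj must be finite")
    neg = vj <= params.d
    A = np.where(neg, params.A_neg, params.A_pos)
    Vj0 = np.where(neg, params.Vj0_neg, params.Vj0_pos)
    gmin = np.where(neg, params.gmin_neg, params.gmin_pos)
    expo = np.clip(A * (vj - Vj0), -500.0, 500.0)
    g = (1.0 - gmin) / (params.p + np.exp(expo)) + gmin
    return float(g) if np.isscalar(Vj) else g


def normalized_conductance(Vj, channel: ChannelSpec | str, regime: str):
    """Dispatch ``g_j(Vj)`` by conductance regime (``clamped`` gives 1)."""
    if isinstance(channel, str):
        channel = make_channel(channel)
    if regime == "clamped":
        vj = np.asarray(Vj, dtype=float)
        ones = np.ones_like(vj)
        return 1.0 if np.isscalar(Vj) else ones
    if regime == "instantaneous":
        return g_inst(Vj, channel.inst)
    if regime == "steady_state":
        return g_ss(Vj, channel.ss)
    raise ValueError(f"unknown regime {regime!r}; valid regimes: {', '.join(REGIMES)}")


def junctional_conductance(Vj, beta: float, regime: str, channel: ChannelSpec | str):
    """Coupling-scaled junction conductance ``beta * g_j(Vj)``.

    ``beta`` is the gap-junctional coupling fraction in [0, 1] (1 = normal
    coupling).  For the ``clamped`` regime the result is ``beta`` regardless
    of ``Vj``.  This is the dimensionless factor that multiplies the nominal
    gap conductivity to give the local gap-region conductivity.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    return beta * normalized_conductance(Vj, channel, regime)


# ---------------------------------------------------------------------------
# plain-text registry and curve export

_INST_KEYS = ("G_neg", "G_pos", "VH_neg", "VH_pos")
_SS_KEYS = ("Vj0_neg", "Vj0_pos", "gmin_neg", "gmin_pos", "z_neg", "z_pos", "p", "d")


def write_registry(path, channels=None) -> None:
    """Write channel parameters as a plain-text ``name.section.key = value`` file."""
    names = channels if channels is not None else CHANNELS
    with open(path, "w") as fh:
        for name in names:
            spec = make_channel(name)
            for key in _INST_KEYS:
                fh.write(f"{name}.inst.{key} = {getattr(spec.inst, key)!r}\n")
            for key in _SS_KEYS:
                fh.write(f"{name}.ss.{key} = {getattr(spec.ss, key)!r}\n")


def read_registry(path) -> dict[str, ChannelSpec]:
    """Read a registry file written by :func:`write_registry`."""
    raw: dict[str, dict[str, dict[str, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lhs, value = (part.strip() for part in line.split("=", 1))
            name, section, key = lhs.rsplit(".", 2)
            raw.setdefault(name, {}).setdefault(section, {})[key] = float(value)
    out = {}
    for name, sections in raw.items():
        out[name] = ChannelSpec(
            name=name,
            inst=InstParams(**sections["inst"]),
            ss=SSParams(**sections["ss"]),
        )
    return out


def export_conductance_table(channel: ChannelSpec | str, vj_grid, path=None):
    """Tabulate both conductance laws on ``vj_grid`` and write CSV.

    Columns: ``Vj_mV, g_inst, g_ss``.  Returns the CSV text; writes to
    ``path`` when given.  Useful for plotting the conductance curves.
    """
    if isinstance(channel, str):
        channel = make_channel(channel)
    vj = np.asarray(vj_grid, dtype=float)
    gi = g_inst(vj, channel.inst)
    gs = g_ss(vj, channel.ss)
    buf = io.StringIO()
    buf.write("Vj_mV,g_inst,g_ss\n")
    for row in zip(vj, gi, gs):
        buf.write("%.6g,%.8g,%.8g\n" % row)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
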
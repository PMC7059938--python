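"""Numba-compiled inner loops for the strand and cable solvers.

Internal unit system: mV, ms, mm, mS/mm, uF/mm^2; membrane currents are
converted from uA/cm^2 to uA/mm^2 at the solver boundary (factor 0.01).

The voltage-dependent Luo-Rudy rate functions and the purely
voltage-dependent current terms are tabulated once on a fine (0.01 mV) grid
at import time; the explicit integrators interpolate linearly in that
table.  The table is built from the exact closed forms in
:mod:`nohm.ionic_lr1` and is tested against them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import ionic_lr1 as _ion

# ---------------------------------------------------------------------------
# Luo-Rudy rate/current tables

V_TAB_MIN = -150.0
V_TAB_MAX = 200.0
V_TAB_STEP = 0.01

_E_NA = float(_ion.LR1.E_Na)
_E_K = float(_ion.LR1.E_K)
_E_K1 = float(_ion.LR1.E_K1)
_G_K = float(_ion.LR1.g_K)

# status codes returned by the time loops
STATUS_DONE = 0
STATUS_EARLY_PROPAGATED = 1
STATUS_EARLY_BLOCKED = 2
STATUS_NAN = 3


def _build_tables() -> np.ndarray:
    v = np.arange(V_TAB_MIN, V_TAB_MAX + 0.5 * V_TAB_STEP, V_TAB_STEP)
    n = v.size
    tab = np.empty((14, n))
    rates = _ion.rate_constants(v)
    for row, name in enumerate(_ion.GATE_NAMES):
        a, b = rates[name]
        tab[2 * row] = a
        tab[2 * row + 1] = b
    tab[12] = _G_K * _ion.xi_factor(v) * (v - _E_K)  # X-gated K current / X
    cst = _ion.LR1
    kp = 1.0 / (1.0 + np.exp((7.488 - v) / 5.98))
    tab[13] = (
        cst.g_K1 * _ion._k1_inf(v, cst) * (v - _E_K1)
        + cst.g_Kp * kp * (v - _E_K1)
        + cst.g_b * (v - cst.E_b)
    )
    return np.ascontiguousarray(tab)


TAB = _build_tables()
_N_TAB = TAB.shape[1]
_INV_DV = 1.0 / V_TAB_STEP

#: uA/cm^2 -> uA/mm^2
CUR_SCALE = 0.01


@njit(inline="always", cache=True)
def _node_update(v, g, i, dt, tab):
    """Ionic current (uA/cm^2) at node i plus in-place forward-Euler gate update."""
    u = (v - V_TAB_MIN) * _INV_DV
    if u < 0.0:
        u = 0.0
    top = _N_TAB - 1.0
    if u > top - 1e-9:
        u = top - 1e-9
    k = int(u)
    w = u - k
    am = tab[0, k] + w * (tab[0, k + 1] - tab[0, k])
    bm = tab[1, k] + w * (tab[1, k + 1] - tab[1, k])
    ah = tab[2, k] + w * (tab[2, k + 1] - tab[2, k])
    bh = tab[3, k] + w * (tab[3, k + 1] - tab[3, k])
    aj = tab[4, k] + w * (tab[4, k + 1] - tab[4, k])
    bj = tab[5, k] + w * (tab[5, k + 1] - tab[5, k])
    ad = tab[6, k] + w * (tab[6, k + 1] - tab[6, k])
    bd = tab[7, k] + w * (tab[7, k + 1] - tab[7, k])
    af = tab[8, k] + w * (tab[8, k + 1] - tab[8, k])
    bf = tab[9, k] + w * (tab[9, k + 1] - tab[9, k])
    ax = tab[10, k] + w * (tab[10, k + 1] - tab[10, k])
    bx = tab[11, k] + w * (tab[11, k + 1] - tab[11, k])
    xk = tab[12, k] + w * (tab[12, k + 1] - tab[12, k])
    iv = tab[13, k] + w * (tab[13, k + 1] - tab[13, k])

    m = g[i, 0]
    h = g[i, 1]
    jg = g[i, 2]
    d = g[i, 3]
    f = g[i, 4]
    x = g[i, 5]
    cai = g[i, 6]

    esi = 7.7 - 13.0287 * np.log(cai)
    isi = 0.09 * d * f * (v - esi)
    ina = 23.0 * m * m * m * h * jg * (v - _E_NA)
    iion = ina + isi + x * xk + iv

    m += dt * (am - (am + bm) * m)
    h += dt * (ah - (ah + bh) * h)
    jg += dt * (aj - (aj + bj) * jg)
    d += dt * (ad - (ad + bd) * d)
    f += dt * (af - (af + bf) * f)
    x += dt * (ax - (ax + bx) * x)
    cai += dt * (-1.0e-4 * isi + 0.07 * (1.0e-4 - cai))

    g[i, 0] = min(max(m, 0.0), 1.0)
    g[i, 1] = min(max(h, 0.0), 1.0)
    g[i, 2] = min(max(jg, 0.0), 1.0)
    g[i, 3] = min(max(d, 0.0), 1.0)
    g[i, 4] = min(max(f, 0.0), 1.0)
    g[i, 5] = min(max(x, 0.0), 1.0)
    g[i, 6] = max(cai, 1.0e-12)
    return iion


@njit(cache=True)
def _relax_0d(v0, w0, relax_ms, dt, tab):
    g = np.empty((1, 7))
    g[0, :] = w0
    v = v0
    n = int(relax_ms / dt)
    for _ in range(n):
        iion = _node_update(v, g, 0, dt, tab)
        v += dt * (-iion)  # Cm = 1 uF/cm^2
    return v, g[0, :6].copy(), g[0, 6]


def relax_0d(v0, w0, relax_ms, dt):
    """Relax the isolated (0-D) membrane to its resting fixed point."""
    return _relax_0d(v0, w0, relax_ms, dt, TAB)


@njit(cache=True)
def _pace_0d(v0, w0, t_end, dt, stim_amp, stim_starts, stim_dur, rec_stride, tab):
    g = np.empty((1, 7))
    g[0, :] = w0
    v = v0
    n = int(t_end / dt)
    n_rec = n // rec_stride + 1
    out_t = np.empty(n_rec)
    out_v = np.empty(n_rec)
    row = 0
    for step in range(n):
        t = step * dt
        if step % rec_stride == 0:
            out_t[row] = t
            out_v[row] = v
            row += 1
        s = 0.0
        for k in range(stim_starts.size):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                s = stim_amp
                break
        iion = _node_update(v, g, 0, dt, tab)
        v += dt * (s - iion)
    return out_t[:row], out_v[:row], v, g[0, :6].copy(), g[0, 6]


def pace_0d(v0, w0, t_end, dt, stim_amp, stim_starts, stim_dur, rec_stride):
    """0-D paced run; returns (t, v, v_end, gates_end, cai_end)."""
    return _pace_0d(v0, w0, t_end, dt, stim_amp, stim_starts, stim_dur,
                    rec_stride, TAB)


@njit(inline="always", cache=True)
def gj_eval(regime, vj, p):
    """Normalized junction conductance.

    regime 0 = clamped (g = 1), 1 = instantaneous, 2 = steady-state.
    Parameter layout: instantaneous ``[G-, G+, VH-, VH+, norm, 0, 0, 0]``;
    steady-state ``[p, d, gmin-, gmin+, A-, A+, Vj0-, Vj0+]``.
    """
    if regime == 0:
        return 1.0
    if regime == 1:
        if vj <= 0.0:
            raw = p[0] * (2.0 * np.cosh(vj / p[2]) - 1.0)
        else:
            raw = p[1] * (2.0 * np.cosh(vj / p[3]) - 1.0)
        return raw / p[4]
    if vj <= p[1]:
        gmin = p[2]
        e = p[4] * (vj - p[6])
    else:
        gmin = p[3]
        e = p[5] * (vj - p[7])
    if e > 500.0:
        return gmin
    return (1.0 - gmin) / (p[0] + np.exp(e)) + gmin


@njit(cache=True)
def run_strand(
    v,
    g,
    sig,
    junc_link,
    junc_a,
    junc_b,
    regime,
    gp,
    sig_scale,
    dx,
    dt,
    t0,
    n_steps,
    am,
    cm,
    stim_node,
    stim_amp,
    stim_starts,
    stim_dur,
    rec_stride,
    out_v,
    out_t,
    watch_node,
    block_floor,
    block_after,
    use_ionic,
    tab,
):
    """Forward-Euler time loop of the discrete cell-chain (circuit) model.

    ``sig`` holds per-link conductivities (mS/mm); entries listed in
    ``junc_link`` are refreshed every step from the transjunctional voltage
    ``v[junc_b] - v[junc_a]`` when ``regime > 0``.  The stimulus enters as a
    current flux (uA/mm^2) spread over the stimulated node's segment.
    Returns ``(status, rows_recorded, t_stop)``.
    """
    n = v.size
    nj = junc_link.size
    inv_dx2 = 1.0 / (dx * dx)
    amcm = am * cm
    row = 0
    status = STATUS_DONE
    chk = max(int(1.0 / dt), 1)
    t = t0
    for step in range(n_steps):
        t = t0 + step * dt
        if step % rec_stride == 0 and row < out_t.size:
            out_t[row] = t
            for i in range(n):
                out_v[row, i] = v[i]
            row += 1
        if regime > 0:
            for q in range(nj):
                vj = v[junc_b[q]] - v[junc_a[q]]
                sig[junc_link[q]] = sig_scale * gj_eval(regime, vj, gp)
        s = 0.0
        for k in range(stim_starts.size):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                s = stim_amp
                break
        f_prev = 0.0
        for i in range(n):
            if i < n - 1:
                f_next = sig[i] * (v[i + 1] - v[i])
            else:
                f_next = 0.0
            div = (f_next - f_prev) * inv_dx2
            if i == stim_node and s != 0.0:
                div += s / dx
            if use_ionic == 1:
                iion = _node_update(v[i], g, i, dt, tab)
            else:
                iion = 0.0
            v[i] += dt * (div / amcm - iion * CUR_SCALE / cm)
            f_prev = f_next
        if step % chk == 0:
            vmax = v[0]
            for i in range(1, n):
                if v[i] > vmax:
                    vmax = v[i]
            if not np.isfinite(vmax):
                status = STATUS_NAN
                break
            if watch_node >= 0 and v[watch_node] > 0.0:
                status = STATUS_EARLY_PROPAGATED
                break
            if block_after > 0.0 and t > block_after and vmax < block_floor:
                status = STATUS_EARLY_BLOCKED
                break
    return status, row, t


@njit(cache=True)
def run_cable(
    v,
    g,
    sig_y0,
    sig_inv_dy,
    sig_tab,
    h,
    dt,
    t0,
    n_steps,
    am,
    cm,
    stim_node,
    stim_amp,
    stim_starts,
    stim_dur,
    rec_stride,
    out_v,
    out_t,
    watch_node,
    block_floor,
    block_after,
    use_ionic,
    tab,
):
    """Forward-Euler time loop of the homogenized 1-D cable.

    The effective conductivity is interpolated per element from a uniform
    table over the potential gradient y = dv/dx (``sig_tab`` on the grid
    ``sig_y0 + k/sig_inv_dy``); a constant (two-entry) table yields the
    linear model.  Standard Galerkin linear elements with a consistent mass
    matrix (factored once, Thomas solve per step); the ionic current is
    nodally interpolated so it stays pointwise after the mass solve.  The
    stimulus is a boundary current flux (uA/mm^2).
    Returns ``(status, rows_recorded, t_stop)``.
    """
    n = v.size
    amcm = am * cm
    inv_h = 1.0 / h
    ntab = sig_tab.size
    row = 0
    status = STATUS_DONE
    chk = max(int(1.0 / dt), 1)
    t = t0

    # Thomas factorization of the dimensionless consistent mass matrix M/h:
    # diag 2/3 (1/3 at the ends), off-diagonals 1/6.
    cp = np.empty(n)
    diag = np.empty(n)
    for i in range(n):
        diag[i] = 1.0 / 3.0 if (i == 0 or i == n - 1) else 2.0 / 3.0
    off = 1.0 / 6.0
    cp[0] = off / diag[0]
    for i in range(1, n):
        cp[i] = off / (diag[i] - off * cp[i - 1])
    base = np.empty(n)
    sol = np.empty(n)

    for step in range(n_steps):
        t = t0 + step * dt
        if step % rec_stride == 0 and row < out_t.size:
            out_t[row] = t
            for i in range(n):
                out_v[row, i] = v[i]
            row += 1
        s = 0.0
        for k in range(stim_starts.size):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                s = stim_amp
                break
        # element fluxes -> nodal residual (internal force + boundary flux)
        f_prev = 0.0
        for i in range(n):
            if i < n - 1:
                y = (v[i + 1] - v[i]) * inv_h
                u = (y - sig_y0) * sig_inv_dy
                if u < 0.0:
                    u = 0.0
                top = ntab - 1.0
                if u > top - 1e-12:
                    u = top - 1e-12
                k2 = int(u)
                w = u - k2
                sg = sig_tab[k2] + w * (sig_tab[k2 + 1] - sig_tab[k2])
                f_next = sg * y
            else:
                f_next = 0.0
            base[i] = f_next - f_prev
            if i == stim_node and s != 0.0:
                base[i] += s
            f_prev = f_next
        # solve (M/h) sol = base  (Thomas)
        sol[0] = base[0] / diag[0]
        for i in range(1, n):
            sol[i] = (base[i] - off * sol[i - 1]) / (diag[i] - off * cp[i - 1])
        for i in range(n - 2, -1, -1):
            sol[i] -= cp[i] * sol[i + 1]
        for i in range(n):
            if use_ionic == 1:
                iion = _node_update(v[i], g, i, dt, tab)
            else:
                iion = 0.0
            v[i] += dt * (sol[i] * inv_h / amcm - iion * CUR_SCALE / cm)
        if step % chk == 0:
            vmax = v[0]
            for i in range(1, n):
                if v[i] > vmax:
                    vmax = v[i]
            if not np.isfinite(vmax):
                status = STATUS_NAN
                break
            if watch_node >= 0 and v[watch_node] > 0.0:
                status = STATUS_EARLY_PROPAGATED
                break
            if block_after > 0.0 and t > block_after and vmax < block_floor:
                status = STATUS_EARLY_BLOCKED
                break
    return status, row, t
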
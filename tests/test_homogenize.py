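"""Effective-conductivity maps against brute-force and resistor-chain oracles."""

import numpy as np
import pytest

from nohm.homogenize import (
    Microstructure,
    effective_conductivity_map,
    lhm_sigma,
    micro_steady_oracle,
    nohm_sigma,
    tabulate_sigma,
)


def brute_force_sigma(y, micro, n_scan=40001):
    """Independent oracle: exhaustive residual scan of
    R(s) = s - F(s; y) over (0, sigma_c], refined by bisection."""
    grid = np.linspace(1e-9, micro.sigma_c, n_scan)

    def F(s):
        jump = (1.0 - micro.delta) * (1.0 - s / micro.sigma_c) * y
        B = micro.beta * float(micro.g_j(micro.S * micro.eps * jump))
        return micro.sigma_c * B / (micro.sigma_c / micro.sigma_g + (1 - micro.delta) * B)

    res = np.array([s - F(s) for s in grid])
    sign_change = np.flatnonzero(res[:-1] * res[1:] < 0)
    assert sign_change.size >= 1
    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if (mid - F(mid)) * (lo - F(lo)) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestLinearConductivity:
    def test_equal_conductivities_halve(self):
        # sigma_c = sigma_g -> harmonic mean is half of each
        m = Microstructure(regime="clamped", beta=1.0,
                           g_jo=0.667 * np.pi * 0.011**2 / 0.1)
        assert m.sigma_g == pytest.approx(0.667, rel=1e-12)
        assert lhm_sigma(m) == pytest.approx(0.3335, abs=1e-4)

    def test_degenerate_and_limiting_cases(self):
        assert lhm_sigma(Microstructure(beta=0.0)) == 0.0
        assert lhm_sigma(Microstructure(beta=1e-6)) < 1e-5
        # junction resistance removed -> cytoplasm-limited
        m = Microstructure(g_jo=1e6)
        assert lhm_sigma(m) == pytest.approx(
            m.sigma_c / (1.0 - m.delta), rel=1e-4
        )

    def test_derived_constants_match_printed_values(self):
        m = Microstructure()
        assert round(m.A_cell * 1e6) == 380  # um^2 from r = 11 um
        # 1 mS/mm = 1 S/m, so the value is already on the printed scale
        assert m.delta_sigma_g == pytest.approx(6.67e-5, abs=5e-8)  # S/m
        assert m.sigma_g == pytest.approx(m.delta_sigma_g / m.delta)


class TestNonOhmicConductivity:
    def test_clamped_recovers_linear_model_exactly(self):
        m = Microstructure(beta=0.3, regime="clamped")
        for y in np.linspace(-2000.0, 2000.0, 41):
            assert nohm_sigma(float(y), m) == lhm_sigma(m)

    def test_zero_gradient_near_linear_value(self):
        # [N](0) = 0 so only g_j(0) =~ 1 separates the two
        m43 = Microstructure(beta=1.0, regime="steady_state", channel="Cx43-Cx43")
        assert nohm_sigma(0.0, m43) == pytest.approx(lhm_sigma(m43), rel=1e-3)
        m45 = Microstructure(beta=1.0, regime="steady_state", channel="Cx45-Cx45")
        assert nohm_sigma(0.0, m45) == pytest.approx(lhm_sigma(m45), rel=2e-2)

    @pytest.mark.parametrize("y", [-60.0, -250.0, 40.0, 800.0])
    @pytest.mark.parametrize("channel", ["Cx45-Cx45", "Cx43-Cx45"])
    def test_matches_brute_force_root(self, y, channel):
        m = Microstructure(beta=1.0, regime="steady_state", channel=channel)
        assert nohm_sigma(y, m) == pytest.approx(brute_force_sigma(y, m), rel=1e-6)

    def test_bounded_and_monotone_in_beta(self):
        y = -150.0
        prev = 0.0
        for beta in (0.05, 0.2, 0.5, 1.0):
            m = Microstructure(beta=beta, regime="steady_state", channel="Cx45-Cx45")
            s = nohm_sigma(y, m)
            assert 0.0 < s <= m.sigma_c
            assert s >= prev
            prev = s

    def test_homotypic_symmetry_heterotypic_asymmetry(self):
        m_sym = Microstructure(beta=1.0, regime="steady_state", channel="Cx45-Cx45")
        c_sym = tabulate_sigma(m_sym, np.linspace(-300, 300, 121))
        assert c_sym(100.0) == pytest.approx(c_sym(-100.0), rel=1e-2)
        m_asym = Microstructure(beta=1.0, regime="steady_state", channel="Cx43-Cx45")
        c_asym = tabulate_sigma(m_asym, np.linspace(-300, 300, 121))
        assert abs(c_asym(100.0) / c_asym(-100.0) - 1.0) > 0.2


class TestTabulation:
    def test_grid_point_and_midpoint_queries(self):
        m = Microstructure(beta=1.0, regime="steady_state", channel="Cx45-Cx45")
        grid = np.arange(-200.0, 201.0, 1.0)
        cmap = tabulate_sigma(m, grid)
        for y in (-117.0, 0.0, 53.0):
            assert cmap(y) == pytest.approx(nohm_sigma(y, m), abs=1e-6 * m.sigma_c)
        for y in (-116.5, 10.5):
            assert cmap(y) == pytest.approx(nohm_sigma(y, m), abs=1e-3 * m.sigma_c)

    def test_outside_grid_falls_back_to_direct_solve(self):
        m = Microstructure(beta=1.0, regime="steady_state", channel="Cx45-Cx45")
        cmap = tabulate_sigma(m, np.linspace(-50.0, 50.0, 101))
        assert cmap(400.0) == pytest.approx(nohm_sigma(400.0, m), rel=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tabulate_sigma(Microstructure(), np.array([]))

    def test_default_map_continuous(self):
        cmap = effective_conductivity_map(
            Microstructure(beta=1.0, regime="steady_state", channel="Cx43-Cx45")
        )
        steps = np.abs(np.diff(cmap.sigma))
        assert np.all(steps < 0.02 * cmap.micro.sigma_c)


class TestMicroOracle:
    def test_clamped_series_resistors_exact(self):
        m = Microstructure(beta=0.3, regime="clamped")
        r = micro_steady_oracle(m, dV=50.0, n_cells=16)
        assert r.sigma_eff == pytest.approx(lhm_sigma(m), rel=1e-12)
        assert not r.blocked

    def test_effective_conductivity_matches_homogenized_map(self):
        m = Microstructure(beta=1.0, regime="steady_state", channel="Cx45-Cx45")
        n = 32
        r = micro_steady_oracle(m, dV=-60.0 * n * m.eps, n_cells=n)
        assert r.sigma_eff == pytest.approx(nohm_sigma(-60.0, m), rel=1e-3)

    def test_profile_antisymmetric_under_polarity_flip(self):
        m = Microstructure(beta=1.0, regime="steady_state", channel="Cx45-Cx45")
        fwd = micro_steady_oracle(m, dV=40.0, n_cells=8)
        rev = micro_steady_oracle(m, dV=-40.0, n_cells=8)
        # Table 1 homotypic parameters are only near-symmetric
        assert np.max(np.abs(fwd.u + rev.u)) < 0.01 * 40.0

    def test_block_regime_flagged(self):
        m = Microstructure(beta=0.01, regime="steady_state", channel="Cx43-Cx45")
        r = micro_steady_oracle(m, dV=-500.0, n_cells=4)
        assert r.blocked

    def test_profile_error_first_order_in_cell_length(self):
        # sup-norm deviation from the homogenized (linear) profile shrinks
        # roughly linearly as the cell length is halved at fixed strand length
        L, y = 6.4, -40.0
        errs = []
        for n in (32, 64, 128):
            m = Microstructure(eps=L / n, beta=1.0, regime="steady_state",
                               channel="Cx45-Cx45")
            r = micro_steady_oracle(m, dV=y * L, n_cells=n)
            lin = y * L + (0.0 - y * L) * r.x / L
            errs.append(np.max(np.abs(r.u - lin)))
        assert errs[0] > errs[1] > errs[2]
        for a, b in zip(errs, errs[1:]):
            assert 1.3 < a / b < 3.0
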
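"""Gap-junction conductance laws against dual-clamp-fit oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nohm import gapjunction as gj


class TestChannelRegistry:
    @pytest.mark.parametrize(
        "name,vj0,gmin,z,p,d",
        [
            ("Cx43-Cx43", (-60.8, 62.9), (0.26, 0.25), (-3.4, 2.9), 1.0, 0.0),
            ("Cx45-Cx45", (-38.9, 38.5), (0.16, 0.17), (-2.5, 2.7), 1.0, 0.0),
            ("Cx43-Cx45", (-15.9, 149.3), (0.05, 0.05), (-2.1, 0.7), 0.73, 25.0),
        ],
    )
    def test_steady_state_parameters(self, name, vj0, gmin, z, p, d):
        spec = gj.make_channel(name)
        assert (spec.ss.Vj0_neg, spec.ss.Vj0_pos) == vj0
        assert (spec.ss.gmin_neg, spec.ss.gmin_pos) == gmin
        assert (spec.ss.z_neg, spec.ss.z_pos) == z
        assert spec.ss.p == p and spec.ss.d == d
        # exponential slopes derived from the gating valence and kT = 25.7 meV
        assert spec.ss.A_neg == pytest.approx(z[0] / 25.7)
        assert spec.ss.A_pos == pytest.approx(z[1] / 25.7)
        assert spec.ss.A_neg < 0 < spec.ss.A_pos

    def test_instantaneous_parameters(self):
        inst = gj.make_channel("Cx43-Cx43").inst
        assert (inst.G_neg, inst.G_pos) == (1.99, 2.01)
        assert (inst.VH_neg, inst.VH_pos) == (-175.8, 318.4)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="Cx43-Cx43"):
            gj.make_channel("Cx40-Cx40")

    def test_registry_round_trip(self, tmp_path):
        path = tmp_path / "channels.cfg"
        gj.write_registry(path)
        loaded = gj.read_registry(path)
        for name in gj.CHANNELS:
            assert loaded[name] == gj.make_channel(name)


class TestInstantaneousConductance:
    def test_normalized_to_one_at_rest(self):
        # G_neg / mean(G+-) on the negative branch at the Vj = 0 tie
        spec = gj.make_channel("Cx43-Cx43")
        assert gj.g_inst(0.0, spec.inst) == pytest.approx(0.995, abs=1e-12)

    def test_large_negative_voltage(self):
        # frozen from direct evaluation G_neg (2 cosh(100/175.8) - 1) / 2.00
        spec = gj.make_channel("Cx43-Cx43")
        assert gj.g_inst(-100.0, spec.inst) == pytest.approx(1.3257228, rel=1e-6)

    def test_branch_mismatch_at_zero_is_small(self):
        for name in gj.CHANNELS:
            p = gj.make_channel(name).inst
            jump = abs(gj.g_inst(-1e-12, p) - gj.g_inst(1e-12, p))
            assert jump == pytest.approx(abs(p.G_neg - p.G_pos) / p.norm, abs=1e-6)
            assert jump < 0.04

    def test_cosh_grouping_identity(self):
        # e^{-x}/(1+e^{x}) + e^{x}/(1+e^{-x}) simplifies to 2 cosh(x) - 1
        x = np.linspace(-3.0, 3.0, 41)
        lhs = np.exp(-x) / (1 + np.exp(x)) + np.exp(x) / (1 + np.exp(-x))
        assert np.allclose(lhs, 2.0 * np.cosh(x) - 1.0, rtol=1e-12)


class TestSteadyStateConductance:
    def test_near_unity_at_rest(self):
        spec = gj.make_channel("Cx43-Cx43")
        assert gj.g_ss(0.0, spec.ss) == pytest.approx(0.9998, abs=2e-4)

    def test_saturates_at_residual_conductance(self):
        spec = gj.make_channel("Cx43-Cx43")
        assert gj.g_ss(-150.0, spec.ss) == pytest.approx(0.260, abs=1e-3)
        assert gj.g_ss(-1000.0, spec.ss) == pytest.approx(spec.ss.gmin_neg, abs=1e-9)
        assert gj.g_ss(1000.0, spec.ss) == pytest.approx(spec.ss.gmin_pos, abs=1e-9)

    def test_heterotypic_continuity_at_branch_point(self):
        # the modified-Boltzmann branch point d = 25 mV: both polarities give
        # g ~ 1.29 there
        spec = gj.make_channel("Cx43-Cx45")
        lo, hi = gj.g_ss(25.0 - 1e-9, spec.ss), gj.g_ss(25.0 + 1e-9, spec.ss)
        assert lo == pytest.approx(1.29, abs=5e-3)
        assert abs(hi - lo) < 3e-3

    def test_homotypic_near_symmetry(self):
        # the published homotypic fits are only near-symmetric: tight at
        # small Vj, but the half-inactivation/valence differences (e.g.
        # -60.8/62.9 mV, -3.4/2.9 for Cx43-Cx43) let the mismatch grow to
        # ~11% on the steep flank near |Vj| ~ 70 mV
        vj = np.linspace(0.1, 100.0, 200)
        for name in ("Cx43-Cx43", "Cx45-Cx45"):
            p = gj.make_channel(name).ss
            ratio = gj.g_ss(-vj, p) / gj.g_ss(vj, p)
            assert np.all(np.abs(ratio - 1.0) < 0.12)
            assert np.mean(np.abs(ratio - 1.0)) < 0.04

    def test_bell_shape_decays_beyond_peak(self):
        # monotone decay to gmin on each side beyond the peak
        for name in gj.CHANNELS:
            p = gj.make_channel(name).ss
            right = gj.g_ss(np.linspace(p.d + 60, 300, 100), p)
            left = gj.g_ss(np.linspace(p.d - 60, -300, 100), p)
            assert np.all(np.diff(right) <= 1e-12)
            assert np.all(np.diff(left) <= 1e-12)
            assert np.all(right > p.gmin_pos - 1e-12)
            assert np.all(left > p.gmin_neg - 1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    vj=st.floats(-300.0, 300.0),
    name=st.sampled_from(gj.CHANNELS),
    regime=st.sampled_from(gj.REGIMES),
)
def test_conductance_positive_and_bounded(vj, name, regime):
    g = gj.normalized_conductance(vj, name, regime)
    assert 0.0 < g < 20.0
    if regime == "clamped":
        assert g == 1.0


class TestJunctionalConductance:
    def test_scaling_and_clamped(self):
        assert gj.junctional_conductance(-40.0, 0.0, "steady_state", "Cx43-Cx43") == 0.0
        assert gj.junctional_conductance(123.0, 0.1, "clamped", "Cx43-Cx43") == 0.1
        g = gj.junctional_conductance(0.0, 1.0, "steady_state", "Cx43-Cx43")
        assert g == pytest.approx(0.9998, abs=2e-4)

    def test_clamped_is_constant_in_vj(self):
        vals = {gj.junctional_conductance(v, 0.37, "clamped", "Cx45-Cx45")
                for v in (-200.0, -1.0, 0.0, 55.0)}
        assert vals == {0.37}

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            gj.junctional_conductance(0.0, 1.5, "clamped", "Cx43-Cx43")

    def test_curve_export(self, tmp_path):
        path = tmp_path / "curves.csv"
        text = gj.export_conductance_table("Cx45-Cx45", [-50.0, 0.0, 50.0], path)
        assert path.read_text() == text
        assert text.splitlines()[0] == "Vj_mV,g_inst,g_ss"
        assert len(text.splitlines()) == 4
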
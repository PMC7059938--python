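"""Discrete cell-chain model: geometry, junction handling, integration."""

import numpy as np
import pytest

from nohm import cellmodel as cm
from nohm.config import Stimulus


@pytest.fixture()
def geom():
    return cm.StrandGeometry()


def make_config(**kw):
    defaults = dict(variant="voltage_gated", channel="Cx43-Cx43",
                    regime="instantaneous", beta=1.0)
    defaults.update(kw)
    return cm.CellularConfig(**defaults)


class TestGeometry:
    def test_default_strand_bookkeeping(self, geom):
        assert geom.n_cells == 64
        assert geom.dx == pytest.approx(0.01)
        assert geom.n_nodes == 641
        assert geom.A_m == pytest.approx(363.64, rel=1e-3)
        assert round(geom.A_cell * 1e6) == 380

    def test_junction_links_between_cells(self, geom):
        links = cm.junction_links(geom)
        assert links.size == geom.n_cells - 1
        assert links[0] == 9 and links[-1] == 629
        assert np.all(np.diff(links) == geom.n_div)

    def test_incommensurate_length_rejected(self):
        with pytest.raises(ValueError):
            cm.StrandGeometry(L=6.45)


class TestJunctionVoltage:
    def test_uniform_potential_gives_zero(self, geom):
        v = np.full(geom.n_nodes, -84.0)
        assert cm.junction_vj(9, v, geom) == 0.0

    def test_linear_profile_spans_two_cells(self, geom):
        # sampling nodes sit n_div - 1 nodes away on each side of the
        # junction link: 2 n_div - 1 = 19 node spacings for n_div = 10
        s = 0.5  # mV per node
        v = s * np.arange(geom.n_nodes, dtype=float)
        assert cm.junction_vj(319, v, geom) == pytest.approx(19 * s)

    def test_sign_flip_under_profile_inversion(self, geom):
        rng = np.random.default_rng(1)
        v = rng.normal(size=geom.n_nodes)
        assert cm.junction_vj(319, -v, geom) == pytest.approx(
            -cm.junction_vj(319, v, geom)
        )

    def test_intracellular_link_rejected(self, geom):
        v = np.zeros(geom.n_nodes)
        with pytest.raises(ValueError, match="intercellular"):
            cm.junction_vj(10, v, geom)


class TestLocalConductivity:
    def test_intracellular_is_cytoplasmic(self):
        config = make_config()
        assert cm.local_conductivity(5, 0.0, config) == pytest.approx(0.667)

    def test_clamped_junction_link_carries_gjo(self):
        # link conductance sigma A/dx at beta = 1 equals the nominal junction
        # conductance 2.534 uS
        config = make_config(variant="clamped")
        g = config.geometry
        sigma = cm.local_conductivity(9, 0.0, config)
        conductance_mS = sigma * g.A_cell / g.dx
        assert conductance_mS == pytest.approx(2.534e-3, rel=1e-12)
        # and g_jo matches the conductance of one cell's cytoplasm, so the
        # series per-cell conductivity is ~sigma_c/2 = 0.333 mS/mm
        cytoplasm_mS = g.sigma_c * g.A_cell / g.eps
        assert cytoplasm_mS == pytest.approx(2.534e-3, rel=1e-3)

    def test_gated_at_zero_vj_matches_clamped(self):
        gated = make_config(regime="steady_state")
        clamped = make_config(variant="clamped")
        s1 = cm.local_conductivity(9, 0.0, gated)
        s2 = cm.local_conductivity(9, 0.0, clamped)
        assert s1 == pytest.approx(s2, rel=1e-3)

    def test_beta_zero_disconnects(self):
        config = make_config(beta=0.0, variant="clamped")
        assert cm.local_conductivity(9, 0.0, config) == 0.0


class TestStability:
    def test_default_dt_respects_bound(self):
        config = make_config()
        assert config.dt <= config.dt_stability_bound()
        assert config.dt == pytest.approx(0.9 * config.dt_stability_bound())

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError, match="stability"):
            make_config(dt=0.005)


class TestStep:
    def test_uniform_rest_is_numerical_fixed_point(self):
        config = make_config(t_end=1.0)
        state = cm.initial_state(config)
        # no stimulus
        config.stimulus = Stimulus(amplitude=0.0)
        out = cm.step(state, config)
        assert np.max(np.abs(out.v - state.v)) < 1e-12

    def test_charge_conserved_without_membrane_current(self):
        config = make_config(disable_ionic=True)
        config.stimulus = Stimulus(amplitude=0.0)
        state = cm.initial_state(config)
        rng = np.random.default_rng(2)
        state.v = -84.0 + 10.0 * rng.random(state.v.size)
        mean0 = state.v.mean()
        for _ in range(200):
            state = cm.step(state, config)
        assert state.v.mean() == pytest.approx(mean0, abs=1e-10)
        assert np.std(state.v) < 10.0  # diffusion smooths, never amplifies

    def test_decoupled_nodes_integrate_stimulus_only(self):
        # with all link conductivities zero and no membrane current, only the
        # stimulated node changes, by dt*amp/(dx Am Cm) per step
        geom = cm.StrandGeometry(sigma_c=0.0)
        config = cm.CellularConfig(geometry=geom, variant="clamped",
                                   beta=0.0, disable_ionic=True, dt=1e-4,
                                   stimulus=Stimulus(amplitude=30.0))
        state = cm.initial_state(config)
        out = cm.step(state, config)
        dv = out.v - state.v
        expected = config.dt * 30.0 / (geom.dx * geom.A_m * geom.C_m)
        assert dv[0] == pytest.approx(expected, rel=1e-12)
        assert np.all(dv[1:] == 0.0)


class TestSimulate:
    def test_zero_stimulus_stays_at_rest(self):
        config = make_config(t_end=5.0, stimulus=Stimulus(amplitude=0.0))
        res = cm.simulate(config)
        assert np.max(np.abs(res.v - res.v[0, 0])) < 1e-6

    def test_gated_with_unit_conductance_matches_clamped_bitwise(self, monkeypatch):
        # forcing g_j = 1 in the voltage-gated variant must reproduce the
        # clamped trajectory exactly (they solve the same circuit)
        import nohm.cellmodel as cmod

        gated = make_config(regime="steady_state", beta=0.4, t_end=5.0)
        clamped = make_config(variant="clamped", beta=0.4, t_end=5.0)
        unit = np.array([1.0, 0.0, 1.0, 1.0, -0.1, 0.1, 0.0, 0.0])  # gmin = 1
        monkeypatch.setattr(cmod, "_gj_param_array", lambda cfg: unit)
        r1 = cmod.simulate(gated)
        r2 = cmod.simulate(clamped)
        assert np.array_equal(r1.v, r2.v)

    def test_retrograde_mirrors_normal_for_homotypic_channel(self):
        from nohm import protocols

        cvs = {}
        for direction in ("normal", "retrograde"):
            res = protocols.run_model("cm-gated", channel="Cx43-Cx43",
                                      regime="instantaneous", beta=1.0,
                                      direction=direction, t_end=40.0)
            cvs[direction] = protocols.conduction_velocity(res).cv
        assert cvs["retrograde"] == pytest.approx(cvs["normal"], rel=1e-2)

    def test_metadata_embedded(self):
        config = make_config(t_end=1.0)
        res = cm.simulate(config)
        assert res.meta["model"] == "cm-gated"
        assert res.meta["n_nodes"] == 641
        assert res.meta["dt_ms"] == config.dt
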
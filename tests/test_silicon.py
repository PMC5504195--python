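import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from siplant import (SiParams, SiState, axial_si_flux, junction_partition,
                     root_uptake_fluxes, step_root, unload_flux)
from siplant.hydraulics import WaterState
from siplant.silicon import SiliconStepper, mixing_volumes
from siplant.plant_network import Pathway, RootParams

from conftest import make_chain_plant


def _state(g, c_m_out=1.0, alpha=1.0, c_m_cor=0.0):
    s = SiState.initial(g, c_m_out, SiParams())
    s.alpha = alpha
    s.c_m_cor = c_m_cor
    return s


def _still_water(g):
    """A zero-flow WaterState for kernel tests."""
    n = g.n_nodes
    nx = len(g.edges_of(Pathway.XYLEM))
    np_ = len(g.edges_of(Pathway.PHLOEM))
    z = np.zeros
    return WaterState(z(n), z(n), z(n), z(n), z(nx), z(np_), z(n), 0.0,
                      z(len(g.leaf_indices)))


class TestRootUptake:
    def test_transporter_plus_leak(self):
        g = make_chain_plant(3)
        g.root = RootParams(2.0, 1.0, 0.1, 1.0, 0.05, 0.0)
        s = _state(g, c_m_out=1.0, c_m_cor=0.5)
        j_oc, _ = root_uptake_fluxes(s, g.root)
        assert j_oc == pytest.approx(2.0 * 1.0 - 0.1 * (0.5 - 1.0))  # 2.05

    def test_pure_leak_vanishes_at_equal_concentrations(self):
        g = make_chain_plant(3)
        s = _state(g, c_m_out=1.0, alpha=0.0, c_m_cor=1.0)
        j_oc, _ = root_uptake_fluxes(s, g.root)
        assert j_oc == 0.0

    def test_cortex_steady_state_matches_bisection(self):
        """Long-run cortex concentration solves J_oc(C) = J_cs(C), the root
        found independently by bisection on the two flux expressions."""
        g = make_chain_plant(3)
        root = g.root
        alpha, c_out, c_st = 0.7, 1.0, 0.2

        def imbalance(c_cor):
            j_oc = alpha * root.tr_exo * c_out - root.p_cm * (c_cor - c_out)
            j_cs = alpha * root.tr_end * c_cor - root.p_cm * (c_st - c_cor)
            return j_oc - j_cs

        c_star = bisect(imbalance, 0.0, 100.0, xtol=1e-12)
        s = _state(g, alpha=alpha)
        s.c_m[0] = c_st
        v_mix = mixing_volumes(g, SiParams())[0]
        for _ in range(20000):
            s = step_root(s, root, j_m_up=0.0, dt=0.05, v_mix_root=v_mix)
            s.c_m[0] = c_st  # hold the stele fixed as in the oracle
        assert s.c_m_cor == pytest.approx(c_star, rel=1e-6)

    def test_step_root_arithmetic(self):
        g = make_chain_plant(3)
        g.root = RootParams(2.0, 0.0, 0.1, 1.0, 0.05, 0.0)
        s = _state(g, c_m_out=1.0, c_m_cor=0.5)
        # J_oc = 2.05, J_cs = -p_cm*(0 - 0.5) = 0.05
        out = step_root(s, g.root, 0.0, 0.1, v_mix_root=0.1)
        assert out.c_m_cor == pytest.approx(0.5 + 0.1 * (2.05 - 0.05) / 1.0)

    def test_zero_fluxes_freeze_state(self):
        g = make_chain_plant(3)
        g.root = RootParams(0.0, 0.0, 0.0, 1.0, 0.05, 0.0)
        s = _state(g, c_m_out=0.0)
        out = step_root(s, g.root, 0.0, 0.5, v_mix_root=0.1)
        assert out.c_m_cor == s.c_m_cor
        assert np.array_equal(out.c_m, s.c_m)


class TestAxialFlux:
    @pytest.mark.parametrize("c,j,expected", [
        (0.0, 5.0, 0.0),
        (1.5, 2.0, 3.0),
        (1.5, -2.0, 0.0),  # no transport against the transpiration stream
    ])
    def test_cases(self, c, j, expected):
        assert axial_si_flux(c, j) == expected


class TestJunctionPartition:
    def test_rho_one_is_noop(self):
        c_dvb, c_evb = junction_partition(1.7, 0.4, 1.1, 1.0)
        assert c_dvb == pytest.approx(1.7)
        assert c_evb == pytest.approx(1.7)

    def test_worked_example_conserves_mass(self):
        c_dvb, c_evb = junction_partition(1.0, 1.0, 3.0, 2.0)
        assert c_evb == pytest.approx(4.0 / 5.0)
        assert c_dvb == pytest.approx(1.6)
        assert 1.0 * c_dvb + 3.0 * c_evb == pytest.approx((1.0 + 3.0) * 1.0)

    def test_zero_dvb_flow_limit(self):
        c_dvb, c_evb = junction_partition(2.0, 0.0, 1.5, 3.0)
        assert c_evb == pytest.approx(2.0)
        assert c_dvb == pytest.approx(6.0)  # carries zero flux

    def test_zero_flow_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            assert junction_partition(2.0, 0.0, 0.0, 2.0) == (2.0, 2.0)

    @given(c=st.floats(0.0, 10.0), jd=st.floats(1e-6, 5.0),
           je=st.floats(1e-6, 5.0), rho=st.floats(1.0, 5.0))
    @settings(max_examples=100, derandomize=True)
    def test_mass_conservation_and_enrichment(self, c, jd, je, rho):
        c_dvb, c_evb = junction_partition(c, jd, je, rho)
        assert jd * c_dvb + je * c_evb == pytest.approx((jd + je) * c, rel=1e-9)
        assert c_dvb == pytest.approx(rho * c_evb, rel=1e-9)

    def test_printed_form_breaks_mass_balance(self):
        """The non-conserving variant (rho on the EVB flow) is retained for
        comparison and demonstrably creates Si at the junction."""
        c_dvb, c_evb = junction_partition(1.0, 1.0, 3.0, 2.0, conserve_mass=False)
        assert 1.0 * c_dvb + 3.0 * c_evb != pytest.approx(4.0, rel=1e-6)


class TestUnload:
    def test_flux_product(self):
        assert unload_flux(2.0, 0.5, 0.1) == pytest.approx(0.1)

    def test_zero_concentration(self):
        assert unload_flux(0.0, 0.5, 0.1) == 0.0

    def test_euler_cell_increment(self):
        g = make_chain_plant(3, v_con=1.0)
        params = SiParams(k_m_unload=0.1)
        stepper = SiliconStepper(g, params)
        s = _state(g)
        s.c_m[:] = 2.0
        w = _still_water(g)
        out, diag = stepper.step(s, w, dt=0.25)
        # J = 0.1 * 2.0 * 1.0 per node; V_cyt = 1 -> dC_cyt = J*dt
        assert np.allclose(out.c_m_cyt, 0.1 * 2.0 * 1.0 * 0.25)
        assert np.allclose(diag.j_unload, 0.2)


class TestStepSilicon:
    def test_frozen_without_flow_or_unloading(self):
        g = make_chain_plant(4)
        g.root = RootParams(0.5, 1.0, 0.05, 1.0, 0.05, 0.0)
        params = SiParams(k_m_unload=0.0)
        stepper = SiliconStepper(g, params)
        s = _state(g)
        s.c_m[:] = [1.0, 0.5, 0.2, 0.0]
        w = _still_water(g)
        out, _ = stepper.step(s, w, dt=0.1)
        # only root compartments move (amount/volume round trip costs 1 ulp)
        assert np.allclose(out.c_m[1:], s.c_m[1:], rtol=1e-15, atol=1e-15)
        assert out.c_m_cor > s.c_m_cor

    def test_pulse_advection_matches_upwind_reference(self):
        """A Si pulse on an unbranched path advects exactly like an
        independently coded 1-D first-order upwind scheme."""
        n, flow, dt = 6, 0.5, 0.02
        g = make_chain_plant(n, v_con=0.2)
        g.root = RootParams(0.0, 0.0, 0.0, 1.0, 0.05, 0.0)  # no uptake
        params = SiParams(k_m_unload=0.0, root_si_volume="con")
        stepper = SiliconStepper(g, params)
        s = _state(g, c_m_out=0.0)
        c0 = np.array([5.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        s.c_m = c0.copy()
        w = _still_water(g)
        w.j_w_x[:] = flow

        ref = c0.copy()
        for _ in range(200):
            out_flux = flow * ref                      # upwind: upstream value
            out_flux[-1] = 0.0                         # last node has no out-edge
            dref = -out_flux
            dref[1:] += out_flux[:-1]
            ref = ref + dt * dref / 0.2
            s, _ = stepper.step(s, w, dt)
        assert np.allclose(s.c_m, ref, rtol=1e-12, atol=1e-12)

    def test_whole_run_ledger_and_positivity(self, constant_run):
        traj = constant_run
        assert np.all(traj.c_m >= 0)
        assert np.all(traj.c_m_cyt >= 0)
        assert traj.c_m_cor.min() >= 0
        stored = traj.total_si[-1] - traj.total_si[0]
        assert stored == pytest.approx(traj.cumulative_uptake[-1], rel=1e-3)

    def test_uptake_monotone_in_alpha(self):
        """Cumulative uptake over a fixed steady flow never decreases with
        the expression factor."""
        g = make_chain_plant(4, v_con=0.2)
        params = SiParams(k_m_unload=0.1)
        w = _still_water(g)
        w.j_w_x[:] = 0.3
        uptakes = []
        for alpha in np.linspace(0.0, 1.0, 6):
            stepper = SiliconStepper(g, params)
            s = _state(g, alpha=alpha)
            total = 0.0
            for _ in range(480):  # one day at dt = 0.05
                s, diag = stepper.step(s, w, 0.05)
                total += diag.j_m_oc * 0.05
            uptakes.append(total)
        assert np.all(np.diff(uptakes) >= -1e-12)

    def test_rho_one_everywhere_equals_partition_free(self):
        """With no DVB enrichment the junction split is a no-op: whole-plant
        trajectories match a run whose junction table is empty."""
        from siplant import ControlConfig, build_standard_plant, default_config
        from siplant.simulate import generate_standard_forcing, run_simulation
        cfg = default_config()
        cfg.junctions.rho = 1.0
        forcing = generate_standard_forcing(1, 0.05)
        ctrl = ControlConfig.for_mode("constant", 0.0, 0.0)
        g1 = build_standard_plant(cfg)
        t1 = run_simulation(g1, forcing, ctrl, cfg, days=1)
        g2 = build_standard_plant(cfg)
        g2.junctions = []
        t2 = run_simulation(g2, forcing, ctrl, cfg, days=1)
        assert np.array_equal(t1.c_m, t2.c_m)
        assert np.array_equal(t1.c_m_cyt, t2.c_m_cyt)
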
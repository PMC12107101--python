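"""Reaction-diffusion fiber model: binding kinetics, diffusion, chase decays."""
import dataclasses

import numpy as np
import pytest

from mantchase import fiber as fb
from tests.conftest import bessel_cylinder_fraction


@pytest.fixture
def geom():
    return fb.FiberGeometry()


@pytest.fixture
def params():
    return fb.RdParams()


class TestGeometry:
    def test_default_fiber_is_72_um_diameter(self, geom):
        assert geom.fiber_radius == 36.0
        assert 2 * geom.fiber_radius == 72.0
        assert geom.n_cells == 12

    def test_volumes_proportional_to_annulus_area(self, geom):
        e = geom.edges
        np.testing.assert_allclose(geom.volumes, np.pi * (e[1:] ** 2 - e[:-1] ** 2))

    def test_bath_bc_requires_bath_shells(self):
        with pytest.raises(fb.ConfigurationError):
            fb.FiberGeometry(n_bath_shells=0, outer_bc="bath")


class TestBindingRhs:
    def test_pure_off_kinetics_when_no_free_nucleotide(self, params, geom):
        state = fb.init_equilibrium(params, geom)
        state.mant_free[:] = 0.0
        d = fb.binding_rhs(state, params)
        np.testing.assert_allclose(d.nsp_mant, -params.k_off_nsp * state.nsp_mant)
        np.testing.assert_allclose(d.drx_mant, -state.drx_mant / params.t_drx)
        np.testing.assert_allclose(d.srx_mant, -state.srx_mant / params.t_srx)

    def test_nonspecific_isotherm_is_steady_state(self, params, geom):
        # occupancy K_A C / (1 + K_A C) at C = 250 uM -> 0.93333 of S_tot
        state = fb.init_equilibrium(params, geom)
        occ = state.nsp_mant[0] / params.s_tot_nsp
        k_a_c = params.k_a_nsp * 250e-6
        assert occ == pytest.approx(k_a_c / (1 + k_a_c))
        assert occ == pytest.approx(0.93333, abs=1e-5)
        d = fb.binding_rhs(state, params)
        np.testing.assert_allclose(d.nsp_mant, 0.0, atol=1e-10)

    def test_mant_is_conserved_shellwise(self, params, geom):
        state = fb.init_equilibrium(params, geom)
        state.mant_free[:geom.n_shells] = np.linspace(250, 10, geom.n_shells)
        state.atp_free[:geom.n_shells] = 100.0
        state.drx_atp[:] = 5.0
        d = fb.binding_rhs(state, params)
        nf = geom.n_shells
        total_mant = d.mant_free[:nf] + d.nsp_mant + d.drx_mant + d.srx_mant
        total_atp = d.atp_free[:nf] + d.drx_atp + d.srx_atp
        np.testing.assert_allclose(total_mant, 0.0, atol=1e-9)
        np.testing.assert_allclose(total_atp, 0.0, atol=1e-9)

    def test_equal_turnover_pools_merge(self, geom):
        # with T_drx == T_srx the split myosin pools behave as a single pool
        split = fb.RdParams(t_drx=50.0, t_srx=50.0, f_srx=0.3)
        merged = fb.RdParams(t_drx=50.0, t_srx=50.0, f_srx=0.0)
        s1 = fb.init_equilibrium(split, geom)
        s2 = fb.init_equilibrium(merged, geom)
        d1 = fb.binding_rhs(s1, split)
        d2 = fb.binding_rhs(s2, merged)
        np.testing.assert_allclose(
            d1.drx_mant + d1.srx_mant, d2.drx_mant + d2.srx_mant, atol=1e-12
        )
        np.testing.assert_allclose(d1.mant_free, d2.mant_free, atol=1e-12)

    def test_negative_concentration_rejected(self, params, geom):
        state = fb.init_equilibrium(params, geom)
        state.mant_free[0] = -1.0
        with pytest.raises(ValueError):
            fb.binding_rhs(state, params)


class TestDiffusion:
    def test_uniform_concentration_is_stationary_when_sealed(self, params):
        g = fb.FiberGeometry(n_bath_shells=0, outer_bc="sealed")
        state = fb.init_equilibrium(params, g)
        new = fb.diffusion_step(state, g, params, dt=0.001)
        np.testing.assert_allclose(new.mant_free, state.mant_free)

    def test_sealed_step_conserves_mass(self, params):
        g = fb.FiberGeometry(n_bath_shells=0, outer_bc="sealed")
        state = fb.init_equilibrium(params, g)
        state.mant_free[:] = np.linspace(250.0, 5.0, g.n_cells)
        total0 = state.total_mant_moles(g)
        for _ in range(200):
            state = fb.diffusion_step(state, g, params, dt=0.005)
        assert abs(state.total_mant_moles(g) - total0) / total0 < 1e-10

    def test_unstable_dt_raises(self, params):
        g = fb.FiberGeometry(n_bath_shells=0, outer_bc="sealed")
        state = fb.init_equilibrium(params, g)
        with pytest.raises(ValueError, match="unstable"):
            fb.diffusion_step(state, g, params, dt=10.0)

    def test_absorbing_cylinder_matches_bessel_series(self):
        # refined grid; pure diffusion of the free pool only
        g = fb.FiberGeometry(n_shells=60, dr=0.6, n_bath_shells=0, outer_bc="absorbing")
        p = fb.RdParams(myosin_total=0.0, s_tot_nsp=0.0)
        tr = fb.simulate_chase(p, g, sample_dt=0.25, duration=12.0)
        oracle = bessel_cylinder_fraction(tr.times, p.d_fiber, g.fiber_radius)
        oracle[0] = 1.0
        mask = oracle > 0.01
        assert np.max(np.abs(tr.values[mask] - oracle[mask])) < 0.01


class TestInitEquilibrium:
    def test_empty_pools_leave_only_free_mant(self, geom):
        p = fb.RdParams(myosin_total=0.0, s_tot_nsp=0.0)
        state = fb.init_equilibrium(p, geom)
        np.testing.assert_allclose(state.mant_free, 250.0)
        assert state.nsp_mant.sum() == 0 and state.drx_mant.sum() == 0

    def test_myosin_pool_partitioned_by_f_srx(self, geom):
        p = fb.RdParams(f_srx=0.25)
        state = fb.init_equilibrium(p, geom)
        # heads are nucleotide-saturated at 250 uM, so bound ~ pool size
        assert state.srx_mant[0] / (state.srx_mant[0] + state.drx_mant[0]) == pytest.approx(
            0.25, abs=2e-4
        )
        total = state.drx_mant[0] + state.srx_mant[0]
        assert total == pytest.approx(105.0, rel=2e-3)


class TestFluorescence:
    def test_empty_fiber_gives_zero(self, params, geom):
        state = fb.init_equilibrium(fb.RdParams(myosin_total=0, s_tot_nsp=0), geom)
        state.mant_free[:] = 0.0
        assert fb.fluorescence(state, params, geom) == 0.0

    def test_amount_mode_equals_total_mant_content(self, params, geom):
        state = fb.init_equilibrium(params, geom)
        state.mant_free[geom.n_shells:] = 0.0  # bath does not fluoresce anyway
        sig = fb.fluorescence(state, params, geom)
        v = geom.volumes[: geom.n_shells]
        expect = np.sum(
            (state.mant_free[: geom.n_shells] + state.nsp_mant + state.drx_mant + state.srx_mant) * v
        )
        assert sig == pytest.approx(expect)

    def test_weighted_mode_scales_myosin_bound_tenfold(self, geom):
        p_amt = fb.RdParams(s_tot_nsp=0.0, fluorescence_mode="amount")
        p_wt = dataclasses.replace(p_amt, fluorescence_mode="weighted")
        state = fb.init_equilibrium(p_amt, geom)
        state.mant_free[:] = 0.0  # only myosin-bound mant remains
        assert fb.fluorescence(state, p_wt, geom) == pytest.approx(
            10.0 * fb.fluorescence(state, p_amt, geom)
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(fb.ConfigurationError):
            fb.RdParams(fluorescence_mode="bogus")


class TestChase:
    def test_mass_conserved_with_reactions_when_sealed(self, params):
        g = fb.FiberGeometry(n_bath_shells=0, outer_bc="sealed")
        state0 = fb.init_equilibrium(params, g)
        times = np.linspace(0.0, 100.0, 26)
        ys = fb._integrate(params, g, state0, times)
        m0 = state0.total_mant_moles(g)
        for i in (5, 25):
            st = fb.FiberState.from_vector(ys[:, i], g.n_cells, g.n_shells)
            assert abs(st.total_mant_moles(g) - m0) / m0 < 1e-8

    def test_chase_decay_is_monotone_and_normalized(self, params, geom):
        tr = fb.simulate_chase(params, geom, duration=400.0)
        assert tr.values[0] == 1.0
        assert np.all(np.diff(tr.values) < 1e-6)

    def test_late_time_slope_approaches_srx_turnover(self):
        # all-SRX fiber, fast diffusion, no nonspecific sites
        p = fb.RdParams(f_srx=1.0, s_tot_nsp=0.0, d_sol=6000.0)
        tr = fb.simulate_chase(p)
        lv = np.log(tr.values)
        slope = (lv[-1] - lv[300]) / (tr.times[-1] - tr.times[300])
        assert slope == pytest.approx(-1.0 / p.t_srx, rel=0.02)

    def test_components_sum_to_trace(self, params, geom):
        tr, comps = fb.simulate_chase(params, geom, duration=100.0, return_components=True)
        total = comps["free"] + comps["nsp"] + comps["drx"] + comps["srx"]
        np.testing.assert_allclose(total, tr.values, atol=1e-12)

    def test_explicit_and_stiff_integrators_agree_for_pure_diffusion(self):
        g = fb.FiberGeometry(n_shells=9, n_bath_shells=0, outer_bc="absorbing")
        p = fb.RdParams(myosin_total=0.0, s_tot_nsp=0.0)
        state = fb.init_equilibrium(p, g)
        dt = 0.002
        sampled = [1.0]
        cur = state
        for i in range(1, 1001):
            cur = fb.diffusion_step(cur, g, p, dt)
            if i % 250 == 0:
                sampled.append(cur.total_mant_moles(g) / state.total_mant_moles(g))
        tr = fb.simulate_chase(p, g, sample_dt=0.5, duration=2.0)
        np.testing.assert_allclose(sampled, tr.values, atol=5e-4)


class TestGhost:
    def test_buffer_retards_the_decay(self, geom):
        without = fb.simulate_ghost(fb.RdParams(s_tot_nsp=0.0), geom, duration=200.0)
        with_buf = fb.simulate_ghost(fb.RdParams(), geom, duration=200.0)
        diff = with_buf.values - without.values
        assert np.all(diff[1:] >= -1e-9)
        mid = slice(5, 40)  # strict retardation while signal remains
        assert np.all(diff[mid] > 1e-4)

    def test_decay_monotone_in_site_concentration(self, geom):
        t50 = {}
        for s_tot in (0.0, 100.0, 300.0):
            tr = fb.simulate_ghost(fb.RdParams(s_tot_nsp=s_tot), geom, duration=200.0)
            t50[s_tot] = tr.values[25]  # remaining fraction at t = 50 s
        assert t50[0.0] < t50[100.0] < t50[300.0]

    def test_ghost_has_no_myosin_signal(self, geom):
        tr, comps = fb.simulate_chase(
            fb.RdParams(myosin_total=0.0), geom, duration=50.0, return_components=True
        )
        assert np.all(comps["drx"] == 0.0) and np.all(comps["srx"] == 0.0)


class TestImposedFractions:
    @pytest.mark.parametrize("mode", ["amount", "weighted"])
    def test_fractions_hold_exactly_at_t0(self, geom, mode):
        base = fb.RdParams(fluorescence_mode=mode)
        p = fb.impose_signal_fractions(base, nsp_frac=0.6, srx_rel=0.35, geom=geom)
        state = fb._chase_initial_state(p, geom)
        comps = fb.fluorescence_components(state, p, geom)
        total = sum(comps.values())
        assert (comps["free"] + comps["nsp"]) / total == pytest.approx(0.6, abs=1e-9)
        assert comps["srx"] / (comps["srx"] + comps["drx"]) == pytest.approx(0.35, abs=1e-9)

    def test_weighted_mode_rejects_nsp_below_free_floor(self, geom):
        base = fb.RdParams(fluorescence_mode="weighted")
        with pytest.raises(fb.ConfigurationError, match="feasible"):
            fb.impose_signal_fractions(base, nsp_frac=0.1, srx_rel=0.5, geom=geom)

    def test_requires_myosin(self, geom):
        with pytest.raises(fb.ConfigurationError):
            fb.impose_signal_fractions(
                fb.RdParams(myosin_total=0.0), nsp_frac=0.6, srx_rel=0.5, geom=geom
            )
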
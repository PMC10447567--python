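"""Spatial operators and time integration on the moving-thickness domain.

Oracles: analytic integrals for the growth velocity, the closed-form
cosh reaction–diffusion profile for first-order solute consumption, the
chemostat washout condition for the decoupled tank, and discrete
conservation identities of the upwind advection scheme.
"""

import numpy as np
import pytest

import biofilmhp as bh
from biofilmhp import kinetics
from biofilmhp.grid import BiofilmGrid
from biofilmhp.solver import (
    assemble_rhs,
    growth_velocity,
    initial_state_vector,
    particulate_advection,
    solute_diffusion,
    _velocity_from_rates,
)

P = bh.ModelParameters()


def uniform_live_state(p, Lf, S_G, Nz=None):
    """Uniform all-live film at volume fraction 0.08 with uniform glucose."""
    Nz = Nz or p.Nz
    X_b = np.zeros((2, Nz))
    X_b[0] = 0.08 * p.rho_L
    S_b = np.zeros((2, Nz))
    S_b[0] = S_G
    return X_b, S_b


class TestGrid:
    def test_geometry(self):
        g = BiofilmGrid(50)
        assert g.zeta_faces[0] == 0.0 and g.zeta_faces[-1] == 1.0
        assert np.all(np.diff(g.zeta_faces) > 0)
        assert np.allclose(g.zeta_centers, (np.arange(50) + 0.5) / 50)
        assert g.dz(150e-6) == pytest.approx(3e-6)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            BiofilmGrid(1)


class TestGrowthVelocity:
    def test_zero_rates_zero_velocity(self):
        g = BiofilmGrid(P.Nz)
        X_b, S_b = uniform_live_state(P, 100e-6, 0.0)  # no substrate, no growth
        v = growth_velocity(X_b, S_b, 100e-6, P, g)
        assert np.allclose(v, 0.0)
        assert len(v) == P.Nz + 1

    def test_uniform_growth_analytic_integral(self):
        """With uniform all-live biomass and uniform glucose, v(Lf) = mu(S)*Lf."""
        g = BiofilmGrid(P.Nz)
        Lf, S_G = 120e-6, 42.0
        X_b, S_b = uniform_live_state(P, Lf, S_G)
        v = growth_velocity(X_b, S_b, Lf, P, g)
        mu = kinetics.growth_rate(S_G, P)
        assert v[-1] == pytest.approx(mu * Lf, rel=1e-12)
        # linear profile in z
        assert np.allclose(v, mu * g.zeta_faces * Lf, rtol=1e-12)

    def test_degenerate_empty_film_rejected(self):
        g = BiofilmGrid(4)
        X_b = np.zeros((2, 4))
        with pytest.raises(FloatingPointError):
            _velocity_from_rates(np.zeros((2, 4)), X_b, 1e-4, P, g)


class TestParticulateAdvection:
    def test_no_motion_no_transport(self):
        g = BiofilmGrid(20)
        X_b = np.random.default_rng(0).uniform(1e3, 2e4, (2, 20))
        term = particulate_advection(X_b, np.zeros(21), 0.0, 1e-4, g)
        assert np.allclose(term, 0.0)

    def test_uniform_field_linear_velocity(self):
        """For uniform X and v = c*z the interior term is exactly -c*X."""
        g = BiofilmGrid(50)
        Lf, c = 1e-4, 3.0
        X_b = np.full((2, 50), 1.7e4)
        v = c * g.zeta_faces * Lf
        term = particulate_advection(X_b, v, 0.0, Lf, g)
        assert np.allclose(term[:, :-1], -c * X_b[:, :-1], rtol=1e-10)

    def test_discrete_conservation_identity(self):
        """Cell sums balance the detachment outflux and domain dilation."""
        rng = np.random.default_rng(1)
        g = BiofilmGrid(30)
        Lf = 1.3e-4
        X_b = rng.uniform(1e3, 2e4, (2, 30))
        v = np.concatenate([[0.0], np.cumsum(rng.uniform(0, 1e-5, 30))])
        dLf = 0.4 * v[-1]
        term = particulate_advection(X_b, v, dLf, Lf, g)
        dz = Lf / g.Nz
        w_top = v[-1] - dLf
        lhs = term.sum(axis=1) * dz
        rhs = -w_top * X_b[:, -1] - (dLf / Lf) * X_b.sum(axis=1) * dz
        assert np.allclose(lhs, rhs, rtol=1e-12)


class TestSoluteDiffusion:
    def test_equilibrated_film_no_flux(self):
        g = BiofilmGrid(50)
        S_t = np.array([80.0, 10.0])
        S_b = np.tile(S_t[:, None], (1, 50))
        term, J_dif, S_s = solute_diffusion(S_b, S_t, 1e-4, P, g)
        assert np.allclose(term, 0.0)
        assert np.allclose(J_dif, 0.0)
        assert np.allclose(S_s, S_t)

    @pytest.mark.parametrize("Nz, tol", [(50, 0.01), (400, 5e-4)])
    def test_cosh_profile_oracle(self, Nz, tol):
        """Steady first-order consumption matches the closed-form
        C*cosh(z/lambda) profile (see tests/oracles.py)."""
        from oracles import cosh_oracle_max_rel_error

        assert cosh_oracle_max_rel_error(Nz) < tol


class TestAssembleRhs:
    def test_equilibrium_fixed_point(self):
        """No reactions, solutes equilibrated, no flow imbalance: dy = 0."""
        p = P.replace(mu_max=0.0, k_dis=0.0, k_B_L=0.0, k_B_D=0.0,
                      K_det=0.0, S_in_G=80.0)
        g = BiofilmGrid(p.Nz)
        X_b, _ = uniform_live_state(p, p.Lf0, 0.0)
        S_t = np.array([80.0, 0.0])
        S_b = np.tile(S_t[:, None], (1, p.Nz))
        from biofilmhp.solver import _pack
        y = _pack(np.zeros(2), S_t, X_b, S_b, p.Lf0)
        dy = assemble_rhs(5.0, y, p, bh.DoseSchedule(), g)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_detachment_flux_arithmetic(self):
        """J_det = K_det*Lf^2 * X_top = 4.5 g/m^2/day for the reference state."""
        v_det = kinetics.detachment_velocity(150e-6, P)
        assert v_det * 2e4 == pytest.approx(4.5)

    def test_chemostat_washout_without_biofilm_coupling(self):
        """With A = 0 the tank is a pure chemostat; Q/V = 10/d exceeds
        mu_max = 9.6/d so suspended biomass washes out."""
        p = P.replace(A=0.0)
        res = bh.integrate(p, bh.DoseSchedule(), t_final=30.0)
        assert res.X_t[-1, 0] < 1e-3  # from 1 g/m^3 initially
        # and the decline is monotone after the initial instants
        live = res.X_t[:, 0]
        assert np.all(np.diff(live[live > 1e-12]) < 1e-9)


class TestIntegration:
    def test_result_invariants(self, case_a, params):
        assert np.all(np.diff(case_a.t) > 0)
        assert case_a.t[0] == 0.0
        y0 = initial_state_vector(params)
        assert case_a.Lf[0] == pytest.approx(params.Lf0)
        assert np.allclose(case_a.X_b[0].ravel(), y0[4:4 + 2 * params.Nz])

    def test_untreated_film_plateaus_fast(self, case_a):
        """Thickness rises from 50 um and plateaus within ~2 days."""
        Lf_2d = case_a.Lf[np.argmin(np.abs(case_a.t - 2.0))]
        assert Lf_2d > 0.9 * case_a.Lf[-1]
        assert case_a.Lf[-1] > case_a.Lf[0]

    def test_volume_fraction_conserved(self, case_b, params):
        """P_tot stays at its initial 0.08 in every cell at all times."""
        rho = np.array([params.rho_L, params.rho_D])
        P_tot = (case_b.X_b / rho[None, :, None]).sum(axis=1)
        assert np.max(np.abs(P_tot - 0.08)) / 0.08 <= 1e-3

    def test_steady_state_growth_detachment_balance(self, case_a, params):
        """At steady state v(Lf) = K_det*Lf^2 (thickness fixed point)."""
        s = case_a.final_state
        g = case_a.grid
        v = growth_velocity(s.X_b, s.S_b, s.Lf, params, g)
        v_det = kinetics.detachment_velocity(s.Lf, params)
        assert abs(v[-1] - v_det) / v_det <= 1e-3

    def test_steady_state_glucose_flux_balance(self, case_a, params):
        """Tank glucose balance: Q*S_in = Q*S_t + A*J_dif within 0.5%."""
        s = case_a.final_state
        _, J_dif, _ = solute_diffusion(s.S_b, s.S_t, s.Lf, params, case_a.grid)
        # J_dif < 0 when glucose enters the biofilm; tank consumption by
        # suspended biomass adds V*R_S
        r_g, _ = kinetics.solute_rates(s.X_t[0], s.X_t[1], s.S_t[0], s.S_t[1], params)
        supplied = params.Q * params.S_in_G
        accounted = params.Q * s.S_t[0] - params.A * J_dif[0] - params.V * r_g
        assert abs(supplied - accounted) / supplied <= 0.005

    def test_hp_profile_monotone_under_dosing(self, case_b):
        """Consumption-only kinetics: steady HP decreases from surface to base."""
        S_H = case_b.final_state.S_b[bh.HP]
        assert np.all(np.diff(S_H) >= -1e-12)  # base..surface ordering

    def test_disinfection_knockout_decouples_hp(self, case_a, params):
        """With k_dis = 0, dosing has no feedback on growth: the live
        trajectory matches the undosed case."""
        p = params.replace(k_dis=0.0)
        res = bh.integrate(p, bh.continuous_schedule(500.0),
                           sample_times=np.linspace(0, 100, 401))
        ref = bh.integrate(params, bh.DoseSchedule(),
                           sample_times=np.linspace(0, 100, 401))
        assert np.allclose(res.Lf, ref.Lf, rtol=1e-4)
        assert np.allclose(res.X_b[:, 0, :], ref.X_b[:, 0, :], rtol=1e-3, atol=1e-6)

    def test_dosing_recovery_within_a_day(self, params):
        """Case C: after dosing ends at day 6 the film re-attains its
        pre-treatment thickness within about a day."""
        res = bh.integrate(params, bh.DoseSchedule(time1=2, time2=6,
                                                   dose1=500.0, dose2=0.0),
                           t_final=12.0, n_samples=601)
        Lf_pre = res.Lf[np.argmin(np.abs(res.t - 2.0))]
        Lf_recovered = res.Lf[np.argmin(np.abs(res.t - 7.5))]
        assert Lf_recovered == pytest.approx(Lf_pre, rel=0.02)
        # and the film was thicker during treatment
        assert res.Lf[np.argmin(np.abs(res.t - 6.0))] > 1.1 * Lf_pre

    def test_eradication_is_terminal_not_error(self, params):
        """Without dead-cell neutralization a modest dose collapses the
        film; the run ends normally with the eradicated flag."""
        p = params.replace(k_B_D=0.0)
        res = bh.integrate_to_steady_state(p, bh.continuous_schedule(200.0))
        assert res.eradicated
        assert res.diagnostics["success"]

    def test_grid_refinement_thickness_stable(self, case_a, case_a_fine_grid):
        """Final untreated thickness moves < 1% from Nz = 50 to Nz = 200."""
        assert case_a_fine_grid.Lf[-1] == pytest.approx(case_a.Lf[-1], rel=0.01)
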
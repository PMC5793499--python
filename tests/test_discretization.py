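"""Transport operator, interface conditions and RHS assembly."""

import math

import numpy as np
import pytest

from mgcorrode import (DegenerateZoneError, Phase, PhaseState, ZoneMesh,
                       assemble_phase_rhs, initialize_case, interface_rates,
                       outer_radius, transform_rhs, SolverConfig)
from mgcorrode.discretization import MIN_ZONE_WIDTH

from test_conservation import make_params


def mesh_from(inner, outer, values):
    return ZoneMesh(n=len(values) - 2, inner=inner, outer=outer,
                    values=np.asarray(values, dtype=float))


class TestTransformRhs:
    def test_uniform_field_is_steady(self):
        mesh = mesh_from(0.3, 1.1, np.full(52, 0.7))
        dX = transform_rhs(mesh, 0.0, 0.0, 1.5, lambda r: np.zeros_like(r), 2)
        assert np.allclose(dX, 0.0, atol=1e-12)

    def test_uniform_field_steady_even_on_moving_mesh(self):
        # mesh motion only generates apparent advection of gradients
        mesh = mesh_from(0.3, 1.1, np.full(52, 0.7))
        dX = transform_rhs(mesh, -0.2, 0.05, 1.5, lambda r: np.full_like(r, 0.3), 1)
        assert np.allclose(dX, 0.0, atol=1e-12)

    def test_central_differences_exact_on_quadratics(self):
        a, b, c = 0.8, -0.4, 0.2
        D, V = 1.3, 0.7
        mesh = ZoneMesh(n=30, inner=0.2, outer=1.4, values=np.zeros(32))
        r = mesh.r()
        mesh.values = a * r**2 + b * r + c
        dX = transform_rhs(mesh, 0.0, 0.0, D,
                           lambda rr: np.full_like(rr, V), 0)
        exact = -V * (2 * a * r[1:-1] + b) + D * 2 * a
        assert np.allclose(dX, exact, rtol=1e-10, atol=1e-10)

    def test_radial_operator_second_order_convergence(self):
        """Manufactured profile cos(r): halving h reduces max error ~4x."""
        D, d = 1.3, 2

        def err(n):
            mesh = ZoneMesh(n=n, inner=0.3, outer=1.2, values=np.zeros(n + 2))
            r = mesh.r()
            mesh.values = np.cos(r)
            dX = transform_rhs(mesh, 0.0, 0.0, D,
                               lambda rr: np.zeros_like(rr), d)
            ri = r[1:-1]
            exact = D * (-np.cos(ri) - d / ri * np.sin(ri))
            return np.max(np.abs(dX - exact))

        ratio = err(100) / err(200)
        assert 3.2 < ratio < 4.8

    def test_interior_flux_balance_telescopes(self):
        """Static slab, no advection: total content change equals the
        difference of the one-sided boundary fluxes (discrete conservation)."""
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.2, 1.0, 42)
        D = 0.9
        mesh = mesh_from(0.0, 1.3, vals)
        L, h = mesh.width, mesh.h
        dX = transform_rhs(mesh, 0.0, 0.0, D, lambda r: np.zeros_like(r), 0)
        total_rate = np.sum(dX) * h * L
        flux_out = D * (vals[-1] - vals[-2]) / (h * L)
        flux_in = D * (vals[1] - vals[0]) / (h * L)
        assert total_rate == pytest.approx(flux_out - flux_in, rel=1e-10)

    def test_degenerate_zone_rejected(self):
        mesh = mesh_from(0.5, 0.5 + 0.1 * MIN_ZONE_WIDTH, np.ones(25))
        with pytest.raises(DegenerateZoneError):
            transform_rhs(mesh, 0.0, 0.0, 1.0, lambda r: np.zeros_like(r), 1)


def joint_state(p, beta=0.999, n2=60, W2=None, C2=None):
    S = outer_radius(beta, beta, p)
    return PhaseState(phase=Phase.P2_1, t=0.01, alpha=beta, beta=beta, S=S,
                      W1=None,
                      W2=np.full(n2, 1.0) if W2 is None else W2,
                      C2=np.full(n2, 1.0) if C2 is None else C2)


def two_zone_state(p, alpha=0.5, beta=0.8, n1=60, n2=60, phase=Phase.P2_2,
                   W1=None, W2_val=0.95):
    S = outer_radius(alpha, beta, p)
    r2 = np.linspace(beta, S, n2 + 2)[1:-1]
    C2 = (r2 - beta) / (S - beta)
    return PhaseState(phase=phase, t=1.0, alpha=alpha, beta=beta, S=S,
                      W1=np.full(n1, 0.9) if W1 is None else W1,
                      W2=np.full(n2, W2_val), C2=C2)


class TestInterfaceRates:
    def test_joint_interface_rate_from_mass_action(self):
        """Thin carbonate shell, ambient water: gamma0*bdot = -kappa*W^2."""
        p = make_params(kappa=0.04)
        rates = interface_rates(joint_state(p), p)
        assert rates.beta_dot == pytest.approx(-0.031, abs=5e-4)
        assert rates.alpha_dot == rates.beta_dot

    def test_joint_interface_robin_conditions_satisfied(self):
        """Returned boundary values reproduce the Robin fluxes on the stencil."""
        p = make_params(kappa=0.3)
        st = joint_state(p, beta=0.9)
        rates = interface_rates(st, p)
        bv = rates.boundary_values
        n2, h2, L2 = st.n2, 1.0 / (st.n2 + 1), st.S - st.beta
        dW = (-3 * bv["W2_beta"] + 4 * st.W2[0] - st.W2[1]) / (2 * h2 * L2)
        dC = (-3 * bv["C2_beta"] + 4 * st.C2[0] - st.C2[1]) / (2 * h2 * L2)
        bd = rates.beta_dot
        assert -p.DW * (1 - p.eps2) * dW == pytest.approx(
            p.gamma1 * p.omega_alpha * bd, rel=1e-9)
        assert -(1 - p.eps2) * dC == pytest.approx(
            p.gamma2 * p.omega_alpha * bd, rel=1e-9)
        assert p.gamma0 * bd == pytest.approx(-p.kappa * bv["W2_beta"] ** 2,
                                              rel=1e-9)

    def test_zero_water_gradient_means_static_mg_interface(self):
        p = make_params(kappa=math.inf)
        st = two_zone_state(p, phase=Phase.P1_1, W1=np.zeros(60))
        rates = interface_rates(st, p)
        assert rates.alpha_dot == pytest.approx(0.0, abs=1e-14)

    def test_large_kappa_recovers_instantaneous_limit(self):
        """Finite-rate alpha condition tends to the Stefan condition."""
        p_inf = make_params(kappa=math.inf)
        st = two_zone_state(p_inf, phase=Phase.P1_1,
                            W1=np.linspace(0.01, 0.9, 60))
        ad_inf = interface_rates(st, p_inf).alpha_dot
        p_big = make_params(kappa=1e12)
        st_big = two_zone_state(p_big, phase=Phase.P2_2,
                                W1=np.linspace(0.01, 0.9, 60))
        ad_big = interface_rates(st_big, p_big).alpha_dot
        assert ad_big == pytest.approx(ad_inf, rel=1e-3)
        assert interface_rates(st_big, p_big).boundary_values["W1_alpha"] \
            == pytest.approx(0.0, abs=1e-3)

    def test_conversion_rate_is_advection_mode_independent(self):
        """CO2 vanishes at beta, so beta_dot - vs1(beta) is set by the CO2
        gradient alone in every advection mode."""
        p = make_params(kappa=0.3)
        st = two_zone_state(p)
        results = {mode: interface_rates(st, p, mode)
                   for mode in ("fluid", "none", "solid")}
        wa, d = p.omega_alpha, p.d
        R = {mode: r.beta_dot + (wa - 1) * (st.alpha / st.beta) ** d * r.alpha_dot
             for mode, r in results.items()}
        assert R["none"] == pytest.approx(R["fluid"], rel=1e-9)
        assert R["solid"] == pytest.approx(R["fluid"], rel=1e-9)

    def test_symmetry_ghost_after_mg_exhaustion(self):
        p = make_params()
        W1 = np.linspace(0.8, 0.9, 60)
        st = two_zone_state(p, alpha=0.0, beta=0.8, phase=Phase.P2_3, W1=W1)
        rates = interface_rates(st, p)
        assert rates.alpha_dot == 0.0
        assert rates.boundary_values["W1_alpha"] == pytest.approx(
            (4 * W1[0] - W1[1]) / 3)


class TestAssemblePhaseRhs:
    @pytest.mark.parametrize("case_preset", ["fig3", "fig4"])
    def test_seeded_start_has_finite_derivatives(self, case_preset):
        from mgcorrode import preset

        p, _ = preset(case_preset)
        cfg = SolverConfig(n1=40, n2=40)
        st = initialize_case(p, cfg)
        dW1, dW2, dC2, ad, bd = assemble_phase_rhs(st, p)
        for arr in (dW2, dC2) + (() if dW1 is None else (dW1,)):
            assert np.all(np.isfinite(arr))
        assert np.isfinite(ad) and np.isfinite(bd)
        assert ad <= 0.0

    def test_equilibrated_inner_zone_is_quiescent(self):
        """W1 uniform and equal to the interface value: no zone-1 dynamics
        away from the interface."""
        p = make_params(kappa=0.042)
        st = two_zone_state(p, alpha=0.0, beta=0.8, phase=Phase.P2_3,
                            W1=np.full(60, 0.95), W2_val=0.95)
        dW1, _, _, _, _ = assemble_phase_rhs(st, p)
        assert np.max(np.abs(dW1[:-5])) < 1e-6
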
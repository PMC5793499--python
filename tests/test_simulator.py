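"""Phase sequencing, events, seeding and trajectory invariants."""

import math

import numpy as np
import pytest

import mgcorrode as mg
from mgcorrode import (Phase, PhaseState, SolverConfig, advance_phase,
                       initialize_case, integrate_phase,
                       magnesium_balance_residual, simulate)
from mgcorrode.simulator import EVENT_CO2_EXHAUSTED

from test_conservation import make_params


class TestSolverConfig:
    def test_zero_start_offset_rejected(self):
        with pytest.raises(ValueError, match="tau0"):
            SolverConfig(tau0=0.0)

    @pytest.mark.parametrize("bad", [{"n1": 5}, {"delta_seed": 0.5},
                                     {"advection_mode": "warp"},
                                     {"rtol": -1.0}])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SolverConfig(**bad)


class TestInitializeCase:
    def test_finite_rate_start_displacement(self):
        """Leading-order joint-interface motion: S0 - beta = (kappa/gamma0)*tau0."""
        p = make_params(kappa=0.04)
        cfg = SolverConfig(tau0=1e-8)
        st = initialize_case(p, cfg)
        assert st.phase is Phase.P2_1
        assert 1.0 - st.beta == pytest.approx(3.1e-10, rel=5e-3)
        assert np.all(st.W2 == 1.0) and np.all(st.C2 == 1.0)

    def test_instantaneous_seed_conserves_magnesium(self):
        p = make_params(kappa=math.inf)
        st = initialize_case(p, SolverConfig())
        assert st.phase is Phase.P1_1
        assert magnesium_balance_residual(st, p) < 1e-8
        # water rises linearly from the Mg surface to ambient at beta
        assert np.all(np.diff(st.W1) > 0)
        assert st.W1[0] < 0.1 and st.W1[-1] > 0.9

    def test_case_request_must_match_kappa(self):
        with pytest.raises(ValueError, match="Case"):
            initialize_case(make_params(kappa=0.04), SolverConfig(), case=1)
        with pytest.raises(ValueError, match="Case"):
            initialize_case(make_params(kappa=math.inf), SolverConfig(), case=2)


@pytest.fixture(scope="module")
def p21_end():
    p, _ = mg.preset("fig3")
    cfg = SolverConfig(n1=40, n2=40)
    st = initialize_case(p, cfg)
    end, label = integrate_phase(st, p, cfg)
    return p, cfg, end, label


class TestPhaseTransitions:
    def test_joint_phase_ends_with_co2_exhausted(self, p21_end):
        p, cfg, end, label = p21_end
        assert label == EVENT_CO2_EXHAUSTED
        rates = mg.interface_rates(end, p, cfg.advection_mode)
        assert abs(rates.boundary_values["C2_beta"]) < 1e-6

    def test_hydroxide_seeding(self, p21_end):
        p, cfg, end, _ = p21_end
        nxt = advance_phase(end, EVENT_CO2_EXHAUSTED, p, cfg)
        assert nxt.phase is Phase.P2_2
        assert nxt.beta - nxt.alpha == pytest.approx(cfg.delta_seed * p.S0)
        assert np.ptp(nxt.W1) == 0.0  # uniform at the pre-transition value
        assert magnesium_balance_residual(nxt, p) < 1e-12

    def test_tolerance_refinement_moves_event_little(self, p21_end):
        p, cfg, end, _ = p21_end
        import dataclasses

        tight = dataclasses.replace(cfg, rtol=cfg.rtol / 2, atol=cfg.atol / 2)
        end2, _ = integrate_phase(initialize_case(p, tight), p, tight)
        assert abs(end2.t - end.t) / end.t < 1e-3

    def test_inconsistent_event_rejected(self, p21_end):
        p, cfg, end, _ = p21_end
        with pytest.raises(ValueError, match="inconsistent"):
            advance_phase(end, "mg_exhausted", p, cfg)


class TestTrajectoryInvariants:
    def test_transition_time_ordering(self, fig3_result):
        r = fig3_result
        assert r.T_ab < r.T_alpha < r.T_beta

    def test_alpha_nonincreasing_and_S_nondecreasing(self, fig3_result):
        r = fig3_result
        assert np.all(np.diff(r.alpha) <= 1e-10)
        assert np.all(np.diff(r.S) >= -1e-10)

    def test_beta_rises_then_recedes(self, fig3_result):
        """Solid-volume expansion pushes the hydroxide-carbonate interface
        outward while the Mg core converts; after Mg exhaustion it recedes
        monotonically to zero."""
        r = fig3_result
        assert r.beta.max() > 1.05 * r.params.S0
        after = r.t > r.T_alpha
        assert np.all(np.diff(r.beta[after]) <= 1e-10)
        joint = r.phase == "2.1"
        assert np.all(np.diff(r.beta[joint]) <= 1e-12)

    def test_final_size_reached(self, fig3_result, fig4_full_n50):
        for r in (fig3_result, fig4_full_n50):
            assert r.S[-1] == pytest.approx(r.S_inf, abs=1e-4)
            assert r.beta[-1] <= 1.1e-6

    def test_magnesium_balance_along_trajectory(self, fig3_result):
        r = fig3_result
        p = r.params
        d1 = p.d + 1
        wa, wb = p.omega_alpha, p.omega_beta
        total = (wa * wb * r.alpha**d1 + wb * (r.beta**d1 - r.alpha**d1)
                 + (r.S**d1 - r.beta**d1))
        assert np.max(np.abs(total - wa * wb * p.S0**d1)) < 1e-6

    def test_water_peak_exceeds_ambient_near_interface(self, fig3_result):
        """Water produced by the carbonation reaction accumulates near beta,
        locally exceeding the exterior concentration (seen once the Mg core
        is gone and the hydroxide zone no longer drains it)."""
        snap = fig3_result.snapshots[1]
        assert snap.phase == "2.3"
        assert np.max(snap.W2) > 1.0
        assert np.argmax(snap.W2) < len(snap.W2) // 2  # peak sits near beta

    def test_snapshot_zone_extents(self, fig3_result):
        snap = fig3_result.snapshots[0]
        assert snap.r1 is not None
        assert snap.r1[0] >= 0.0
        assert snap.r1[-1] == pytest.approx(snap.r2[0])

    def test_instantaneous_case_has_no_joint_phase(self, fig4_partial):
        assert fig4_partial.T_ab is None
        assert fig4_partial.T_alpha is not None
        assert set(np.unique(fig4_partial.phase)) == {"1.1"}


class TestNumericalRobustness:
    def test_mesh_doubling_changes_times_below_one_percent(self, fig3_result,
                                                           fig3_result_n50):
        for attr in ("T_alpha", "T_beta"):
            coarse = getattr(fig3_result_n50, attr)
            fine = getattr(fig3_result, attr)
            assert abs(coarse - fine) / fine < 0.01

    def test_seeding_insensitivity(self, fig3_result_n50, fig3_result_seeds):
        """tau0 and delta_seed perturbed by two orders of magnitude."""
        for attr in ("T_alpha", "T_beta"):
            a = getattr(fig3_result_n50, attr)
            b = getattr(fig3_result_seeds, attr)
            assert abs(a - b) / a < 0.005

    def test_kappa_to_infinity_approaches_instantaneous_case(self, fig4_partial):
        p, _ = mg.preset("fig4")
        big = p.replace(kappa=1e4)
        r = simulate(big, SolverConfig(n1=50, n2=50), until="T_alpha")
        assert r.T_alpha == pytest.approx(fig4_partial.T_alpha, rel=0.02)

    def test_upwind_advection_agrees_with_central(self):
        """Interface Peclet numbers are small: upwinding barely matters."""
        p, _ = mg.preset("fig3")
        central = simulate(p, SolverConfig(n1=40, n2=40), until="T_ab")
        upwind = simulate(p, SolverConfig(n1=40, n2=40, upwind=True),
                          until="T_ab")
        assert upwind.T_ab == pytest.approx(central.T_ab, rel=0.02)

    def test_bit_reproducibility(self):
        p, _ = mg.preset("fig3")
        cfg = SolverConfig(n1=40, n2=40)
        a = simulate(p, cfg, until="T_ab")
        b = simulate(p, cfg, until="T_ab")
        assert a.T_ab == b.T_ab
        assert np.array_equal(a.beta, b.beta)


class TestCheckpoint:
    def test_phase_state_json_round_trip(self):
        p = make_params()
        st = initialize_case(p, SolverConfig(n1=30, n2=30))
        clone = PhaseState.from_json(st.to_json())
        assert clone.phase is st.phase
        assert clone.t == st.t
        assert np.array_equal(clone.W2, st.W2)
        assert clone.W1 is None

    def test_structural_validation(self):
        with pytest.raises(ValueError, match="zone 1"):
            PhaseState(phase=Phase.P2_1, t=0.0, alpha=1.0, beta=1.0, S=1.0,
                       W1=np.ones(5), W2=np.ones(5), C2=np.ones(5))
        st = PhaseState(phase=Phase.P2_1, t=0.0, alpha=0.9, beta=0.5, S=1.0,
                        W1=None, W2=np.ones(5), C2=np.ones(5))
        with pytest.raises(ValueError, match="alpha"):
            st.validate()
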
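"""Shared fixtures.

Full corrosion histories are expensive (the hydroxide layer outlives the Mg
core by two orders of magnitude in time), so the runs used by several tests
are session-scoped and sized desk-scale; mesh sizes per fixture are chosen so
that the assertions they feed are well inside the discretisation error
observed in the mesh-doubling checks.
"""

import math

import pytest
from hypothesis import settings

import mgcorrode as mg

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig3_params():
    params, _ = mg.preset("fig3")
    return params


@pytest.fixture(scope="session")
def fig3_result(fig3_params):
    """Full finite-rate base-case history (cylinder), n = 100 per zone."""
    cfg = mg.SolverConfig(n1=100, n2=100, snapshot_times=(10.0, 100.0))
    return mg.simulate(fig3_params, cfg)


@pytest.fixture(scope="session")
def fig3_result_n50(fig3_params):
    """Same run at half the resolution, for mesh-doubling comparisons."""
    return mg.simulate(fig3_params, mg.SolverConfig(n1=50, n2=50))


@pytest.fixture(scope="session")
def fig3_result_seeds(fig3_params):
    """n = 50 run with perturbed singular-start handling (tau0, delta_seed)."""
    cfg = mg.SolverConfig(n1=50, n2=50, tau0=1e-6, delta_seed=1e-4)
    return mg.simulate(fig3_params, cfg)


@pytest.fixture(scope="session")
def fig4_partial():
    """Instantaneous-reaction (Case 1) cylinder, run until Mg exhaustion."""
    params, _ = mg.preset("fig4")
    return mg.simulate(params, mg.SolverConfig(n1=100, n2=100),
                       until="T_alpha")


@pytest.fixture(scope="session")
def fig4_full_n50():
    params, _ = mg.preset("fig4")
    return mg.simulate(params, mg.SolverConfig(n1=50, n2=50))


@pytest.fixture(scope="session")
def kappa_spread_runs():
    """Full histories for kappa in {0.3, 6, inf} at fixed porosities."""
    params, _ = mg.preset("fig5")
    cfg = mg.SolverConfig(n1=50, n2=50)
    return {kappa: mg.simulate(params.replace(kappa=kappa), cfg)
            for kappa in (0.3, 6.0, math.inf)}


@pytest.fixture(scope="session")
def advection_trio():
    """fluid/none/solid advection variants of the base case, to Mg exhaustion."""
    params, _ = mg.preset("fig9")
    cfg = mg.SolverConfig(n1=50, n2=50)
    return mg.compare_advection_modes(params, cfg, until="T_alpha")


@pytest.fixture(scope="session")
def s0_sweep():
    """T_beta against initial size over a factor-8 range (kappa ~ 0.3)."""
    params, _ = mg.preset("fig5")
    cfg = mg.SolverConfig(n1=40, n2=40)
    return mg.sweep("S0", [0.5, 1.0, 2.0, 4.0], params, cfg)


@pytest.fixture(scope="session")
def eps2_sweep():
    """T_beta against the carbonate solid fraction (kappa ~ 0.3)."""
    params, _ = mg.preset("fig5")
    cfg = mg.SolverConfig(n1=40, n2=40)
    return mg.sweep("eps2", [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8], params, cfg)
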
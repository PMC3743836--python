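"""Shared fixtures.

The expensive travelling-wave simulations are session-scoped and shared by
the metric, property, and acceptance tests; every run uses the same scaled
study geometry (2.5 mm domain, supra-threshold 200-um potassium bolus at
x = 0.5 mm) so that metrics are comparable across regimes.
"""

import numpy as np
import pytest

from csdsim import (
    StimulusSpec, TissueState, build_default_parameters, initiate_csd, integrate,
    run_regime_experiment, solve_resting_state,
)
from csdsim.tissue import Grid1D
from csdsim.vasculature import calibrate_vascular_response, farr_david_target

LENGTH = 0.25          # cm
N_POINTS = 64
T_WAVE = 60.0          # s, oxygen-clamped wave run
RTOL = 1e-4


@pytest.fixture(scope="session")
def params():
    return build_default_parameters()


@pytest.fixture(scope="session")
def rest(params):
    return solve_resting_state(params, rebalance=False)


@pytest.fixture(scope="session")
def grid():
    return Grid1D(length=LENGTH, n_points=N_POINTS)


@pytest.fixture(scope="session")
def stim():
    return StimulusSpec(center=0.05, sigma=0.02, peak=15.0)


def _wave_run(params, grid, stim, regime, t_end, **kw):
    rest = solve_resting_state(params, rebalance=False)
    state = initiate_csd(TissueState.from_resting(rest, grid), stim, grid)
    return integrate(state, grid, params, regime, t_end, rtol=RTOL,
                     stimulus=stim, **kw)


@pytest.fixture(scope="session")
def run_oxy(params, grid, stim):
    """Oxygen-clamped wave, the in-vitro baseline."""
    return _wave_run(params, grid, stim, "oxygen_clamped", T_WAVE)


@pytest.fixture(scope="session")
def run_oxy_fine(params, stim):
    """Same wave on a grid with doubled resolution (convergence check)."""
    return _wave_run(params, Grid1D(length=LENGTH, n_points=2 * N_POINTS),
                     stim, "oxygen_clamped", 40.0)


@pytest.fixture(scope="session")
def run_vessel_g0(params, grid, stim):
    """Vessel-clamped with gamma = 0: must coincide with oxygen-clamped."""
    return _wave_run(params.replace(gamma=0.0), grid, stim, "vessel_clamped", 40.0)


@pytest.fixture(scope="session")
def run_vessel(params, grid, stim):
    """Vessel-clamped at the default oxygen coupling gamma = 0.5."""
    return _wave_run(params, grid, stim, "vessel_clamped", 90.0)


@pytest.fixture(scope="session")
def calibrated_params(params):
    """Default parameters with the vascular response fit to the target curve."""
    fit = calibrate_vascular_response(farr_david_target(), K_rest=params.K_e0)
    return params.replace(a=fit.a, b=fit.b, c=fit.c, K_dil=fit.K_dil)


@pytest.fixture(scope="session")
def run_coupled(calibrated_params, grid, stim):
    """Fully coupled regime with the calibrated vascular response."""
    return _wave_run(calibrated_params, grid, stim, "coupled", 90.0)


@pytest.fixture(scope="session")
def resting_hold(params, grid):
    """Unstimulated coupled run: the resting state held for 100 s."""
    rest = solve_resting_state(params, rebalance=False)
    return integrate(TissueState.from_resting(rest, grid), grid, params,
                     "coupled", 100.0, rtol=RTOL)


@pytest.fixture(scope="session")
def gamma_sweep(params, grid, stim):
    """Vessel-clamped sweep over the oxygen coupling constant."""
    return run_regime_experiment(
        "vessel_clamped", {"gamma": [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0]},
        params, grid, stim, t_end=90.0, rtol=RTOL)


@pytest.fixture(scope="session")
def ab_sweep(calibrated_params, grid, stim):
    """Coupled 2x2 sweep over constriction width a and maximal dilation b."""
    return run_regime_experiment(
        "coupled", {"a": [50.0, 80.0], "b": [0.0, 0.6]},
        calibrated_params, grid, stim, t_end=90.0, rtol=RTOL)
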
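"""Stimulus, integration, wave metrics, and the three experiment regimes."""

import numpy as np
import pytest

from csdsim import (
    SimulationResult, StimulusSpec, TissueState, duration_above,
    find_stimulus_threshold, initiate_csd, integrate, run_regime_experiment,
    solve_resting_state, wave_metrics, wave_speed,
)
from csdsim.simulate import default_probes
from csdsim.tissue import FIELDS, Grid1D


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

class TestStimulus:
    def test_zero_peak_leaves_state_unchanged(self, rest, grid):
        state = TissueState.from_resting(rest, grid)
        out = initiate_csd(state, StimulusSpec(center=0.1, sigma=0.02, peak=0.0), grid)
        assert np.array_equal(out.to_vector(), state.to_vector())

    def test_injected_moles_match_gaussian_integral(self, rest, grid, params):
        # centre the bolus so the truncated Gaussian tails are negligible
        centred = StimulusSpec(center=grid.length / 2, sigma=0.02, peak=15.0)
        state = TissueState.from_resting(rest, grid)
        out = initiate_csd(state, centred, grid)
        added = np.trapezoid(out.arrays["K_e"] - state.arrays["K_e"], grid.x)
        analytic = centred.peak * centred.sigma * np.sqrt(2.0 * np.pi)
        assert added == pytest.approx(analytic, rel=1e-3)

    def test_injection_is_electroneutral(self, rest, grid, stim):
        state = TissueState.from_resting(rest, grid)
        out = initiate_csd(state, stim, grid)
        net0 = state.arrays["Na_e"] + state.arrays["K_e"] - state.arrays["Cl_e"]
        net1 = out.arrays["Na_e"] + out.arrays["K_e"] - out.arrays["Cl_e"]
        assert np.allclose(net0, net1, atol=1e-12)

    def test_stimulus_outside_domain_rejected(self, rest, grid):
        state = TissueState.from_resting(rest, grid)
        with pytest.raises(ValueError, match="inside the domain"):
            initiate_csd(state, StimulusSpec(center=0.01, sigma=0.02, peak=5.0), grid)

    def test_grid_too_coarse_for_stimulus_rejected(self, rest):
        coarse = Grid1D(length=1.0, n_points=10)
        state = TissueState.from_resting(rest, coarse)
        with pytest.raises(ValueError, match="coarse"):
            initiate_csd(state, StimulusSpec(center=0.5, sigma=0.02, peak=5.0), coarse)


# ---------------------------------------------------------------------------
# synthetic trajectories for the metric extractors
# ---------------------------------------------------------------------------

def _result_with_ke(t, ke, grid, params, stim=None):
    """SimulationResult whose only nontrivial field is [K+]e (n_points, n_t)."""
    y = np.zeros((len(FIELDS) * grid.n_points, t.size))
    i = FIELDS.index("K_e")
    y[i * grid.n_points:(i + 1) * grid.n_points, :] = ke
    return SimulationResult(t=t, y=y, grid=grid, params=params,
                            regime="oxygen_clamped", stimulus=stim)


class TestWaveSpeed:
    def _travelling(self, params, v_cm_s, width=0.01):
        grid = Grid1D(length=0.4, n_points=200)
        t = np.arange(0.0, 50.0, 0.1)
        front = grid.x[:, None] - 0.05 - v_cm_s * t[None, :]
        ke = 3.5 + 50.0 / (1.0 + np.exp(front / width))
        return _result_with_ke(t, ke, grid, params)

    def test_recovers_constructed_speed(self, params):
        res = self._travelling(params, v_cm_s=3.0 / 600.0)   # 3 mm/min
        speed, r2, onsets = wave_speed(res, probes=[0.1, 0.15, 0.2, 0.25])
        assert speed == pytest.approx(3.0, rel=0.01)
        assert r2 > 0.999
        assert np.all(np.isfinite(onsets))

    def test_stationary_bump_flagged_as_nonpropagating(self, params):
        grid = Grid1D(length=0.4, n_points=200)
        t = np.arange(0.0, 20.0, 0.1)
        ke = np.tile(3.5 + 30.0 * np.exp(-((grid.x - 0.05) / 0.02) ** 2)[:, None],
                     (1, t.size))
        res = _result_with_ke(t, ke, grid, params)
        speed, r2, onsets = wave_speed(res, probes=[0.2, 0.25, 0.3])
        assert np.isnan(speed)
        assert np.all(np.isnan(onsets))

    def test_speed_insensitive_to_threshold_for_sharp_front(self, params):
        res = self._travelling(params, v_cm_s=3.0 / 600.0, width=0.004)
        s4, _, _ = wave_speed(res, threshold=4.0, probes=[0.1, 0.15, 0.2])
        s8, _, _ = wave_speed(res, threshold=8.0, probes=[0.1, 0.15, 0.2])
        assert abs(s8 / s4 - 1.0) < 0.02

    def test_too_few_probes_rejected(self, params):
        res = self._travelling(params, v_cm_s=0.005)
        with pytest.raises(ValueError, match="3 probes"):
            wave_speed(res, probes=[0.1, 0.2])


class TestDurationAbove:
    def _trace(self, params, t, values):
        grid = Grid1D(length=0.1, n_points=8)
        ke = np.tile(np.asarray(values, dtype=float), (grid.n_points, 1))
        return _result_with_ke(t, ke, grid, params)

    def test_never_above_gives_zero(self, params):
        t = np.arange(0.0, 10.0, 0.5)
        res = self._trace(params, t, np.full(t.size, 3.5))
        assert duration_above(res, probe=0.05) == 0.0

    def test_square_pulse_measured_exactly(self, params):
        t = np.arange(0.0, 80.0, 0.5)
        y = np.full(t.size, 2.0)
        y[(t > 10.0) & (t < 50.0)] = 20.0
        y[t == 10.0] = 6.0    # threshold-valued samples at the pulse edges
        y[t == 50.0] = 6.0
        res = self._trace(params, t, y)
        assert duration_above(res, probe=0.05) == pytest.approx(40.0)

    def test_multiple_excursions_add(self, params):
        t = np.arange(0.0, 60.0, 0.5)
        y = np.full(t.size, 2.0)
        for lo, hi in ((5.0, 15.0), (30.0, 35.0)):   # 10 s + 5 s
            y[(t > lo) & (t < hi)] = 20.0
            y[t == lo] = 6.0
            y[t == hi] = 6.0
        res = self._trace(params, t, y)
        assert duration_above(res, probe=0.05) == pytest.approx(15.0)


# ---------------------------------------------------------------------------
# integration behaviour
# ---------------------------------------------------------------------------

class TestIntegration:
    def test_determinism_bit_identical(self, rest, params):
        grid = Grid1D(length=0.1, n_points=8)
        state = TissueState.from_resting(rest, grid)
        state.arrays["K_e"] = state.arrays["K_e"] + 10.0
        state.arrays["Cl_e"] = state.arrays["Cl_e"] + 10.0
        r1 = integrate(state, grid, params, "coupled", 5.0, rtol=1e-5)
        r2 = integrate(state, grid, params, "coupled", 5.0, rtol=1e-5)
        assert np.array_equal(r1.y, r2.y)

    def test_tolerance_convergence_of_peak_potassium(self, rest, params):
        grid = Grid1D(length=0.1, n_points=8)
        state = TissueState.from_resting(rest, grid)
        state.arrays["K_e"] = state.arrays["K_e"] + 20.0   # uniform ignition
        state.arrays["Cl_e"] = state.arrays["Cl_e"] + 20.0
        peaks = [integrate(state, grid, params, "oxygen_clamped", 30.0,
                           rtol=r).field("K_e").max() for r in (1e-4, 5e-5)]
        assert abs(peaks[1] / peaks[0] - 1.0) < 5e-3

    def test_nonfinite_initial_state_rejected(self, rest, params):
        grid = Grid1D(length=0.1, n_points=8)
        state = TissueState.from_resting(rest, grid)
        state.arrays["V_s"] = state.arrays["V_s"] * np.nan
        with pytest.raises(ValueError, match="nonfinite"):
            integrate(state, grid, params, "coupled", 1.0)


# ---------------------------------------------------------------------------
# simulated-wave metrics (shared runs)
# ---------------------------------------------------------------------------

class TestSimulatedWave:
    def test_wave_reaches_probes_at_equal_lags(self, run_oxy):
        m = wave_metrics(run_oxy)
        assert m.propagated
        lags = np.diff(m.onset_times_s)
        assert np.all(lags > 0)
        assert lags.std() / lags.mean() < 0.05   # equally spaced probes, equal lags

    def test_front_speed_is_constant_and_physiological(self, run_oxy):
        m = wave_metrics(run_oxy)
        assert m.speed_r2 >= 0.99
        assert 1.0 < m.speed_mm_min < 10.0       # mm/min, CSD range

    def test_peak_potassium_in_reported_ceiling_range(self, run_oxy):
        m = wave_metrics(run_oxy)
        assert 30.0 < m.peak_K_e < 80.0

    def test_buffer_saturates_then_rereleases(self, run_oxy, params):
        probe = default_probes(run_oxy.stimulus)[0]
        b = run_oxy.probe_trace("B", probe)
        k = run_oxy.probe_trace("K_e", probe)
        assert b.min() < 0.5 * params.B_tot       # strongly depleted during the wave
        # after potassium clearance the bound pool slowly re-releases: the free
        # buffer recovers from its minimum but is still far from full
        assert b[-1] > b.min()
        assert b[-1] < 0.95 * params.B_tot
        assert k[-1] < 6.0                        # the event is over at this probe

    def test_gamma_zero_vessel_clamp_matches_oxygen_clamp(self, run_oxy, run_vessel_g0,
                                                          params):
        n = run_vessel_g0.t.size
        dk = np.max(np.abs(run_vessel_g0.field("K_e") - run_oxy.field("K_e")[:, :n]))
        assert dk < 0.3   # mM; identical vector fields up to solver tolerance
        assert np.max(np.abs(run_vessel_g0.field("O2") - params.O2_0)) == 0.0
        m0 = wave_metrics(run_oxy)
        m1 = wave_metrics(run_vessel_g0, duration_probe=None)
        assert m1.speed_mm_min == pytest.approx(m0.speed_mm_min, rel=5e-3)

    def test_coupled_dilation_constriction_recovery_sequence(self, run_coupled):
        probe = default_probes(run_coupled.stimulus)[0]
        idx = run_coupled.probe_index(probe)
        r = run_coupled.radius_rel()[idx, :]
        t_min = np.argmin(r)
        assert r[:t_min].max() > 1.005      # transient dilation first
        assert r[t_min] < 0.6               # deep constriction
        assert r[-1] > 0.85                 # recovery by the end of the run

    def test_constriction_deepens_deoxygenation(self, run_coupled, run_vessel):
        # same gamma: the coupled (constricting) run must go lower in oxygen
        assert run_coupled.field("O2").min() < run_vessel.field("O2").min()


class TestRegimeExperiment:
    def test_speed_duration_amplitude_nondecreasing_in_gamma(self, gamma_sweep):
        df = gamma_sweep.sort_values("gamma")
        assert (df["error"] == "").all()
        assert df["propagated"].all()
        for col in ("speed_mm_min", "duration_s", "peak_K_e"):
            assert np.all(np.diff(df[col]) > -1e-9), col

    def test_duration_nonincreasing_in_constriction_width_and_dilation(self, ab_sweep):
        df = ab_sweep
        assert (df["error"] == "").all()
        for b, sub in df.groupby("b"):
            s = sub.sort_values("a")["duration_s"].to_numpy()
            assert s[1] <= s[0] + 0.05, f"duration not nonincreasing in a at b={b}"
        for a, sub in df.groupby("a"):
            s = sub.sort_values("b")["duration_s"].to_numpy()
            assert s[1] <= s[0] + 0.05, f"duration not nonincreasing in b at a={a}"

    def test_failing_point_recorded_not_fatal(self, params, grid, stim):
        df = run_regime_experiment("coupled", {"b": [-5.0]}, params, grid, stim,
                                   t_end=1.0)
        assert len(df) == 1
        assert df.loc[0, "error"] != ""

    def test_single_point_sweep_equals_direct_run(self, params, grid, stim):
        t_end = 25.0
        df = run_regime_experiment("oxygen_clamped", {}, params, grid, stim,
                                   t_end=t_end, rtol=1e-4, dt_out=0.1)
        rest = solve_resting_state(params, rebalance=False)
        state = initiate_csd(TissueState.from_resting(rest, grid), stim, grid)
        res = integrate(state, grid, params, "oxygen_clamped", t_end, rtol=1e-4,
                        dt_out=0.1, stimulus=stim)
        m = wave_metrics(res)
        assert df.loc[0, "speed_mm_min"] == pytest.approx(m.speed_mm_min, rel=1e-9)
        assert df.loc[0, "peak_K_e"] == pytest.approx(m.peak_K_e, rel=1e-9)


def test_threshold_search_rejects_propagating_lower_bracket(params, grid, stim):
    with pytest.raises(ValueError, match="lower bracket"):
        find_stimulus_threshold(params, grid, stim=stim, t_end=25.0,
                                lo=15.0, hi=30.0)
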
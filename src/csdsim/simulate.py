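"""Time integration, CSD initiation, wave metrics, and regime experiments.

The model is deterministic: there is no randomness anywhere, so repeated runs
with the same configuration are bit-identical.
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from . import tissue
from .parameters import ModelParameters, RestingState, balance_leak_conductances, solve_resting_state
from .tissue import FIELDS, Grid1D, TissueState, assemble_rhs, jacobian_sparsity
from .vasculature import response_from_params, vessel_radius

__all__ = [
    "StimulusSpec", "SimulationResult", "WaveMetrics", "initiate_csd",
    "integrate", "wave_speed", "duration_above", "wave_metrics",
    "run_regime_experiment", "find_stimulus_threshold", "default_probes",
]

#: reporting position: 780 um downstream of the stimulus centre, plus four
#: further probes at 120 um spacing for the speed fit.
PROBE_OFFSET = 0.078   # cm
PROBE_SPACING = 0.012  # cm
N_PROBES = 5

#: potassium threshold (mM) defining both CSD duration and front onset.
K_THRESHOLD = 6.0


@dataclass
class StimulusSpec:
    """Gaussian extracellular potassium bolus used to ignite CSD."""

    center: float = 0.05   # cm
    sigma: float = 0.02    # cm (200 um)
    peak: float = 15.0     # mM added [K+]e at the centre

    def validate(self, grid: Grid1D) -> None:
        if self.sigma <= 0:
            raise ValueError("stimulus sigma must be positive")
        if self.peak < 0:
            raise ValueError("stimulus peak must be nonnegative")
        if self.center - 2 * self.sigma < 0 or self.center + 2 * self.sigma > grid.length:
            raise ValueError("stimulus (center +/- 2 sigma) must lie inside the domain")
        if grid.dx > self.sigma / 4:
            raise ValueError(
                f"grid too coarse for the stimulus: dx = {grid.dx:.4g} cm exceeds "
                f"sigma/4 = {self.sigma / 4:.4g} cm")


def default_probes(stim: StimulusSpec) -> np.ndarray:
    """Probe positions downstream of the stimulus (cm)."""
    return stim.center + PROBE_OFFSET + PROBE_SPACING * np.arange(N_PROBES)


def initiate_csd(state: TissueState, stim: StimulusSpec, grid: Grid1D) -> TissueState:
    """Return a copy of ``state`` with the potassium bolus added.

    [K+]e gains ``peak * exp(-(x-center)^2 / (2 sigma^2))``; [Cl-]e gains the
    identical profile so the injection is electroneutral (the bolus is KCl).
    Everything else is untouched.
    """
    stim.validate(grid)
    out = state.copy()
    bump = stim.peak * np.exp(-((grid.x - stim.center) ** 2) / (2.0 * stim.sigma**2))
    out.arrays["K_e"] = out.arrays["K_e"] + bump
    out.arrays["Cl_e"] = out.arrays["Cl_e"] + bump
    return out


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory of one simulation, sampled on a fixed output raster."""

    t: np.ndarray                 # s, shape (n_t,)
    y: np.ndarray                 # shape (n_fields * n_points, n_t)
    grid: Grid1D
    params: ModelParameters
    regime: str
    stimulus: Optional[StimulusSpec] = None
    diagnostics: dict = dc_field(default_factory=dict)

    def field(self, name: str) -> np.ndarray:
        """Trajectory of one state field, shape (n_points, n_t)."""
        i = FIELDS.index(name)
        n = self.grid.n_points
        return self.y[i * n:(i + 1) * n, :]

    def probe_index(self, x: float) -> int:
        if not 0.0 <= x <= self.grid.length:
            raise ValueError(f"probe position {x} outside the domain")
        return int(round(x / self.grid.dx))

    def probe_trace(self, name: str, x: float) -> np.ndarray:
        return self.field(name)[self.probe_index(x), :]

    def radius_rel(self) -> np.ndarray:
        """r/r0 over space and time (identically 1 outside the coupled regime)."""
        if self.regime != "coupled":
            return np.ones_like(self.field("K_e"))
        return vessel_radius(np.maximum(self.field("K_e"), 0.0),
                             response_from_params(self.params))


def _atol_vector(grid: Grid1D) -> np.ndarray:
    per_field = {"V_s": 1e-3, "V_d": 1e-3, "B": 1e-4, "O2": 1e-7}
    atol = []
    for f in FIELDS:
        if f in per_field:
            a = per_field[f]
        elif f in ("Na_s", "K_s", "Cl_s", "Na_d", "K_d", "Cl_d",
                   "Na_e", "K_e", "Cl_e"):
            a = 1e-4
        else:  # gating
            a = 1e-7
        atol.append(np.full(grid.n_points, a))
    return np.concatenate(atol)


def integrate(initial: TissueState, grid: Grid1D, params: ModelParameters,
              regime: str, t_end: float, rtol: float = 1e-5,
              atol=None, dt_out: float = 0.1,
              stimulus: Optional[StimulusSpec] = None) -> SimulationResult:
    """Stiff (BDF) integration of the full model.

    Output is sampled every ``dt_out`` seconds.  Raises RuntimeError with the
    final time reached on solver failure, and on any nonfinite state.
    """
    if regime not in tissue.REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    y0 = initial.to_vector()
    if not np.all(np.isfinite(y0)):
        raise ValueError("nonfinite initial state")
    if atol is None:
        atol = _atol_vector(grid)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], t_end)
    wall = time.perf_counter()
    with warnings.catch_warnings():
        # the coloured finite-difference Jacobian probes step sizes across
        # ~15 orders of magnitude of state scales; silence its benign
        # overflow chatter
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module=r"scipy\.integrate\._ivp\.common")
        sol = solve_ivp(
            assemble_rhs, (0.0, t_end), y0, method="BDF", t_eval=t_eval,
            args=(grid, params, regime), rtol=rtol, atol=atol,
            jac_sparsity=jacobian_sparsity(grid),
        )
    wall = time.perf_counter() - wall
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"stiff integration failed at t = {reached:.3f} s of {t_end} s: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise RuntimeError("nonfinite state produced during integration")
    diag = {"nfev": int(sol.nfev), "njev": int(sol.njev), "nlu": int(sol.nlu),
            "n_steps": int(sol.t.size), "wall_time_s": wall, "rtol": rtol,
            "message": str(sol.message)}
    return SimulationResult(t=sol.t, y=sol.y, grid=grid, params=params,
                            regime=regime, stimulus=stimulus, diagnostics=diag)


# ---------------------------------------------------------------------------
# wave metrics
# ---------------------------------------------------------------------------

def _first_crossing(t: np.ndarray, trace: np.ndarray, threshold: float) -> Optional[float]:
    """Time of first upward crossing of ``threshold``, linearly interpolated."""
    above = trace >= threshold
    if not np.any(above):
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = trace[i - 1], trace[i]
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def wave_speed(result: SimulationResult, threshold: float = K_THRESHOLD,
               probes: Optional[Sequence[float]] = None):
    """Front speed from threshold-onset times at several probes.

    Returns ``(speed_mm_per_min, r_squared, onset_times)``; speed is the
    slope of a linear fit of probe position against onset time.  If the wave
    fails to reach every probe the run is flagged as non-propagating and
    ``(nan, nan, onsets)`` is returned.  An R^2 below 0.99 indicates a
    non-constant front speed.
    """
    if probes is None:
        if result.stimulus is None:
            raise ValueError("no probes given and the run has no stimulus to anchor them")
        probes = default_probes(result.stimulus)
    probes = np.asarray(probes, dtype=float)
    if probes.size < 3:
        raise ValueError("speed fit needs at least 3 probes")
    onsets = np.array([
        np.nan if (c := _first_crossing(result.t, result.probe_trace("K_e", x),
                                        threshold)) is None else c
        for x in probes
    ])
    if np.any(np.isnan(onsets)):
        return float("nan"), float("nan"), onsets
    fit = linregress(onsets, probes)
    speed_cm_s = fit.slope
    return float(speed_cm_s * 600.0), float(fit.rvalue**2), onsets


def duration_above(result: SimulationResult, probe: float,
                   threshold: float = K_THRESHOLD) -> float:
    """Total time (s) the probe's [K+]e exceeds ``threshold``.

    Lebesgue measure of the super-threshold set under linear interpolation
    between samples; sums over multiple excursions; 0 if never above.
    """
    t = result.t
    yv = result.probe_trace("K_e", probe)
    above = yv > threshold
    total = 0.0
    for i in range(len(t) - 1):
        t0, t1 = t[i], t[i + 1]
        y0, y1 = yv[i], yv[i + 1]
        if above[i] and above[i + 1]:
            total += t1 - t0
        elif above[i] != above[i + 1] and y1 != y0:
            tc = t0 + (threshold - y0) / (y1 - y0) * (t1 - t0)
            total += (tc - t0) if above[i] else (t1 - tc)
    return float(total)


@dataclass
class WaveMetrics:
    """Summary observables of one simulated CSD event."""

    propagated: bool
    speed_mm_min: float      # front speed
    speed_r2: float          # linearity of position vs onset time
    duration_s: float        # time [K+]e > 6 mM at the reporting probe
    peak_K_e: float          # mM, max over space and time
    min_r_rel: float         # min r/r0 over space and time (1 if uncoupled)
    min_O2: float            # mM, min over space and time
    onset_times_s: np.ndarray

    def as_row(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("propagated", "speed_mm_min", "speed_r2", "duration_s",
              "peak_K_e", "min_r_rel", "min_O2")}
        return d


def wave_metrics(result: SimulationResult, threshold: float = K_THRESHOLD,
                 probes: Optional[Sequence[float]] = None,
                 duration_probe: Optional[float] = None) -> WaveMetrics:
    """Extract WaveMetrics from a trajectory.

    The duration probe defaults to the first default probe (780 um downstream
    of the stimulus).
    """
    if probes is None:
        if result.stimulus is None:
            raise ValueError("no probes given and the run has no stimulus to anchor them")
        probes = default_probes(result.stimulus)
    probes = np.asarray(probes, dtype=float)
    speed, r2, onsets = wave_speed(result, threshold, probes)
    if duration_probe is None:
        duration_probe = float(probes[0])
    return WaveMetrics(
        propagated=bool(np.all(np.isfinite(onsets))),
        speed_mm_min=speed,
        speed_r2=r2,
        duration_s=duration_above(result, duration_probe, threshold),
        peak_K_e=float(result.field("K_e").max()),
        min_r_rel=float(result.radius_rel().min()),
        min_O2=float(result.field("O2").min()),
        onset_times_s=onsets,
    )


# ---------------------------------------------------------------------------
# regime experiments
# ---------------------------------------------------------------------------

def run_regime_experiment(regime: str, sweep: dict, params: ModelParameters,
                          grid: Grid1D, stim: StimulusSpec, t_end: float,
                          rtol: float = 1e-5, dt_out: float = 0.25) -> pd.DataFrame:
    """One WaveMetrics row per point of the (outer-product) sweep grid.

    ``sweep`` maps parameter names to value lists; an empty dict runs the base
    configuration once.  Runs are independent; a failing run is recorded in
    its row's ``error`` column rather than aborting the sweep.  Each row also
    records the regime, grid, and solver tolerance for provenance.
    """
    if regime not in tissue.REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    names = list(sweep)
    combos = list(itertools.product(*(sweep[k] for k in names))) or [()]
    rows = []
    for combo in combos:
        point = dict(zip(names, combo))
        row = {**point, "regime": regime, "n_points": grid.n_points,
               "length_cm": grid.length, "rtol": rtol, "error": ""}
        try:
            p = balance_leak_conductances(params.replace(**point))
            rest = solve_resting_state(p, rebalance=False)
            state0 = initiate_csd(TissueState.from_resting(rest, grid), stim, grid)
            res = integrate(state0, grid, p, regime, t_end, rtol=rtol,
                            dt_out=dt_out, stimulus=stim)
            row.update(wave_metrics(res).as_row())
        except Exception as exc:  # per-row failure, not fatal to the sweep
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def find_stimulus_threshold(params: ModelParameters, grid: Grid1D,
                            regime: str = "oxygen_clamped",
                            stim: Optional[StimulusSpec] = None,
                            t_end: float = 60.0, lo: float = 0.0,
                            hi: float = 30.0, tol: float = 1.0) -> float:
    """Minimal bolus peak (mM) that ignites a propagating wave, by bisection.

    ``lo`` must fail to propagate and ``hi`` must propagate; the returned
    value is the midpoint of the final bracket of width <= ``tol``.
    """
    stim = stim or StimulusSpec()
    rest = solve_resting_state(params)
    base = TissueState.from_resting(rest, grid)

    def propagates(peak: float) -> bool:
        s = StimulusSpec(center=stim.center, sigma=stim.sigma, peak=peak)
        res = integrate(initiate_csd(base, s, grid), grid, rest.params, regime,
                        t_end, stimulus=s)
        speed, _, onsets = wave_speed(res)
        return bool(np.all(np.isfinite(onsets)))

    if propagates(lo):
        raise ValueError("lower bracket already propagates")
    if not propagates(hi):
        raise ValueError("upper bracket does not propagate")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if propagates(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
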
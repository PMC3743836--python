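# csdsim

Continuum simulation of **cortical spreading depression (CSD)** with
metabolic and vascular feedback.

CSD is a slow (mm/min) wave of near-complete neuronal depolarisation and
ionic redistribution that propagates through grey matter; it underlies
migraine aura and accompanies stroke, traumatic brain injury, and
subarachnoid haemorrhage. Classical CSD models treat the energy supply as
unlimited — appropriate for a brain slice in oxygenated bath, not for the
intact brain, where the wave itself constricts the vessels that deliver the
oxygen its recovery depends on. `csdsim` closes that loop.

## The model

Five compartments on a 1-D tissue continuum: neuronal somata and dendrites
(Hodgkin–Huxley-style gating, GHK channel currents: persistent Na⁺,
delayed-rectifier and A-type K⁺, dendritic NMDA, ohmic leaks), extracellular
space (ion reaction–diffusion), a saturable glial potassium buffer, and a
lumped vascular tree. The pieces that make it a *metabolic* model:

- **Na⁺/K⁺-ATPase**, rate `I_max · s_Na(Na_i)³ · s_K(K_e)²`, scaled by an
  oxygen factor `f(O2)` with `f(0) = ε ≈ 0.05` (anaerobic floor) and
  `f(O2₀) = 1` at the resting tissue oxygen O2₀ = 0.2 mM.
- **Neurovascular coupling**: effective vessel radius
  `r(K_e)/r₀ = C(K_e; a) · D(K_e; b, c, K_dil)` — a constricting Gaussian of
  width `a` times a dilating bump of height `b` — normalised to 1 at resting
  potassium. Moderate K⁺ elevations dilate, large ones constrict.
- **Poiseuille flow**: CBF/CBF₀ = (r/r₀)⁴, so a 60% constriction cuts flow
  to 2.6% of baseline.
- **Tissue oxygen** reaction–diffusion: supply = flow × normalised
  blood–tissue O2 difference; consumption = steady non-pump share (1−γ)
  plus pump share γ scaled by instantaneous pump rate.

Three experiment regimes reproduce the classical in-vitro/in-vivo contrast:
`oxygen_clamped` (unlimited oxygen), `vessel_clamped` (fixed supply rate,
dynamic oxygen), and `coupled` (full feedback).

## Worked example

```python
from csdsim import (build_default_parameters, solve_resting_state, TissueState,
                    StimulusSpec, initiate_csd, integrate, wave_metrics)
from csdsim.tissue import Grid1D

params = build_default_parameters()          # rest-balanced defaults
grid = Grid1D(length=0.25, n_points=96)      # 2.5 mm of cortex
rest = solve_resting_state(params, rebalance=False)
stim = StimulusSpec(center=0.05, sigma=0.02, peak=15.0)   # KCl bolus
state = initiate_csd(TissueState.from_resting(rest, grid), stim, grid)
result = integrate(state, grid, params, regime="coupled", t_end=60.0,
                   stimulus=stim)
m = wave_metrics(result)
print(f"speed     {m.speed_mm_min:.2f} mm/min (R^2 = {m.speed_r2:.4f})")
print(f"duration  {m.duration_s:.1f} s above 6 mM at the 780 um probe")
print(f"peak K_e  {m.peak_K_e:.1f} mM   min r/r0 {m.min_r_rel:.2f}   "
      f"min O2 {m.min_O2:.3f} mM")
```

prints

```
speed     3.26 mm/min (R^2 = 0.9985)
duration  27.0 s above 6 mM at the 780 um probe
peak K_e  63.7 mM   min r/r0 0.42   min O2 0.005 mM
```

— a wave travelling at 3.3 mm/min whose potassium peak drives the vessels
to 42% of their resting radius, collapsing blood flow to ~3% of baseline
and the local tissue oxygen to near zero: the metabolic demand of CSD
exceeds what the vasculature can deliver, and the constriction it triggers
makes the deficit worse. Under `regime="oxygen_clamped"` the same stimulus
gives a slower, briefer wave (3.2 mm/min, 23 s, peak 54 mM) — the model's
account of why CSD is faster and longer-lasting in vivo than in slices.

A command line covers the same ground: `csdsim run`, `csdsim sweep`
(regime experiments over parameter grids, e.g. the oxygen-coupling constant
γ or the vascular constants a and b), `csdsim metrics` (recompute from a
stored trajectory), `csdsim calibrate` (fit the vascular response to a
radius-vs-potassium table), `csdsim check` (invariant suite), and
`csdsim fixture` (regression reference runs).

## Layout

- `src/csdsim/parameters.py` — parameter record, unit system, resting state
- `src/csdsim/membrane.py` — gating, GHK currents, pump, oxygen factor
- `src/csdsim/vasculature.py` — radius response, Poiseuille flow, O2 balance
- `src/csdsim/tissue.py` — spatial right-hand side, buffer, conservation
- `src/csdsim/simulate.py` — stiff integration, stimulus, wave metrics, sweeps
- `src/csdsim/cli.py` — command-line interface and trajectory storage
- `docs/methods.md` — model details, parameter provenance, numerics
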
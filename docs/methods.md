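# Methods

`csdsim` simulates cortical spreading depression (CSD) — the slow,
self-propagating wave of near-complete neuronal depolarisation and ionic
redistribution seen in grey matter — with explicit metabolic and vascular
feedback. This note documents the model, its parameters and their
provenance, the numerical choices, and the limits of what the test suite
demonstrates.

## Model structure

Five compartments share each point of a 1-D tissue continuum: neuronal
somata (volume fraction `W_s`), neuronal dendrites (`W_d`), extracellular
space (ECS, `W_e`), a glial potassium buffer, and a lumped vascular tree.
Volume fractions are fixed — cell swelling is deliberately outside the scope
of the model, as is calcium signalling.

### Membrane electrophysiology

Each neuronal compartment carries a membrane potential obeying
`C_m dV/dt = -I_total + I_coupling`, with the soma–dendrite electrotonic
coupling current `g_sd (V_other - V_self)/A_self` (equal and opposite after
area weighting, so it moves charge between compartments without creating
any).

Cross-membrane currents per ion (outward positive):

- **Persistent (P-type) Na⁺** — GHK flux form, gating `m²h` with fast
  activation (τ = 2 ms, half-activation −40 mV) and slow, partial
  inactivation (τ up to ~3 s near rest).
- **Delayed-rectifier K⁺** — GHK, `n²`, τ = 3 ms, half-activation −30 mV.
- **A-type K⁺** — GHK, `a²b`, fast transient.
- **NMDA** (dendrites only) — GHK for Na⁺ and K⁺ with equal permeability,
  gated by the product of a Jahr–Stevens magnesium-block factor
  `1/(1 + [Mg]/3.57 · e^(-0.062V))` and a slow (τ = 500 ms) voltage-driven
  activation variable. Glutamate dynamics are not modelled; the channel is
  driven by voltage alone. The NMDA plateau is what sustains the
  depolarised state during the wave; the persistent Na channel ignites it.
- **Ohmic leaks** for Na⁺, K⁺, Cl⁻. The chloride leak conductance is a free
  parameter (its Nernst potential is pinned to `V_rest` by construction, so
  it carries no resting current); the Na⁺ and K⁺ leak conductances are
  **derived**, not chosen: they absorb whatever current the gated channels
  and the pump leave unbalanced at rest. This guarantees an exact resting
  fixed point for any otherwise-valid parameter set, and fails loudly
  (negative required conductance) if the channel/pump balance is
  inconsistent.
- **Na⁺/K⁺-ATPase** — scalar rate
  `P = I_max · (Na_i/(Na_i+K_mNa))³ · (K_e/(K_e+K_mK))²` (three
  intracellular Na sites, two extracellular K sites), contributing `+3P` of
  Na current and `−2P` of K current. The full pump rate is this expression
  multiplied by the oxygen factor below.

The transient (fast-inactivating) sodium channel is omitted: its currents
are negligible on the minutes time scale of CSD.

### Oxygen limitation of the pump

The pump's oxygen factor is Michaelis–Menten in tissue oxygen, affinely
rescaled to satisfy two anchors: factor(0) = ε (the ~5% of ATP production
that is oxygen-independent, i.e. glycolytic) and factor(O2₀) = 1 at the
resting tissue oxygen of 0.2 mM:

    f(O2) = ε + (1 − ε) · [O2/(O2 + K_half)] / [O2₀/(O2₀ + K_half)]

with `K_half` = 0.08 mM exposed in config. The factor is continuous,
monotone, floors at ε, and saturates modestly above rest.

### Ion balances

ECS ions obey reaction–diffusion:
`d[ion]ₑ/dt = D* ∇²[ion]ₑ + (A_s I_s + A_d I_d)/(zF W_e)`, with effective
diffusivities equal to aqueous values divided by tortuosity squared
(λ = 1.6). The potassium equation additionally subtracts the glial
buffering flux. Intracellular ions carry no spatial diffusion term; soma
and dendrite exchange ions through a flux proportional to their
concentration difference, volume-weighted so moles are conserved. ECS
chloride initially equals the sum of the cations (electroneutrality);
intracellular electroneutrality is carried by implicit immobile anions and
is not enforced dynamically.

### Glial potassium buffer

First-order uptake/release with a threshold:

    uptake  = k₁ · g(K_e) · K_e · B,   g = 1/(1 + exp(−(K_e − K_th)/s))
    release = k₂ · (B_tot − B)
    v_buffer = uptake − release,   dB/dt = −v_buffer

The threshold sigmoid (centre 15 mM, width 1 mM) makes buffering strong
only for clearly pathological potassium; the initial free buffer B₀ is set
so the flux is exactly zero at resting potassium. The buffer saturates
early in the wave and then slowly re-releases potassium — the long shallow
tail seen after recovery.

### Vasculature and oxygen supply

The effective vessel radius responds to local ECS potassium as a product of
a constricting and a dilating term, renormalised to 1 at resting potassium:

    r(K)/r₀ = N · C(K) · D(K)
    C(K) = exp(−((K − K_rest)/a)²)  for K > K_rest, else 1
    D(K) = 1 + b · exp(−((K − K_dil)/c)²)

`a` is the Gaussian constriction width (the 63%-constriction potassium
elevation), `b` the maximal fractional dilation, `c` the dilation width,
`K_dil` the dilation-peak potassium. The dilation bump is deliberately
narrow (c = 3 mM): a wide bump leaks into the normalisation point at
`K_rest`, which silently converts "more dilation" into "uniformly more
constriction" after renormalising — inverting the physiological role of
`b`.

Blood flow is Poiseuille: CBF/CBF₀ = (r/r₀)⁴. Tissue oxygen obeys

    dO2/dt = D_O2 ∇²O2 + k_O2 [ cbf · (O2_b − O2)/(O2_b − O2₀)
                                − α(O2) ((1 − γ) + γ · pump_rel) ]

supply being flow times the normalised blood–tissue oxygen difference, and
consumption being the steady non-pump share (1 − γ) plus the pump share γ
scaled by the instantaneous tissue-averaged pump rate relative to rest. The
availability factor α(O2) (the same Michaelis saturation as the pump
factor, normalised to 1 at rest) shuts consumption off as oxygen vanishes;
without it the source term would integrate oxygen to negative
concentrations during deep hypoxia. γ — the fraction of resting oxygen
consumption attributable to the pump — defaults to 0.5, the midpoint of the
wide experimental range, and is the primary sweep parameter.

### Experiment regimes

- `oxygen_clamped` — O2 pinned at O2₀, pump factor ≡ 1, radius frozen at 1.
  The in-vitro (slice) limit: unlimited oxygen.
- `vessel_clamped` — radius frozen at 1 (constant maximal supply rate) but
  oxygen dynamic and coupled to the pump through γ. Isolates consumption.
- `coupled` — radius follows local potassium, flow follows radius. The
  in-vivo model. With γ = 0 and uniform initial oxygen, both clamped
  regimes and the coupled oxygen dynamics reduce exactly to the
  oxygen-clamped trajectory, which the tests verify.

## Parameter provenance

Three classes of values, all exposed as fields of `ModelParameters`, none
hard-coded in model logic:

1. **Anchored**: ε = 0.05, O2₀ = 0.2 mM, the 3:2 pump stoichiometry, the
   r⁴ flow law, ECS electroneutrality, E_Cl = V_rest, the 6 mM
   duration/onset threshold, the 780 µm reporting probe.
2. **Lineage defaults**: resting concentrations, volume fractions,
   membrane areas, diffusivities, pump half-saturations (K_mK = 2 mM,
   K_mNa = 7.7 mM) follow the Kager/Somjen/Yao family of CSD models this
   model descends from.
3. **Calibrated here**: the maximal channel permeabilities, pump maximum,
   and buffer constants were set, once, so that the oxygen-clamped model
   reproduces the canonical CSD phenotype — speed ≈ 3 mm/min, peak [K⁺]ₑ
   ≈ 54 mM, duration above 6 mM ≈ 23 s, ignition threshold near the
   physiological potassium ceiling (~12–15 mM). The vascular constants
   (a = 65 mM, b = 0.15, c = 3 mM, K_dil = 9 mM) generate the built-in
   synthetic Farr–David-shaped target curve; `a` is set mid-band of the
   physiologically plausible 30–80 mM range, anchored so the curve reads
   ≈40% of rest radius at CSD-peak potassium. The curve is a synthetic
   stand-in shaped by the qualitative description of the arteriolar
   response (dilation below ~15 mM, constriction above), not digitised
   data.

## Numerics

- **Units**: mV, mM, s, cm, µA/cm² throughout. Gating kinetics are written
  in their conventional millisecond form and converted by a single factor
  at definition. With these units the factor converting `A·I/(zFW)` to
  mM/s is exactly 1/F.
- **Spatial discretisation**: method of lines on a uniform grid;
  conservative second-difference Laplacian whose boundary stencils impose
  zero interface flux, so the discrete operator sums to zero to machine
  precision and total Na, Cl, and K (free + buffered) are conserved to
  better than 10⁻⁶ relative over a full wave.
- **Time integration**: `scipy.integrate.solve_ivp` BDF with a
  hand-specified Jacobian sparsity pattern (the model's actual dependency
  graph: ~10–16 couplings per field plus diffusion neighbours), rtol 10⁻⁴
  by default, per-field absolute tolerances, 0.1 s output raster. Halving
  rtol moves peak potassium by <0.5%.
- **State layout**: field-major (`y[f·N:(f+1)·N]` is field f on the grid);
  the 24 fields are the two potentials, eleven gating variables, nine ion
  concentrations, free buffer, and oxygen.
- **Degenerate inputs**: concentrations are floored at 10⁻⁹ mM inside
  current evaluations; gating variables are clipped to [0,1] and oxygen to
  ≥0 before kinetics are evaluated; the GHK u → 0 singularity is handled
  by its analytic limit.
- **Study geometry** (tests and acceptance runs): 2.5 mm domain, 64–128
  grid points, Gaussian KCl bolus (σ = 200 µm, +15 mM peak) at x = 0.5 mm,
  probes from 780 µm downstream of the stimulus at 120 µm spacing. A 2.5 mm
  domain is the shortest in which the wave settles to constant speed
  (R² > 0.999 for position vs onset time) before boundary effects appear;
  doubling the grid changes the measured speed by <2%.

## What the simulations do and do not show

The model reproduces, from mechanism rather than prescription: constant
wave speed in the low mm/min range; peak extracellular potassium in the
30–70 mM range; buffer saturation followed by re-release; speed, duration
and amplitude all increasing with the oxygen coupling γ; transient dilation
followed by deep constriction (to ~40% of rest) and recovery in the coupled
regime; deeper deoxygenation with vasoconstriction than without at equal γ;
and shorter CSD when constriction is weakened (larger `a`) or dilation
strengthened (larger `b`).

It does not model: osmotic volume changes, calcium, glutamate release,
post-CSD hypoperfusion, explicit vascular network geometry, or any
vasoactive mediator other than potassium. The synthetic vascular target
curve means quantitative vascular conclusions inherit the uncertainty of
that curve's shape; the qualitative orderings above are robust to it. All
dynamics are deterministic — there is no stochastic channel or input noise,
so "reproducibility" in this package means bit-identical repetition, not
statistical agreement.
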
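"""Model parameters, unit system, and the resting steady state.

Internal unit system (used by every function in this package):

======================  =========  =====================================
quantity                unit       notes
======================  =========  =====================================
time                    s          gating rates written in ms are
                                   converted once, at definition (x1000)
voltage                 mV
concentration           mM         = mmol / L
length                  cm
current density         uA/cm^2
capacitance             uF/cm^2    C dV/dt: dV/dt[mV/s] = 1e3 * I/C
conductance             mS/cm^2    I[uA/cm^2] = g * (V - E)[mV]
GHK permeability        cm/s       I[uA/cm^2] = P z^2 F xi GHK(c) [mM]
area / tissue volume    1/cm
diffusivity             cm^2/s
pump / buffer fluxes    mM/s
======================  =========  =====================================

Concentration balance from a membrane current:
``d[ion]/dt [mM/s] = sign * A[1/cm] * I[uA/cm^2] / (z * F * W)`` -- the 1e-6
(uA -> A) and 1e6 (mol/cm^3 -> mM) factors cancel exactly.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from typing import Optional, TextIO, Union

import numpy as np
import yaml

FARADAY = 96485.33  # C/mol
GAS_CONSTANT = 8.3145  # J/(mol K)

MS = 1.0e-3  # one millisecond in internal time units (s)


def thermal_voltage(T: float) -> float:
    """RT/F in mV (26.71 mV at 310 K)."""
    return 1.0e3 * GAS_CONSTANT * T / FARADAY


# ---------------------------------------------------------------------------
# parameter record
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """Complete, unit-consistent parameter set for the CSD model.

    Values not constrained by surviving anchors follow the Kager/Somjen/Yao
    modelling lineage; every one is an overridable field of this record, none
    is hard-coded in model logic.  See docs/methods.md for provenance notes.
    """

    # --- membrane / geometry ---
    C_m: float = 1.0            # uF/cm^2, membrane capacitance per area
    R_d: float = 0.05           # ohm cm^3, dendritic-tree input resistance per tissue volume
    L_d: float = 0.01           # cm, half-length of the effective dendritic tree
    A_s: float = 1800.0         # 1/cm, soma membrane area per tissue volume
    A_d: float = 8000.0         # 1/cm, dendrite membrane area per tissue volume
    W_s: float = 0.30           # -, soma volume fraction
    W_d: float = 0.40           # -, dendrite volume fraction
    W_e: float = 0.13           # -, ECS volume fraction
    W_glia: float = 0.17        # -, glial volume fraction (inert bookkeeping)

    # --- ECS diffusion (aqueous values reduced by tortuosity^2, lambda=1.6) ---
    D_Na: float = 5.2e-6        # cm^2/s
    D_K: float = 7.66e-6        # cm^2/s
    D_Cl: float = 7.93e-6       # cm^2/s

    # --- physical constants ---
    F: float = FARADAY          # C/mol
    T: float = 310.0            # K

    # --- maximal GHK permeabilities (cm/s) and leak conductances (mS/cm^2) ---
    P_NaP_s: float = 2.0e-6     # persistent Na, soma
    P_NaP_d: float = 2.0e-6     # persistent Na, dendrite
    P_KDR_s: float = 8.0e-6     # delayed-rectifier K, soma
    P_KDR_d: float = 8.0e-6     # delayed-rectifier K, dendrite
    P_KA_s: float = 2.0e-6      # A-type K, soma
    P_KA_d: float = 2.0e-6      # A-type K, dendrite
    P_NMDA: float = 9.0e-6      # NMDA (dendrite only; carries Na and K equally)
    Mg_e: float = 1.0           # mM, external magnesium for the NMDA block
    g_Cl_leak_s: float = 0.10   # mS/cm^2 (E_Cl = V_rest, so zero rest current)
    g_Cl_leak_d: float = 0.10
    # Na/K leak conductances are *derived* by the resting balance
    # (balance_leak_conductances); the defaults below are placeholders that
    # build_default_parameters overwrites.
    g_Na_leak_s: float = float("nan")
    g_Na_leak_d: float = float("nan")
    g_K_leak_s: float = float("nan")
    g_K_leak_d: float = float("nan")

    # --- Na+/K+-ATPase ---
    I_pump_max: float = 18.0    # uA/cm^2, maximal scalar pump rate per membrane
    K_mK: float = 2.0           # mM, ECS potassium half-saturation
    K_mNa: float = 7.7          # mM, ICS sodium half-saturation

    # --- oxygen / metabolism ---
    epsilon: float = 0.05       # -, oxygen-independent ATP fraction
    gamma: float = 0.5          # -, pump share of steady-state O2 consumption
    O2_0: float = 0.2           # mM, resting tissue oxygen
    O2_blood: float = 0.5       # mM, blood-side oxygen tension parameter
    k_O2: float = 0.03          # mM/s, blood->tissue transfer / consumption scale
    D_O2: float = 1.5e-5        # cm^2/s, tissue oxygen diffusivity
    K_O2half: float = 0.08      # mM, half-saturation of the pump oxygen factor

    # --- vascular response r([K+]e) ---
    a: float = 65.0             # mM, Gaussian constriction width
    b: float = 0.15             # -, maximal fractional dilation
    c: float = 3.0              # mM, dilation response width
    K_dil: float = 9.0          # mM, [K+]e of peak dilation

    # --- glial potassium buffer ---
    k1: float = 3.0e-3          # 1/(mM s), forward (uptake) rate
    k2: float = 2.0e-3          # 1/s, reverse (release) rate
    B_tot: float = 40.0        # mM (ECS-referenced), total buffer
    K_th: float = 15.0          # mM, buffering threshold
    buffer_slope: float = 1.0   # mM, steepness of the threshold sigmoid

    # --- soma-dendrite ion exchange ---
    chi_sd: float = 0.2         # 1/s

    # --- resting concentrations / potential ---
    Na_e0: float = 140.0        # mM
    K_e0: float = 3.5           # mM
    Cl_e0: float = 143.5        # mM, = Na_e0 + K_e0 (ECS electroneutrality)
    Na_i0: float = 10.0         # mM (soma and dendrite)
    K_i0: float = 133.5         # mM
    Cl_i0: float = float("nan") # mM, derived so E_Cl = V_rest
    V_rest: float = -70.0       # mV

    # ------------------------------------------------------------------
    @property
    def RTF(self) -> float:
        """RT/F in mV."""
        return thermal_voltage(self.T)

    @property
    def g_sd(self) -> float:
        """Soma-dendrite electrotonic coupling conductance, mS/cm^3 tissue.

        1/R_d with R_d in ohm cm^3 gives S/cm^3; expressed in mS/cm^3 so that
        g_sd*(V_other - V_self)/A is directly in uA/cm^2.
        """
        return 1.0e3 / self.R_d

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ValueError on any violated invariant."""
        positive = [
            "C_m", "R_d", "L_d", "A_s", "A_d", "W_s", "W_d", "W_e",
            "D_Na", "D_K", "D_Cl", "F", "T",
            "P_NaP_s", "P_NaP_d", "P_KDR_s", "P_KDR_d", "P_KA_s", "P_KA_d",
            "P_NMDA", "g_Cl_leak_s", "g_Cl_leak_d",
            "I_pump_max", "K_mK", "K_mNa",
            "O2_0", "O2_blood", "k_O2", "D_O2", "K_O2half",
            "a", "c", "K_dil", "k1", "k2", "B_tot", "K_th", "buffer_slope",
            "chi_sd", "Na_e0", "K_e0", "Cl_e0", "Na_i0", "K_i0",
        ]
        for name in positive:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name} must be strictly positive, got {v!r}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.b < 0.0:
            raise ValueError(f"b must be nonnegative, got {self.b}")
        if self.W_s + self.W_d + self.W_e + self.W_glia > 1.0 + 1e-12:
            raise ValueError("volume fractions W_s + W_d + W_e + W_glia exceed 1")
        if abs(self.Cl_e0 - (self.Na_e0 + self.K_e0)) > 1e-9:
            raise ValueError("ECS electroneutrality violated: Cl_e0 != Na_e0 + K_e0")
        if self.O2_blood <= self.O2_0:
            raise ValueError("O2_blood must exceed O2_0 (blood supplies the tissue)")
        if np.isfinite(self.Cl_i0):
            e_cl = -self.RTF * math.log(self.Cl_e0 / self.Cl_i0)
            if abs(e_cl - self.V_rest) > 0.1:
                raise ValueError(
                    f"resting chloride Nernst potential ({e_cl:.3f} mV) does not "
                    f"match V_rest ({self.V_rest} mV) within 0.1 mV"
                )

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **overrides) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)

    def dump_yaml(self, stream: Optional[TextIO] = None) -> Optional[str]:
        """Write the full parameter set as a flat key: value document."""
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=True)

    @classmethod
    def load_yaml(cls, source: Union[str, TextIO]) -> "ModelParameters":
        if isinstance(source, str):
            source = io.StringIO(source)
        return cls.from_dict(yaml.safe_load(source))


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

@dataclass
class RestingState:
    """Spatially uniform equilibrium of the full model.

    Gating variables sit at their voltage steady states, the free buffer at
    the value that zeroes the buffering flux, oxygen at O2_0, and the leak
    conductances in ``params`` are balanced so that every per-ion membrane
    flux vanishes; the full right-hand side evaluated here is zero to
    numerical round-off.
    """

    V_s: float
    V_d: float
    gating: dict            # name -> float, see membrane.GATE_NAMES
    Na_s: float
    K_s: float
    Cl_s: float
    Na_d: float
    K_d: float
    Cl_d: float
    Na_e: float
    K_e: float
    Cl_e: float
    B: float                # mM, free buffer
    O2: float               # mM
    r_rel: float            # -, vessel radius / resting radius (= 1)
    params: ModelParameters


def resting_chloride_i(params: ModelParameters) -> float:
    """ICS chloride that puts the Cl Nernst potential at V_rest."""
    # E_Cl = -RT/F ln(Cl_e/Cl_i) = V_rest  =>  Cl_i = Cl_e exp(V_rest * F/RT)
    return params.Cl_e0 * math.exp(params.V_rest / params.RTF)


def resting_free_buffer(params: ModelParameters) -> float:
    """Free buffer B0 that zeroes the buffering flux at [K+]e = K_e0."""
    from .tissue import buffer_gain  # local import to avoid a cycle

    g = buffer_gain(params.K_e0, params)
    return params.k2 * params.B_tot / (params.k2 + params.k1 * g * params.K_e0)


def balance_leak_conductances(params: ModelParameters) -> ModelParameters:
    """Return a copy with Na/K leak conductances that zero every resting flux.

    For each compartment and each of Na and K, the leak conductance absorbs
    whatever current the gated channels and the pump leave unbalanced at rest:
    ``g_leak = -(I_gated + I_pump) / (V_rest - E_ion)``.  Raises ValueError if
    the balance would require a negative conductance (inconsistent
    parameters, e.g. a pump too weak to oppose the channel influx).
    """
    from . import membrane as mb

    p = params.replace(Cl_i0=resting_chloride_i(params))
    V = p.V_rest
    g = mb.gating_steady_state(V, V)
    xi_na = mb.nernst_potential(p.Na_e0, p.Na_i0, +1, p.T)
    xi_k = mb.nernst_potential(p.K_e0, p.K_i0, +1, p.T)
    P0 = mb.pump_rate(p.K_e0, p.Na_i0, p)  # oxygen factor is 1 at O2_0

    updates = {}
    for comp in ("s", "d"):
        m, h = getattr(g, f"m_{comp}"), getattr(g, f"h_{comp}")
        n = getattr(g, f"n_{comp}")
        aa, bb = getattr(g, f"a_{comp}"), getattr(g, f"b_{comp}")
        I_nap = mb.ghk_current(V, +1, p.Na_i0, p.Na_e0,
                               getattr(p, f"P_NaP_{comp}") * m**2 * h, p.T)
        I_kdr = mb.ghk_current(V, +1, p.K_i0, p.K_e0,
                               getattr(p, f"P_KDR_{comp}") * n**2, p.T)
        I_ka = mb.ghk_current(V, +1, p.K_i0, p.K_e0,
                              getattr(p, f"P_KA_{comp}") * aa**2 * bb, p.T)
        I_nmda_na = I_nmda_k = 0.0
        if comp == "d":
            P_open = p.P_NMDA * g.s_d * mb.nmda_mg_block(V, p)
            I_nmda_na = mb.ghk_current(V, +1, p.Na_i0, p.Na_e0, P_open, p.T)
            I_nmda_k = mb.ghk_current(V, +1, p.K_i0, p.K_e0, P_open, p.T)
        g_na = -(I_nap + I_nmda_na + 3.0 * P0) / (V - xi_na)
        g_k = -(I_kdr + I_ka + I_nmda_k - 2.0 * P0) / (V - xi_k)
        if g_na <= 0 or g_k <= 0:
            raise ValueError(
                f"resting balance failed in compartment '{comp}': required leak "
                f"conductances g_Na={g_na:.4g}, g_K={g_k:.4g} mS/cm^2 are not positive"
            )
        updates[f"g_Na_leak_{comp}"] = g_na
        updates[f"g_K_leak_{comp}"] = g_k
    return p.replace(**updates)


def build_default_parameters(**overrides) -> ModelParameters:
    """Construct the default, validated, rest-balanced parameter set.

    Keyword overrides are applied before the derived quantities (ECS chloride,
    ICS chloride, leak conductances) are recomputed, so overriding e.g. K_e0
    keeps the set self-consistent.
    """
    p = ModelParameters(**overrides)
    if "Cl_e0" not in overrides:
        p = p.replace(Cl_e0=p.Na_e0 + p.K_e0)
    recompute_cl_i = "Cl_i0" not in overrides or not np.isfinite(p.Cl_i0)
    if recompute_cl_i:
        p = p.replace(Cl_i0=resting_chloride_i(p))
    rebalance = not all(
        np.isfinite(getattr(p, k)) for k in
        ("g_Na_leak_s", "g_Na_leak_d", "g_K_leak_s", "g_K_leak_d")
    ) or not any(k.startswith("g_") for k in overrides)
    if rebalance:
        p = balance_leak_conductances(p)
    p.validate()
    return p


def solve_resting_state(params: ModelParameters, rebalance: bool = True,
                        tol: float = 1e-8) -> RestingState:
    """Assemble the resting equilibrium and verify it is a fixed point.

    With ``rebalance`` (default) the leak conductances are recomputed from the
    resting balance first.  The returned state carries the (possibly updated)
    parameter set in ``.params``.  Raises RuntimeError if the max-norm of the
    full right-hand side at the assembled state exceeds ``tol`` (internal
    units), which signals an inconsistent parameter set.
    """
    from . import membrane as mb
    from . import tissue

    p = balance_leak_conductances(params) if rebalance else params
    g = mb.gating_steady_state(p.V_rest, p.V_rest)
    state = RestingState(
        V_s=p.V_rest, V_d=p.V_rest,
        gating={name: float(getattr(g, name)) for name in mb.GATE_NAMES},
        Na_s=p.Na_i0, K_s=p.K_i0, Cl_s=p.Cl_i0,
        Na_d=p.Na_i0, K_d=p.K_i0, Cl_d=p.Cl_i0,
        Na_e=p.Na_e0, K_e=p.K_e0, Cl_e=p.Cl_e0,
        B=resting_free_buffer(p), O2=p.O2_0, r_rel=1.0,
        params=p,
    )
    # verify on a tiny grid in the fully coupled regime
    grid = tissue.Grid1D(length=0.1, n_points=8)
    y0 = tissue.TissueState.from_resting(state, grid).to_vector()
    dy = tissue.assemble_rhs(0.0, y0, grid, p, regime="coupled")
    resid = float(np.max(np.abs(dy)))
    if resid > tol:
        raise RuntimeError(
            f"resting state is not a fixed point: max|dState/dt| = {resid:.3e} > {tol:g}"
        )
    return state
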
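"""Neuronal membrane biophysics at a single tissue point (vectorised over the grid).

Channel complement per the Kager/Somjen/Yao modelling lineage: persistent
(P-type) sodium, delayed-rectifier potassium and A-type potassium in both
compartments, NMDA (sodium and potassium, voltage-gated magnesium block) in
the dendrites only, ohmic leak currents for all three ions, and the
Na+/K+-ATPase with 3 Na out : 2 K in stoichiometry.  Gated channel currents
use the Goldman-Hodgkin-Katz (GHK) flux form, which stays well behaved under
the near-complete collapse of ionic gradients that CSD produces.  The fast,
inactivating (transient) sodium channel is deliberately omitted: it does not
materially shape the slow CSD currents.

Sign convention: outward current positive, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .parameters import FARADAY, ModelParameters, thermal_voltage

__all__ = [
    "nernst_potential", "ghk_current", "GatingState", "GATE_NAMES",
    "gating_steady_state", "gating_rhs", "nmda_mg_block",
    "pump_rate", "pump_current", "oxygen_pump_factor",
    "CompartmentCurrents", "membrane_currents", "membrane_potential_rhs",
]


def nernst_potential(conc_out, conc_in, valence: int, T: float):
    """Equilibrium (Nernst) potential in mV.

    ``(RT / zF) ln(c_out / c_in)``; concentrations in mM (any common unit),
    temperature in K.  Raises ValueError on non-positive concentrations or
    zero valence.
    """
    conc_out = np.asarray(conc_out, dtype=float)
    conc_in = np.asarray(conc_in, dtype=float)
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if np.any(conc_out <= 0) or np.any(conc_in <= 0):
        raise ValueError("Nernst potential requires strictly positive concentrations")
    out = thermal_voltage(T) / valence * np.log(conc_out / conc_in)
    return float(out) if out.ndim == 0 else out


def ghk_current(V, valence: int, conc_in, conc_out, P, T: float):
    """Goldman-Hodgkin-Katz current density, uA/cm^2, outward positive.

    ``I = P z F u (c_in - c_out e^{-u}) / (1 - e^{-u})`` with
    ``u = z V F / (R T)``; P in cm/s, concentrations in mM.  The u -> 0
    removable singularity is handled explicitly.  Reverses exactly at the
    Nernst potential.
    """
    V = np.asarray(V, dtype=float)
    u = valence * V / thermal_voltage(T)
    small = np.abs(u) < 1e-9
    u_safe = np.where(small, 1.0, u)
    frac = np.where(
        small,
        np.asarray(conc_in, dtype=float) - np.asarray(conc_out, dtype=float),
        u_safe * (conc_in - conc_out * np.exp(-u_safe)) / (-np.expm1(-u_safe)),
    )
    # with P in cm/s and c in mM the uA<->A and mol/cm^3<->mM factors cancel
    out = np.asarray(P * valence * FARADAY * frac)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------

GATE_NAMES = ("m_s", "h_s", "n_s", "a_s", "b_s",
              "m_d", "h_d", "n_d", "a_d", "b_d", "s_d")


@dataclass
class GatingState:
    """Channel gating variables, each in [0, 1], per compartment.

    m/h: persistent-Na activation/inactivation; n: delayed-rectifier K
    activation; a/b: A-type K activation/inactivation; s: slow NMDA
    activation (dendrite only).  Suffix _s soma, _d dendrite.
    """

    m_s: np.ndarray
    h_s: np.ndarray
    n_s: np.ndarray
    a_s: np.ndarray
    b_s: np.ndarray
    m_d: np.ndarray
    h_d: np.ndarray
    n_d: np.ndarray
    a_d: np.ndarray
    b_d: np.ndarray
    s_d: np.ndarray

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gate_curves(V):
    """Steady-state activation and time constant (in seconds) per gate family.

    Returns ``{name: (x_inf, tau_s)}`` for the six gate families evaluated at
    membrane potential V (mV).  Voltage dependences are sigmoidal relaxation
    kinetics in the Kager lineage; time constants are written in ms and
    converted here (the single ms->s conversion point).
    """
    V = np.asarray(V, dtype=float)
    ms = 1.0e-3
    curves = {
        # persistent Na: fast activation, slow partial inactivation
        "m": (_sigmoid((V + 40.0) / 6.0), 2.0 * ms),
        "h": (_sigmoid(-(V + 48.0) / 7.0),
              (200.0 + 3000.0 * _sigmoid(-(V + 40.0) / 8.0)) * ms),
        # delayed-rectifier K
        "n": (_sigmoid((V + 30.0) / 10.0), 3.0 * ms),
        # A-type K: fast transient
        "a": (_sigmoid((V + 50.0) / 15.0), 2.0 * ms),
        "b": (_sigmoid(-(V + 75.0) / 8.0), 20.0 * ms),
        # NMDA: slow voltage-driven activation (no glutamate dynamics)
        "s": (_sigmoid((V + 45.0) / 10.0), 500.0 * ms),
    }
    return curves


def gating_steady_state(V_s, V_d) -> GatingState:
    """GatingState with every variable at its voltage steady state."""
    cs = gate_curves(V_s)
    cd = gate_curves(V_d)
    return GatingState(
        m_s=cs["m"][0], h_s=cs["h"][0], n_s=cs["n"][0],
        a_s=cs["a"][0], b_s=cs["b"][0],
        m_d=cd["m"][0], h_d=cd["h"][0], n_d=cd["n"][0],
        a_d=cd["a"][0], b_d=cd["b"][0], s_d=cd["s"][0],
    )


def gating_rhs(gating: GatingState, V_s, V_d, params: ModelParameters) -> GatingState:
    """Relaxation kinetics dx/dt = (x_inf(V) - x)/tau_x(V), in 1/s.

    Trajectories started in [0, 1] remain there: the drift points toward
    x_inf which itself lies in [0, 1].
    """
    cs = gate_curves(V_s)
    cd = gate_curves(V_d)
    out = {}
    for fam, comp in (("m", "s"), ("h", "s"), ("n", "s"), ("a", "s"), ("b", "s"),
                      ("m", "d"), ("h", "d"), ("n", "d"), ("a", "d"), ("b", "d"),
                      ("s", "d")):
        inf, tau = (cs if comp == "s" else cd)[fam]
        x = getattr(gating, f"{fam}_{comp}")
        out[f"{fam}_{comp}"] = (inf - x) / tau
    return GatingState(**out)


def nmda_mg_block(V, params: ModelParameters):
    """Voltage-dependent magnesium unblock factor (Jahr-Stevens form), in (0, 1)."""
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + params.Mg_e / 3.57 * np.exp(-0.062 * V))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Na+/K+-ATPase
# ---------------------------------------------------------------------------

def pump_rate(K_e, Na_i, params: ModelParameters):
    """Scalar pump rate P (uA/cm^2) from substrate saturation alone.

    ``P = I_max (Na_i/(Na_i+K_mNa))^3 (K_e/(K_e+K_mK))^2`` -- two ECS
    potassium binding sites, three ICS sodium binding sites.  Oxygen
    limitation is applied separately (oxygen_pump_factor).
    """
    K_e = np.asarray(K_e, dtype=float)
    Na_i = np.asarray(Na_i, dtype=float)
    s_na = Na_i / (Na_i + params.K_mNa)
    s_k = K_e / (K_e + params.K_mK)
    out = params.I_pump_max * s_na**3 * s_k**2
    return float(out) if out.ndim == 0 else out


def pump_current(K_e, Na_i, params: ModelParameters):
    """(I_pumpNa, I_pumpK) in uA/cm^2: +3P outward Na, -2P inward K."""
    P = pump_rate(K_e, Na_i, params)
    return 3.0 * P, -2.0 * P


def oxygen_pump_factor(O2, params: ModelParameters):
    """Oxygen-dependent pump scaling, in [epsilon, (1-eps)(O2_0+K)/O2_0 + eps).

    Michaelis-Menten in tissue oxygen, affinely rescaled so that the factor is
    exactly epsilon (the oxygen-independent ATP share, ~5%) at zero oxygen and
    exactly 1 at the resting oxygen concentration O2_0.  Monotone
    nondecreasing; saturates above O2_0.
    """
    O2 = np.asarray(O2, dtype=float)
    if np.any(O2 < 0):
        raise ValueError("tissue oxygen concentration must be nonnegative")
    mm = O2 / (O2 + params.K_O2half)
    mm0 = params.O2_0 / (params.O2_0 + params.K_O2half)
    out = params.epsilon + (1.0 - params.epsilon) * mm / mm0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# assembled membrane currents
# ---------------------------------------------------------------------------

@dataclass
class CompartmentCurrents:
    """Per-ion membrane current densities (uA/cm^2, outward positive).

    Channel, leak and pump contributions are kept separate per compartment;
    ``pump_s``/``pump_d`` hold the scalar pump rate P (already oxygen-scaled),
    from which I_pumpNa = +3P and I_pumpK = -2P.
    """

    I_NaP_s: np.ndarray
    I_KDR_s: np.ndarray
    I_KA_s: np.ndarray
    I_Na_leak_s: np.ndarray
    I_K_leak_s: np.ndarray
    I_Cl_leak_s: np.ndarray
    pump_s: np.ndarray
    I_NaP_d: np.ndarray
    I_KDR_d: np.ndarray
    I_KA_d: np.ndarray
    I_NMDA_Na_d: np.ndarray
    I_NMDA_K_d: np.ndarray
    I_Na_leak_d: np.ndarray
    I_K_leak_d: np.ndarray
    I_Cl_leak_d: np.ndarray
    pump_d: np.ndarray

    # soma totals ------------------------------------------------------
    @property
    def I_Na_s(self):
        return self.I_NaP_s + self.I_Na_leak_s + 3.0 * self.pump_s

    @property
    def I_K_s(self):
        return self.I_KDR_s + self.I_KA_s + self.I_K_leak_s - 2.0 * self.pump_s

    @property
    def I_Cl_s(self):
        return self.I_Cl_leak_s

    @property
    def I_total_s(self):
        return self.I_Na_s + self.I_K_s + self.I_Cl_s

    # dendrite totals --------------------------------------------------
    @property
    def I_Na_d(self):
        return self.I_NaP_d + self.I_NMDA_Na_d + self.I_Na_leak_d + 3.0 * self.pump_d

    @property
    def I_K_d(self):
        return self.I_KDR_d + self.I_KA_d + self.I_NMDA_K_d + self.I_K_leak_d - 2.0 * self.pump_d

    @property
    def I_Cl_d(self):
        return self.I_Cl_leak_d

    @property
    def I_total_d(self):
        return self.I_Na_d + self.I_K_d + self.I_Cl_d


def _ghk_fast(u, den, P, c_in, c_out_emu):
    """GHK current with precomputed u, den = 1 - e^{-u}, and c_out * e^{-u}."""
    return P * FARADAY * u * (c_in - c_out_emu) / den


def membrane_currents(V_s, V_d, gating: GatingState, state,
                      O2, params: ModelParameters,
                      oxygen_clamped: bool = False) -> CompartmentCurrents:
    """All membrane currents for the given electro-chemical state.

    ``state`` provides ion concentrations as attributes (Na_s, ..., Cl_e);
    a TissueState or RestingState both qualify.  With ``oxygen_clamped`` the
    pump oxygen factor is pinned at 1 regardless of O2.
    """
    p = params
    rtf = thermal_voltage(p.T)
    V_s = np.asarray(V_s, dtype=float)
    V_d = np.asarray(V_d, dtype=float)
    Na_s = np.maximum(state.Na_s, 1e-9)
    K_s = np.maximum(state.K_s, 1e-9)
    Cl_s = np.maximum(state.Cl_s, 1e-9)
    Na_d = np.maximum(state.Na_d, 1e-9)
    K_d = np.maximum(state.K_d, 1e-9)
    Cl_d = np.maximum(state.Cl_d, 1e-9)
    Na_e = np.maximum(state.Na_e, 1e-9)
    K_e = np.maximum(state.K_e, 1e-9)
    Cl_e = np.maximum(state.Cl_e, 1e-9)

    # shared monovalent-cation GHK drive per compartment (u = V/(RT/F))
    def cation_drive(V):
        u = V / rtf
        u = np.where(np.abs(u) < 1e-9, 1e-9, u)
        emu = np.exp(-u)
        return u, 1.0 - emu, emu

    u_s, den_s, emu_s = cation_drive(V_s)
    u_d, den_d, emu_d = cation_drive(V_d)
    Na_e_emu_s, K_e_emu_s = Na_e * emu_s, K_e * emu_s
    Na_e_emu_d, K_e_emu_d = Na_e * emu_d, K_e * emu_d

    E_Na_s = rtf * np.log(Na_e / Na_s)
    E_K_s = rtf * np.log(K_e / K_s)
    E_Cl_s = -rtf * np.log(Cl_e / Cl_s)
    E_Na_d = rtf * np.log(Na_e / Na_d)
    E_K_d = rtf * np.log(K_e / K_d)
    E_Cl_d = -rtf * np.log(Cl_e / Cl_d)

    if oxygen_clamped:
        f_o2 = 1.0
    else:
        f_o2 = oxygen_pump_factor(np.maximum(O2, 0.0), p)

    s_k2 = (K_e / (K_e + p.K_mK)) ** 2
    P_s = f_o2 * p.I_pump_max * (Na_s / (Na_s + p.K_mNa)) ** 3 * s_k2
    P_d = f_o2 * p.I_pump_max * (Na_d / (Na_d + p.K_mNa)) ** 3 * s_k2

    P_nmda_open = p.P_NMDA * gating.s_d * nmda_mg_block(V_d, p)

    return CompartmentCurrents(
        I_NaP_s=_ghk_fast(u_s, den_s, p.P_NaP_s * gating.m_s**2 * gating.h_s,
                          Na_s, Na_e_emu_s),
        I_KDR_s=_ghk_fast(u_s, den_s, p.P_KDR_s * gating.n_s**2, K_s, K_e_emu_s),
        I_KA_s=_ghk_fast(u_s, den_s, p.P_KA_s * gating.a_s**2 * gating.b_s,
                         K_s, K_e_emu_s),
        I_Na_leak_s=p.g_Na_leak_s * (V_s - E_Na_s),
        I_K_leak_s=p.g_K_leak_s * (V_s - E_K_s),
        I_Cl_leak_s=p.g_Cl_leak_s * (V_s - E_Cl_s),
        pump_s=np.asarray(P_s),
        I_NaP_d=_ghk_fast(u_d, den_d, p.P_NaP_d * gating.m_d**2 * gating.h_d,
                          Na_d, Na_e_emu_d),
        I_KDR_d=_ghk_fast(u_d, den_d, p.P_KDR_d * gating.n_d**2, K_d, K_e_emu_d),
        I_KA_d=_ghk_fast(u_d, den_d, p.P_KA_d * gating.a_d**2 * gating.b_d,
                         K_d, K_e_emu_d),
        I_NMDA_Na_d=_ghk_fast(u_d, den_d, P_nmda_open, Na_d, Na_e_emu_d),
        I_NMDA_K_d=_ghk_fast(u_d, den_d, P_nmda_open, K_d, K_e_emu_d),
        I_Na_leak_d=p.g_Na_leak_d * (V_d - E_Na_d),
        I_K_leak_d=p.g_K_leak_d * (V_d - E_K_d),
        I_Cl_leak_d=p.g_Cl_leak_d * (V_d - E_Cl_d),
        pump_d=np.asarray(P_d),
    )


def membrane_potential_rhs(V_s, V_d, currents: CompartmentCurrents,
                           params: ModelParameters):
    """(dV_s/dt, dV_d/dt) in mV/s.

    ``C_m dV/dt = -I_total + I_coupling`` per unit membrane area.  The
    electrotonic soma-dendrite coupling current is ``g_sd (V_other -
    V_self) / A_self`` with g_sd = 1/R_d per tissue volume, so that after
    area weighting the coupling is equal and opposite:
    ``A_s I_couple_s + A_d I_couple_d = 0``.
    """
    p = params
    I_couple_s = p.g_sd * (np.asarray(V_d) - np.asarray(V_s)) / p.A_s
    I_couple_d = p.g_sd * (np.asarray(V_s) - np.asarray(V_d)) / p.A_d
    dV_s = 1.0e3 * (-currents.I_total_s + I_couple_s) / p.C_m
    dV_d = 1.0e3 * (-currents.I_total_d + I_couple_d) / p.C_m
    return dV_s, dV_d
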
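"""Spatial assembly: the full method-of-lines right-hand side on a 1-D grid.

Only ECS ions and tissue oxygen diffuse; intracellular compartments and the
glial buffer are local.  Boundaries are no-flux (reflecting), so total sodium,
chloride, and potassium (free plus glial-bound) are conserved exactly by the
spatial operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import membrane as mb
from .parameters import ModelParameters, RestingState
from .vasculature import cerebral_blood_flow, oxygen_source, response_from_params, vessel_radius

__all__ = [
    "Grid1D", "TissueState", "FIELDS", "REGIMES", "laplacian_noflux",
    "buffer_gain", "buffer_flux", "ecs_rhs", "ics_rhs", "assemble_rhs",
    "jacobian_sparsity",
]

REGIMES = ("oxygen_clamped", "vessel_clamped", "coupled")

#: state-vector layout: field-major, i.e. y[f * n_points : (f+1) * n_points]
#: holds field FIELDS[f] on the grid.  This groups each field contiguously,
#: giving the stiff solver a simple block sparsity pattern.
FIELDS = ("V_s", "V_d") + mb.GATE_NAMES + (
    "Na_s", "K_s", "Cl_s", "Na_d", "K_d", "Cl_d",
    "Na_e", "K_e", "Cl_e", "B", "O2",
)
_DIFFUSIVE = {"Na_e": "D_Na", "K_e": "D_K", "Cl_e": "D_Cl", "O2": "D_O2"}


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D grid with reflecting (no-flux) boundaries."""

    length: float       # cm
    n_points: int

    def __post_init__(self):
        if self.n_points < 8:
            raise ValueError("grid needs at least 8 points")
        if self.length <= 0:
            raise ValueError("domain length must be positive")

    @property
    def dx(self) -> float:
        return self.length / (self.n_points - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_points)


@dataclass
class TissueState:
    """Full dynamical state on the grid; one array of length n_points per field."""

    arrays: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.__dict__["arrays"][name]
        except KeyError:
            raise AttributeError(name)

    @classmethod
    def from_resting(cls, rest: RestingState, grid: Grid1D) -> "TissueState":
        n = grid.n_points
        vals = {"V_s": rest.V_s, "V_d": rest.V_d, **rest.gating,
                "Na_s": rest.Na_s, "K_s": rest.K_s, "Cl_s": rest.Cl_s,
                "Na_d": rest.Na_d, "K_d": rest.K_d, "Cl_d": rest.Cl_d,
                "Na_e": rest.Na_e, "K_e": rest.K_e, "Cl_e": rest.Cl_e,
                "B": rest.B, "O2": rest.O2}
        return cls({f: np.full(n, float(vals[f])) for f in FIELDS})

    @classmethod
    def from_vector(cls, y: np.ndarray, grid: Grid1D) -> "TissueState":
        n = grid.n_points
        if y.size != n * len(FIELDS):
            raise ValueError(
                f"state vector length {y.size} != {len(FIELDS)} fields x {n} points")
        return cls({f: y[i * n:(i + 1) * n] for i, f in enumerate(FIELDS)})

    def to_vector(self) -> np.ndarray:
        return np.concatenate([np.asarray(self.arrays[f], dtype=float) for f in FIELDS])

    def copy(self) -> "TissueState":
        return TissueState({f: np.array(v, dtype=float) for f, v in self.arrays.items()})

    def gating(self) -> mb.GatingState:
        return mb.GatingState(**{g: self.arrays[g] for g in mb.GATE_NAMES})

    def validate(self, params: ModelParameters) -> None:
        for f in FIELDS[13:]:
            if np.any(np.asarray(self.arrays[f]) < -1e-9):
                raise ValueError(f"negative concentration in field {f}")
        if np.any(self.arrays["B"] > params.B_tot + 1e-9):
            raise ValueError("free buffer exceeds B_tot")


# ---------------------------------------------------------------------------
# spatial operator
# ---------------------------------------------------------------------------

def laplacian_noflux(f, dx: float) -> np.ndarray:
    """Conservative second difference with zero-flux boundaries.

    Interior: standard central stencil.  Boundaries: one-sided flux form
    (interface flux zero at the domain ends), so the output sums to zero to
    machine precision for any input.
    """
    f = np.asarray(f, dtype=float)
    if f.size < 3:
        raise ValueError("laplacian needs at least 3 points")
    out = np.empty_like(f)
    out[1:-1] = f[:-2] - 2.0 * f[1:-1] + f[2:]
    out[0] = f[1] - f[0]
    out[-1] = f[-2] - f[-1]
    return out / dx**2


# ---------------------------------------------------------------------------
# glial buffer
# ---------------------------------------------------------------------------

def buffer_gain(K_e, params: ModelParameters):
    """Threshold sigmoid on the uptake rate, centred at K_th."""
    K_e = np.asarray(K_e, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(K_e - params.K_th) / params.buffer_slope))
    return float(out) if out.ndim == 0 else out


def buffer_flux(K_e, B, params: ModelParameters):
    """(v_buffer, dB/dt) in mM/s.

    ``v_buffer`` is potassium removed from the ECS: uptake
    ``k1 g(K_e) K_e B`` minus release ``k2 (B_tot - B)`` from the bound pool.
    One K bound consumes one unit of free buffer, so dB/dt = -v_buffer.
    Zero net flux at (K_rest, B0) by construction of B0.
    """
    K_e = np.asarray(K_e, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(B < -1e-9) or np.any(B > params.B_tot + 1e-9):
        raise ValueError("free buffer outside [0, B_tot]")
    uptake = params.k1 * buffer_gain(K_e, params) * K_e * B
    release = params.k2 * (params.B_tot - B)
    v = uptake - release
    if v.ndim == 0:
        return float(v), float(-v)
    return v, -v


# ---------------------------------------------------------------------------
# compartment balances
# ---------------------------------------------------------------------------

def ecs_rhs(state: TissueState, currents: mb.CompartmentCurrents, v_buffer,
            grid: Grid1D, params: ModelParameters) -> dict:
    """d[ion]e/dt (mM/s): diffusion + membrane source + K buffering.

    ``d[ion]e/dt = D* lap([ion]e) + (A_s I_s + A_d I_d)/(z F W_e)``; an
    outward cation current raises, an outward anion (Cl) current lowers, the
    ECS concentration.
    """
    p = params
    scale = 1.0 / (p.F * p.W_e)
    return {
        "Na_e": p.D_Na * laplacian_noflux(state.Na_e, grid.dx)
        + (p.A_s * currents.I_Na_s + p.A_d * currents.I_Na_d) * scale,
        "K_e": p.D_K * laplacian_noflux(state.K_e, grid.dx)
        + (p.A_s * currents.I_K_s + p.A_d * currents.I_K_d) * scale
        - v_buffer,
        "Cl_e": p.D_Cl * laplacian_noflux(state.Cl_e, grid.dx)
        - (p.A_s * currents.I_Cl_s + p.A_d * currents.I_Cl_d) * scale,
    }


def ics_rhs(state: TissueState, currents: mb.CompartmentCurrents,
            params: ModelParameters) -> dict:
    """d[ion]i/dt (mM/s) for soma and dendrite: membrane flux + exchange.

    Membrane term ``-A I/(z F W)`` per compartment; soma-dendrite exchange is
    a flux proportional to the concentration difference, volume-weighted so
    that ``W_s (exchange into soma) + W_d (exchange into dendrite) = 0``
    (mole conservation).  No ICS spatial diffusion.
    """
    p = params
    w_sum = p.W_s + p.W_d
    out = {}
    for ion, z in (("Na", +1), ("K", +1), ("Cl", -1)):
        c_s = getattr(state, f"{ion}_s")
        c_d = getattr(state, f"{ion}_d")
        ex_s = p.chi_sd * (c_d - c_s) * (p.W_d / w_sum)
        ex_d = p.chi_sd * (c_s - c_d) * (p.W_s / w_sum)
        out[f"{ion}_s"] = -p.A_s * getattr(currents, f"I_{ion}_s") / (z * p.F * p.W_s) + ex_s
        out[f"{ion}_d"] = -p.A_d * getattr(currents, f"I_{ion}_d") / (z * p.F * p.W_d) + ex_d
    return out


# ---------------------------------------------------------------------------
# full right-hand side
# ---------------------------------------------------------------------------

def assemble_rhs(t: float, y: np.ndarray, grid: Grid1D, params: ModelParameters,
                 regime: str) -> np.ndarray:
    """Time derivative of the flattened state vector under the given regime.

    oxygen_clamped: O2 pinned at its initial (resting) value, pump oxygen
    factor pinned at 1, vessel radius frozen at 1 (the in-vitro, unlimited
    oxygen view).  vessel_clamped: radius frozen at 1 but oxygen dynamic and
    coupled to the pump through gamma.  coupled: radius follows [K+]e and
    blood flow follows the radius.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    p = params
    state = TissueState.from_vector(np.asarray(y, dtype=float), grid)

    gate_arrays = {g: np.clip(state.arrays[g], 0.0, 1.0) for g in mb.GATE_NAMES}
    gating = mb.GatingState(**gate_arrays)
    O2 = np.maximum(state.O2, 0.0)
    oxygen_clamped = regime == "oxygen_clamped"

    cur = mb.membrane_currents(state.V_s, state.V_d, gating, state, O2, p,
                               oxygen_clamped=oxygen_clamped)
    dV_s, dV_d = mb.membrane_potential_rhs(state.V_s, state.V_d, cur, p)
    dgate = mb.gating_rhs(gating, state.V_s, state.V_d, p)

    B = np.clip(state.B, 0.0, p.B_tot)
    v_buf, dB = buffer_flux(np.maximum(state.K_e, 0.0), B, p)

    d_ecs = ecs_rhs(state, cur, v_buf, grid, p)
    d_ics = ics_rhs(state, cur, p)

    n = grid.n_points
    if oxygen_clamped:
        dO2 = np.zeros(n)
    else:
        if regime == "coupled":
            r_rel = vessel_radius(np.maximum(state.K_e, 0.0), response_from_params(p))
            cbf = cerebral_blood_flow(r_rel)
        else:
            cbf = 1.0
        P_ref = mb.pump_rate(p.K_e0, p.Na_i0, p)
        pump_rel = (p.A_s * cur.pump_s + p.A_d * cur.pump_d) / ((p.A_s + p.A_d) * P_ref)
        dO2 = p.D_O2 * laplacian_noflux(state.O2, grid.dx) + oxygen_source(
            O2, cbf, pump_rel, p)

    deriv = {"V_s": dV_s, "V_d": dV_d, **dgate.as_dict(), **d_ics, **d_ecs,
             "B": dB, "O2": dO2}
    out = np.empty(len(FIELDS) * n)
    for i, f in enumerate(FIELDS):
        out[i * n:(i + 1) * n] = deriv[f]
    return out


#: which state fields each field's time derivative actually depends on
#: (at the same grid point; diffusive fields additionally see their own
#: neighbours).  Used to build a tight Jacobian sparsity pattern.
_GATES_S = ("m_s", "h_s", "n_s", "a_s", "b_s")
_GATES_D = ("m_d", "h_d", "n_d", "a_d", "b_d", "s_d")
_ECS = ("Na_e", "K_e", "Cl_e")
_DEPS = {
    "V_s": ("V_s", "V_d") + _GATES_S + ("Na_s", "K_s", "Cl_s") + _ECS + ("O2",),
    "V_d": ("V_s", "V_d") + _GATES_D + ("Na_d", "K_d", "Cl_d") + _ECS + ("O2",),
    **{g: ("V_s", g) for g in _GATES_S},
    **{g: ("V_d", g) for g in _GATES_D},
    "Na_s": ("V_s", "m_s", "h_s", "Na_s", "Na_d", "Na_e", "K_e", "O2"),
    "K_s": ("V_s", "n_s", "a_s", "b_s", "Na_s", "K_s", "K_d", "K_e", "O2"),
    "Cl_s": ("V_s", "Cl_s", "Cl_d", "Cl_e"),
    "Na_d": ("V_d", "m_d", "h_d", "s_d", "Na_d", "Na_s", "Na_e", "K_e", "O2"),
    "K_d": ("V_d", "n_d", "a_d", "b_d", "s_d", "Na_d", "K_d", "K_s", "K_e", "O2"),
    "Cl_d": ("V_d", "Cl_d", "Cl_s", "Cl_e"),
    "Na_e": ("V_s", "V_d", "m_s", "h_s", "m_d", "h_d", "s_d",
             "Na_s", "Na_d", "Na_e", "K_e", "O2"),
    "K_e": ("V_s", "V_d", "n_s", "a_s", "b_s", "n_d", "a_d", "b_d", "s_d",
            "Na_s", "Na_d", "K_s", "K_d", "K_e", "B", "O2"),
    "Cl_e": ("V_s", "V_d", "Cl_s", "Cl_d", "Cl_e"),
    "B": ("K_e", "B"),
    "O2": ("Na_s", "Na_d", "K_e", "O2"),
}


def jacobian_sparsity(grid: Grid1D) -> sp.csr_matrix:
    """Sparsity pattern of the RHS Jacobian for the stiff solver.

    Fields couple locally according to the model's actual dependency graph;
    diffusive fields additionally couple to the same field at neighbouring
    points.  A tight pattern keeps the cost of the coloured finite-difference
    Jacobian low.
    """
    n = grid.n_points
    diag = sp.identity(n, format="coo")
    neighbour = sp.diags([np.ones(n - 1), np.ones(n - 1)], offsets=[-1, 1]).tocoo()
    idx = {f: i for i, f in enumerate(FIELDS)}
    blocks = [[None] * len(FIELDS) for _ in FIELDS]
    for f, deps in _DEPS.items():
        for d in deps:
            blocks[idx[f]][idx[d]] = diag
    for f in _DIFFUSIVE:
        blocks[idx[f]][idx[f]] = (diag + neighbour).tocoo()
    return sp.bmat(blocks, format="csr")
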
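"""Neurovascular limb: vessel radius vs extracellular potassium, Poiseuille
blood flow, and the tissue oxygen source/sink balance.

Extracellular potassium acts directly on vascular smooth muscle: moderate
elevations (below roughly 15-20 mM) dilate cerebral arterioles, large
elevations constrict them.  The effective radius response is an empirical
product of one dilating and one constricting term, normalised to 1 at resting
potassium; blood flow follows the Poiseuille fourth-power law in the radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .parameters import ModelParameters

__all__ = [
    "VascularResponse", "vessel_radius", "cerebral_blood_flow", "oxygen_source",
    "calibrate_vascular_response", "farr_david_target", "response_from_params",
]


@dataclass
class VascularResponse:
    """Parameters of the effective-radius response r([K+]e)/r0.

    constriction: Gaussian fall-off of width ``a`` (mM) above resting
    potassium -- at [K+]e - K_rest = a the constricting term alone is e^-1,
    i.e. ~63% constriction.  dilation: Gaussian bump of height ``b`` and
    width ``c`` centred at ``K_dil``.  The product is renormalised to equal
    exactly 1 at ``K_rest``.
    """

    a: float            # mM, constriction width
    b: float            # -, maximal fractional dilation
    c: float            # mM, dilation width
    K_dil: float        # mM, dilation-peak potassium
    K_rest: float = 3.5  # mM, resting potassium (normalisation point)

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0 or self.b < 0 or self.K_rest <= 0:
            raise ValueError("vascular response requires a, c, K_rest > 0 and b >= 0")
        self.r_rest = float(self._raw(self.K_rest))

    def _raw(self, K):
        K = np.asarray(K, dtype=float)
        constrict = np.where(
            K > self.K_rest,
            np.exp(-(((K - self.K_rest) / self.a) ** 2)),
            1.0,
        )
        dilate = 1.0 + self.b * np.exp(-(((K - self.K_dil) / self.c) ** 2))
        return constrict * dilate


def response_from_params(params: ModelParameters) -> VascularResponse:
    return VascularResponse(a=params.a, b=params.b, c=params.c,
                            K_dil=params.K_dil, K_rest=params.K_e0)


def vessel_radius(K_e, resp: VascularResponse):
    """Relative effective vessel radius r/r0 at ECS potassium K_e (mM).

    Exactly 1 at K_rest; above 1 over a band of moderate elevation (dilation);
    falling toward strong constriction at high potassium.  Strictly positive
    for all K_e >= 0.
    """
    K_e = np.asarray(K_e, dtype=float)
    if np.any(K_e < 0):
        raise ValueError("extracellular potassium concentration must be nonnegative")
    out = resp._raw(K_e) / resp.r_rest
    return float(out) if out.ndim == 0 else out


def cerebral_blood_flow(r_rel):
    """Relative cerebral blood flow CBF/CBF0 = (r/r0)^4 (Poiseuille)."""
    r_rel = np.asarray(r_rel, dtype=float)
    if np.any(r_rel <= 0):
        raise ValueError("relative vessel radius must be strictly positive")
    out = r_rel**4
    return float(out) if out.ndim == 0 else out


def oxygen_source(O2, cbf_rel, pump_rate_rel, params: ModelParameters):
    """Net tissue-oxygen source term (mM/s), excluding diffusion.

    supply: ``k_O2 * cbf_rel * (O2_blood - O2)/(O2_blood - O2_0)`` -- blood
    flow times the normalised blood-tissue oxygen difference.
    consumption: ``k_O2 * alpha(O2) * ((1 - gamma) + gamma * pump_rate_rel)``
    -- the steady non-pump share plus the pump share scaled by the
    instantaneous pump rate relative to its steady-state value (consumption
    beyond steady state appears as gamma * (pump_rate_rel - 1)).  The
    Michaelis availability factor ``alpha(O2) = MM(O2)/MM(O2_0)`` (the same
    saturation as the pump oxygen factor, normalised to 1 at rest) shuts
    consumption off as the substrate vanishes, so tissue oxygen cannot be
    driven negative.  Exactly zero at (O2_0, 1, 1).
    """
    O2 = np.asarray(O2, dtype=float)
    if np.any(O2 < 0):
        raise ValueError("tissue oxygen must be nonnegative")
    if np.any(np.asarray(cbf_rel) < 0) or np.any(np.asarray(pump_rate_rel) < 0):
        raise ValueError("cbf_rel and pump_rate_rel must be nonnegative")
    p = params
    supply = p.k_O2 * np.asarray(cbf_rel) * (p.O2_blood - O2) / (p.O2_blood - p.O2_0)
    alpha = (O2 / (O2 + p.K_O2half)) * (p.O2_0 + p.K_O2half) / p.O2_0
    consume = p.k_O2 * alpha * ((1.0 - p.gamma) + p.gamma * np.asarray(pump_rate_rel))
    out = supply - consume
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

#: Synthetic stand-in for the digitised arteriolar radius vs [K+]e relation
#: of the Farr-David vascular smooth muscle model: rest radius at 3.5 mM,
#: mild (~15%) dilation peaking near 9 mM (narrow, so the bump vanishes
#: at rest), dilation/constriction crossover near 14 mM, and progressive constriction beyond (63%
#: constriction where [K+]e - K_rest equals the Gaussian width of 65 mM,
#: anchored so the curve reads ~40% of rest radius at CSD-peak potassium).  Columns: K_e (mM), r/r0 (dimensionless).
FARR_DAVID_SHAPE = np.array([
    (3.5, 1.000), (5.0, 1.020), (6.5, 1.067),
    (8.0, 1.123), (10.0, 1.117), (12.0, 1.032),
    (15.0, 0.967), (20.0, 0.933), (25.0, 0.892),
    (30.0, 0.842), (35.0, 0.787), (40.0, 0.726),
    (45.0, 0.662), (50.0, 0.596), (60.0, 0.467),
    (70.0, 0.349), (80.0, 0.249),
])


def farr_david_target() -> np.ndarray:
    """Copy of the built-in synthetic Farr-David-shaped target curve."""
    return FARR_DAVID_SHAPE.copy()


def calibrate_vascular_response(target, K_rest: float = 3.5,
                                x0=(45.0, 0.2, 5.0, 8.5)) -> VascularResponse:
    """Least-squares fit of (a, b, c, K_dil) to target (K_e, r_rel) points.

    ``target`` is an (n, 2) array-like with n >= 4 points that should span
    rest, the dilation peak, the crossover, and the strong-constriction
    region.  The normalisation r(K_rest) = 1 is enforced by construction of
    the response, so the fit is over the remaining shape.  Deterministic for
    fixed target and initial guess ``x0``.
    """
    target = np.asarray(target, dtype=float)
    if target.ndim != 2 or target.shape[1] != 2 or target.shape[0] < 4:
        raise ValueError("calibration needs at least 4 (K_e, r_rel) target points")

    def residual(x):
        resp = VascularResponse(a=x[0], b=x[1], c=x[2], K_dil=x[3], K_rest=K_rest)
        return vessel_radius(target[:, 0], resp) - target[:, 1]

    fit = least_squares(
        residual, x0=np.asarray(x0, dtype=float),
        bounds=([1.0, 0.0, 0.5, K_rest], [300.0, 2.0, 50.0, 30.0]),
    )
    if not fit.success:
        raise RuntimeError(f"vascular calibration failed: {fit.message}")
    resp = VascularResponse(a=fit.x[0], b=fit.x[1], c=fit.x[2], K_dil=fit.x[3],
                            K_rest=K_rest)
    resp.fit_residual = float(np.sqrt(np.mean(fit.fun**2)))
    return resp
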
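"""Carotid arterial stiffness metrics from diameters and pressures.

Five standard indices are computed from the systolic/diastolic lumen
diameters (D_s, D_d, mm) and brachial pressures (P_s, P_d, mmHg):

* relative diameter change   RDC = (D_s - D_d) / D_d * 100          [%]
* stiffness index            beta = ln(P_s / P_d) / ((D_s - D_d)/D_d)
* arterial compliance        AC = pi (D_s^2 - D_d^2) / (4 (P_s - P_d))  [mm^2/kPa]
* local pulse wave velocity  PWV = sqrt(beta * P_s / (2 rho))       [m/s]
* pressure-strain modulus    E = (P_s - P_d) / ((D_s - D_d)/D_d)    [kPa]

beta uses the raw pressure ratio (unit-free); AC and E convert the pulse
pressure to kPa and PWV converts P_s to Pa (1 mmHg = 133.322 Pa).  Blood
density defaults to 1050 kg/m^3 (body temperature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import PressurePair

__all__ = ["MMHG_TO_PA", "StiffnessPanel", "stiffness_panel", "average_sides"]

MMHG_TO_PA = 133.322
MMHG_TO_KPA = MMHG_TO_PA / 1000.0
RHO_BLOOD = 1050.0  # kg/m^3


@dataclass
class StiffnessPanel:
    """The five stiffness-related metrics for one vessel (or side average)."""

    rdc: float  # %
    beta: float  # dimensionless
    ac: float  # mm^2/kPa
    pwv: float  # m/s
    e_mod: float  # kPa
    side: str  # "LC", "RC" or "average"
    pressures: PressurePair
    rho: float = RHO_BLOOD

    def as_dict(self) -> dict:
        return {
            "rdc_percent": self.rdc,
            "beta": self.beta,
            "ac_mm2_per_kpa": self.ac,
            "pwv_m_per_s": self.pwv,
            "e_kpa": self.e_mod,
        }


def stiffness_panel(
    d_s: float,
    d_d: float,
    pressures: PressurePair,
    rho: float = RHO_BLOOD,
    side: str = "",
) -> StiffnessPanel:
    """Evaluate all five metrics for one vessel.

    Raises
    ------
    ValueError
        If ``d_s == d_d`` (zero strain: beta and E are undefined) or the
        diameters/pressures are inconsistent.
    """
    if not d_s >= d_d > 0:
        raise ValueError("require d_s >= d_d > 0")
    p_s, p_d = pressures.p_s, pressures.p_d
    strain = (d_s - d_d) / d_d
    if strain == 0:
        raise ValueError(
            "zero diameter change: stiffness index and elastic modulus are undefined"
        )
    pulse_kpa = (p_s - p_d) * MMHG_TO_KPA
    beta = float(np.log(p_s / p_d) / strain)
    ac = float(np.pi * (d_s**2 - d_d**2) / (4.0 * pulse_kpa))
    pwv = float(np.sqrt(beta * p_s * MMHG_TO_PA / (2.0 * rho)))
    e_mod = float(pulse_kpa / strain)
    return StiffnessPanel(
        rdc=float(strain * 100.0),
        beta=beta,
        ac=ac,
        pwv=pwv,
        e_mod=e_mod,
        side=side,
        pressures=pressures,
        rho=rho,
    )


def average_sides(left: StiffnessPanel, right: StiffnessPanel) -> StiffnessPanel:
    """Metric-level arithmetic mean of the left and right carotid panels."""
    if (left.pressures.p_s, left.pressures.p_d) != (right.pressures.p_s, right.pressures.p_d):
        raise ValueError("panels were computed with different pressures")
    if left.rho != right.rho:
        raise ValueError("panels were computed with different blood densities")
    return StiffnessPanel(
        rdc=0.5 * (left.rdc + right.rdc),
        beta=0.5 * (left.beta + right.beta),
        ac=0.5 * (left.ac + right.ac),
        pwv=0.5 * (left.pwv + right.pwv),
        e_mod=0.5 * (left.e_mod + right.e_mod),
        side="average",
        pressures=left.pressures,
        rho=left.rho,
    )
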
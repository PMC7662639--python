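"""Unit conversions used across the package.

Internal conventions are fixed: concentrations in uM (= nmol/mL), volumes in
mL, times in minutes, membrane permeabilities in cm/s, water flux in
uL/cm/h.  Every conversion between these and the working quantities of the
simulator/estimators (volumetric loss rate q in mL/min, solute clearance in
mL/min, first-order rate in 1/min) lives here so no factor is duplicated.
"""

from __future__ import annotations

S_PER_MIN = 60.0
MIN_PER_H = 60.0
UL_PER_ML = 1000.0


def jwater_to_volume_rate(jwater_uL_per_cm_per_h: float, length_cm: float) -> float:
    """Net water absorption rate q (mL/min) for a segment of given length.

    Jwater is expressed per cm of intestine per hour; the whole-segment
    volumetric loss is Jwater * L.
    """
    return jwater_uL_per_cm_per_h * length_cm / UL_PER_ML / MIN_PER_H


def volume_rate_to_jwater(q_mL_per_min: float, length_cm: float) -> float:
    """Inverse of :func:`jwater_to_volume_rate`."""
    return q_mL_per_min / length_cm * UL_PER_ML * MIN_PER_H


def permeability_to_clearance(p_cm_per_s: float, area_cm2: float) -> float:
    """Membrane clearance P*A in mL/min (1 cm^3 == 1 mL)."""
    return p_cm_per_s * area_cm2 * S_PER_MIN


def ka_per_min_to_per_s(ka_per_min: float) -> float:
    return ka_per_min / S_PER_MIN


def peff_to_ka_per_min(peff_cm_per_s: float, radius_cm: float) -> float:
    """First-order luminal disappearance rate implied by an effective
    permeability through the cylindrical-lumen relation Peff = ka*R/2."""
    return 2.0 * peff_cm_per_s / radius_cm * S_PER_MIN


def slope_mL_per_min_to_jwater(slope: float, length_cm: float) -> float:
    """OLS slope of cumulative volume loss (mL/min) -> Jwater (uL/cm/h)."""
    return slope / length_cm * UL_PER_ML * MIN_PER_H
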
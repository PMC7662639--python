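"""Everted-gut-sac (EGS) estimators.

The sac is sampled with replacement: every interval an aliquot of receiver
fluid is withdrawn and replaced by blank buffer, so the measured receiver
concentration under-reports the cumulative transfer.  The cumulative-amount
reconstruction

    Q_n = C_n * V + s * sum_{i=1}^{n-1} C_i

adds back the solute carried away in every earlier aliquot (V sac volume, s
sample volume).  The apparent permeability follows from the flux,
Papp = (dQ/dt) / (A * C0), with dQ/dt the OLS slope of Q against time and
A = 2*pi*R*L the sac surface; the cumulative absorption percentage is
W = Q_n / (V_ref * C0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .models import SegmentGeometry
from . import units


@dataclass(frozen=True)
class EGSTimeSeries:
    """Measured receiver concentrations from one everted-gut-sac run."""

    times_min: np.ndarray
    receiver_concentrations_uM: np.ndarray
    sac_volume_mL: float
    sample_volume_mL: float
    donor_concentration_uM: float
    geometry: SegmentGeometry

    def __post_init__(self) -> None:
        times = np.asarray(self.times_min, dtype=float)
        conc = np.asarray(self.receiver_concentrations_uM, dtype=float)
        object.__setattr__(self, "times_min", times)
        object.__setattr__(self, "receiver_concentrations_uM", conc)
        if len(times) != len(conc):
            raise ValueError("times and receiver concentrations must align")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("receiver concentrations must be non-negative")
        if self.sac_volume_mL <= 0 or self.donor_concentration_uM <= 0:
            raise ValueError("sac volume and donor concentration must be positive")
        if not 0 <= self.sample_volume_mL < self.sac_volume_mL:
            raise ValueError("sample volume must lie in [0, sac volume)")


@dataclass(frozen=True)
class EGSResult:
    cumulative_amounts_nmol: np.ndarray
    flux_nmol_per_min: float
    r_squared: float
    papp_cm_per_s: float
    cumulative_fraction_percent: float | None = None


def cumulative_amounts(series: EGSTimeSeries) -> np.ndarray:
    """Sampling-replacement-corrected cumulative permeated amounts Q_1..Q_n
    (nmol; uM * mL)."""
    conc = series.receiver_concentrations_uM
    withdrawn_before = np.concatenate(([0.0], np.cumsum(conc[:-1])))
    return conc * series.sac_volume_mL + series.sample_volume_mL * withdrawn_before


def apparent_permeability(
    series: EGSTimeSeries,
    fit_window: tuple[float, float] | None = None,
    reference_volume_mL: float | None = None,
) -> EGSResult:
    """Apparent permeability Papp = (dQ/dt) / (A * C0) in cm/s.

    dQ/dt is the OLS slope of the corrected cumulative amounts over the fit
    window (default: all samples).  If ``reference_volume_mL`` is given the
    cumulative absorption percentage W is attached (see
    :func:`cumulative_fraction`).
    """
    q = cumulative_amounts(series)
    t = series.times_min
    if fit_window is not None:
        lo, hi = fit_window
        keep = (t >= lo) & (t <= hi)
        t, q_fit = t[keep], q[keep]
    else:
        q_fit = q
    if len(t) < 3:
        raise ValueError("apparent_permeability requires at least 3 time points")
    area = series.geometry.surface_area_cm2
    if area <= 0 or series.donor_concentration_uM <= 0:
        raise ValueError("surface area and donor concentration must be positive")
    fit = stats.linregress(t, q_fit)
    # slope nmol/min over (cm^2 * nmol/mL) -> cm/min -> cm/s
    papp = fit.slope / (area * series.donor_concentration_uM) / units.S_PER_MIN
    fraction = (
        cumulative_fraction(series, reference_volume_mL=reference_volume_mL)
        if reference_volume_mL is not None
        else None
    )
    return EGSResult(
        cumulative_amounts_nmol=q,
        flux_nmol_per_min=fit.slope,
        r_squared=fit.rvalue**2,
        papp_cm_per_s=papp,
        cumulative_fraction_percent=fraction,
    )


def cumulative_fraction(
    series: EGSTimeSeries,
    reference_volume_mL: float | None = None,
    mode: Literal["donor", "literal"] = "donor",
) -> float:
    """Cumulative absorption percentage W = Q_n / (V_ref * C0) * 100.

    ``mode='donor'`` (default) references the donor-chamber amount, which is
    what an absorption percentage semantically means; ``reference_volume_mL``
    must then be supplied.  ``mode='literal'`` uses the sac volume V as the
    denominator.
    """
    if mode == "literal":
        ref = series.sac_volume_mL
    else:
        if reference_volume_mL is None:
            raise ValueError("mode='donor' requires reference_volume_mL")
        ref = reference_volume_mL
    if ref <= 0:
        raise ValueError("reference volume must be positive")
    q_n = float(cumulative_amounts(series)[-1])
    return q_n / (ref * series.donor_concentration_uM) * 100.0
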
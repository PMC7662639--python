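"""Recirculation-perfusion analysis chain.

From the measured concentrations of a co-perfused volume marker and a model
drug this module reconstructs the perfusate volume over time, corrects the
drug concentration for water absorption, fits the first-order luminal
disappearance rate ka, and converts it to an effective permeability
(Peff = ka*R/2 for a cylindrical lumen) and a regression-based water flux
Jwater.

The volume reconstruction ships in two variants.  The ``recursive`` default
conserves the assumed marker amount across every withdrawal/replacement:

    V_t = ((V_{t-1} - s) * C'_{t-1} + s * c_rep) / C'_t

with s the sample volume and c_rep the marker concentration of the
replacement aliquot.  The ``literal`` variant reuses V_0 in place of
V_{t-1} at every step; it double-counts earlier withdrawals from the second
sample on and is retained for comparison only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .models import SegmentGeometry
from . import units

logger = logging.getLogger(__name__)

Variant = Literal["literal", "recursive"]
AssumedReplacement = Literal["marker_stock", "blank", "none"]


@dataclass(frozen=True)
class PerfusionTimeSeries:
    """Measured concentrations from one recirculation-perfusion run.

    The marker series starts at the t=0 sample (taken before the drug is
    introduced) and is therefore one element longer than the drug series.
    """

    times_min: np.ndarray
    marker_concentrations_uM: np.ndarray
    drug_concentrations_uM: np.ndarray
    nominal_marker_concentration_uM: float
    nominal_volume_mL: float
    nominal_drug_concentration_uM: float
    sample_volume_mL: float
    geometry: SegmentGeometry

    def __post_init__(self) -> None:
        times = np.asarray(self.times_min, dtype=float)
        marker = np.asarray(self.marker_concentrations_uM, dtype=float)
        drug = np.asarray(self.drug_concentrations_uM, dtype=float)
        object.__setattr__(self, "times_min", times)
        object.__setattr__(self, "marker_concentrations_uM", marker)
        object.__setattr__(self, "drug_concentrations_uM", drug)
        if times[0] != 0.0:
            raise ValueError("times_min must start at 0 (the initial marker sample)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if len(marker) != len(times):
            raise ValueError("one marker concentration per sampling time required")
        if len(drug) != len(times) - 1:
            raise ValueError(
                "drug series must be one element shorter than the marker series "
                "(the drug is added after the t=0 sample)"
            )
        if np.any(marker <= 0):
            bad = int(np.flatnonzero(marker <= 0)[0])
            raise ValueError(f"marker concentration at index {bad} is not positive")
        if np.any(drug < 0):
            raise ValueError("drug concentrations must be non-negative")

    @property
    def drug_times_min(self) -> np.ndarray:
        return self.times_min[1:]


@dataclass(frozen=True)
class VolumeTrace:
    """Perfusate volumes reconstructed from the marker concentrations."""

    v0_mL: float
    volumes_mL: np.ndarray
    variant: Variant

    def __post_init__(self) -> None:
        volumes = np.asarray(self.volumes_mL, dtype=float)
        object.__setattr__(self, "volumes_mL", volumes)
        if self.v0_mL <= 0 or np.any(volumes <= 0):
            raise ValueError("reconstructed volumes must be positive")


@dataclass(frozen=True)
class KaFit:
    """Log-linear fit of the corrected drug concentration, C_t = C0*exp(-ka*t)."""

    ka_per_min: float
    c0_fit_uM: float
    r_squared: float
    n_points_used: int


@dataclass(frozen=True)
class WaterFluxEstimate:
    """Regression-based water flux with an endpoint-based alternative.

    The regression slope of the cumulative volume loss (V0 - Vt) against
    time uses every point; the endpoint estimate divides the final loss by
    the final time and therefore hinges entirely on the last sample.
    """

    jwater_uL_per_cm_per_h: float
    r_squared: float
    endpoint_jwater_uL_per_cm_per_h: float


@dataclass(frozen=True)
class PerfusionResult:
    peff_cm_per_s: float
    ka_fit: KaFit
    water_flux: WaterFluxEstimate
    corrected_concentrations_uM: np.ndarray
    volume_trace: VolumeTrace
    variant: Variant

    @property
    def jwater_uL_per_cm_per_h(self) -> float:
        return self.water_flux.jwater_uL_per_cm_per_h


def initial_volume(series: PerfusionTimeSeries) -> float:
    """Perfusate volume at the t=0 sample, V0 = C'*V'/C'_0.

    Before the first sample the marker amount in the circuit equals the
    loaded amount C'*V'; its measured dilution therefore reads out the
    volume remaining after the stabilization period.
    """
    c0_prime = float(series.marker_concentrations_uM[0])
    if c0_prime <= 0:
        raise ValueError("initial marker concentration must be positive")
    return (
        series.nominal_marker_concentration_uM
        * series.nominal_volume_mL
        / c0_prime
    )


def volume_trace(
    series: PerfusionTimeSeries,
    variant: Variant = "recursive",
    assumed_replacement: AssumedReplacement = "marker_stock",
    max_v0_ratio: float = 1.5,
) -> VolumeTrace:
    """Reconstruct perfusate volumes V_1..V_n from the marker series.

    ``assumed_replacement`` states what the analysis assumes was added back
    after each sampling: ``marker_stock`` (aliquot at the nominal marker
    concentration, the default protocol), or ``blank``/``none`` (no marker
    returned; the two are amount-equivalent for the reconstruction).
    """
    v0 = initial_volume(series)
    if v0 > max_v0_ratio * series.nominal_volume_mL:
        raise ValueError(
            f"V0 = {v0:.3f} mL exceeds {max_v0_ratio:.2f} x nominal volume; "
            "marker series is implausible"
        )
    s = series.sample_volume_mL
    c_rep = (
        series.nominal_marker_concentration_uM
        if assumed_replacement == "marker_stock"
        else 0.0
    )
    marker = series.marker_concentrations_uM
    n = len(marker) - 1
    volumes = np.empty(n, dtype=float)
    prev = v0
    for t in range(1, n + 1):
        c_t = marker[t]
        if c_t <= 0:
            raise ValueError(f"marker concentration at sample {t} is not positive")
        base = v0 if variant == "literal" else prev
        volumes[t - 1] = ((base - s) * marker[t - 1] + s * c_rep) / c_t
        prev = volumes[t - 1]
    return VolumeTrace(v0_mL=v0, volumes_mL=volumes, variant=variant)


def corrected_concentrations(
    series: PerfusionTimeSeries, trace: VolumeTrace
) -> np.ndarray:
    """Water-flux-corrected drug concentrations, C_t = C_e * V_t / V_0.

    Referencing every amount back to the initial volume removes the apparent
    concentration rise caused by water absorption, leaving only true
    membrane transport (and any unreplaced sampling losses) in the decay.
    """
    return series.drug_concentrations_uM * trace.volumes_mL / trace.v0_mL


def fit_ka(
    times_min: Sequence[float],
    corrected_uM: Sequence[float],
    fit_window: tuple[float, float] | None = None,
) -> KaFit:
    """First-order disappearance rate by log-linear OLS of ln(C_t) vs t.

    Nonpositive corrected concentrations cannot enter the log fit; they are
    excluded with a logged warning.  At least 3 usable points are required.
    """
    t = np.asarray(times_min, dtype=float)
    c = np.asarray(corrected_uM, dtype=float)
    if fit_window is not None:
        lo, hi = fit_window
        keep = (t >= lo) & (t <= hi)
        t, c = t[keep], c[keep]
    positive = c > 0
    if not np.all(positive):
        n_bad = int(np.sum(~positive))
        logger.warning(
            "fit_ka: excluding %d nonpositive corrected concentration(s)", n_bad
        )
        t, c = t[positive], c[positive]
    if len(t) < 3:
        raise ValueError("fit_ka requires at least 3 positive concentrations")
    fit = stats.linregress(t, np.log(c))
    return KaFit(
        ka_per_min=-fit.slope,
        c0_fit_uM=math.exp(fit.intercept),
        r_squared=fit.rvalue**2,
        n_points_used=len(t),
    )


def peff_from_ka(fit: KaFit, geometry: SegmentGeometry) -> float:
    """Effective permeability Peff = ka*R/2 (cm/s) for a cylindrical lumen."""
    ka_per_s = units.ka_per_min_to_per_s(fit.ka_per_min)
    return ka_per_s * geometry.radius_cm / 2.0


def water_flux(
    trace: VolumeTrace,
    times_min: Sequence[float],
    geometry: SegmentGeometry,
) -> WaterFluxEstimate:
    """Water flux from the regression slope of (V0 - Vt) against time.

    The (t=0, loss=0) point anchors the fit.  The result is normalized per
    cm of intestine and reported in uL/cm/h.  The endpoint alternative
    (final loss / final time) is returned alongside; because it depends only
    on the last sample it inherits that sample's full error.
    """
    t = np.asarray(times_min, dtype=float)
    if len(t) != len(trace.volumes_mL):
        raise ValueError("times must align with the volume trace (t = 1..n)")
    if len(t) < 2:
        raise ValueError("water_flux requires at least 3 points including t=0")
    losses = trace.v0_mL - trace.volumes_mL
    t_fit = np.concatenate(([0.0], t))
    y_fit = np.concatenate(([0.0], losses))
    fit = stats.linregress(t_fit, y_fit)
    jwater = units.slope_mL_per_min_to_jwater(fit.slope, geometry.length_cm)
    endpoint = units.slope_mL_per_min_to_jwater(
        losses[-1] / t[-1], geometry.length_cm
    )
    return WaterFluxEstimate(
        jwater_uL_per_cm_per_h=jwater,
        r_squared=fit.rvalue**2,
        endpoint_jwater_uL_per_cm_per_h=endpoint,
    )


def analyze_perfusion(
    series: PerfusionTimeSeries,
    variant: Variant = "recursive",
    assumed_replacement: AssumedReplacement = "marker_stock",
    fit_window: tuple[float, float] | None = None,
) -> PerfusionResult:
    """Full estimation chain: volume trace -> corrected concentrations ->
    ka fit -> Peff, plus the regression-based water flux."""
    trace = volume_trace(series, variant=variant, assumed_replacement=assumed_replacement)
    corrected = corrected_concentrations(series, trace)
    ka = fit_ka(series.drug_times_min, corrected, fit_window=fit_window)
    peff = peff_from_ka(ka, series.geometry)
    jw = water_flux(trace, series.drug_times_min, series.geometry)
    return PerfusionResult(
        peff_cm_per_s=peff,
        ka_fit=ka,
        water_flux=jw,
        corrected_concentrations_uM=corrected,
        volume_trace=trace,
        variant=variant,
    )
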
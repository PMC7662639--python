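"""Experiment-design and variability models.

These pydantic models validate the structured description of an experiment:
the intestinal segment geometry, the solutes (volume marker and model drug),
the recirculation-perfusion and everted-gut-sac designs, and the noise /
inter-animal variability model used by the simulator.
"""

from __future__ import annotations

import math
from typing import Literal

from pydantic import BaseModel, Field, model_validator

SegmentName = Literal[
    "duodenum", "jejunum", "ileum", "colon", "whole_small_intestine"
]

ReplacementPolicy = Literal["marker_stock", "marker_and_drug_stock", "blank", "none"]


class SegmentGeometry(BaseModel):
    """Effective cylindrical geometry of a perfused/everted intestinal segment.

    The mucosal surface exposed to the lumen is modeled as a smooth cylinder,
    A = 2*pi*R*L, optionally scaled by ``area_multiplier`` to stand in for
    villous amplification if a user wants it.
    """

    segment_name: SegmentName
    radius_cm: float = Field(gt=0)
    length_cm: float = Field(gt=0)
    area_multiplier: float = Field(default=1.0, gt=0)

    model_config = {"frozen": True}

    @property
    def surface_area_cm2(self) -> float:
        return 2.0 * math.pi * self.radius_cm * self.length_cm * self.area_multiplier


#: Default effective radius (cm) and perfused length (cm) per segment.  The
#: radius of the anesthetized-rat lumen is not directly measurable in these
#: protocols; 0.18 cm is a conventional literature figure for rat small
#: intestine and is used for all segments.
_DEFAULT_DIMENSIONS: dict[str, tuple[float, float]] = {
    "duodenum": (0.18, 10.0),
    "jejunum": (0.18, 10.0),
    "ileum": (0.18, 10.0),
    "colon": (0.18, 10.0),
    "whole_small_intestine": (0.18, 40.0),
}


def default_geometry(segment_name: SegmentName) -> SegmentGeometry:
    """Standard geometry for a named segment (R = 0.18 cm, L = 10 cm; the
    whole small intestine uses L = 40 cm)."""
    radius, length = _DEFAULT_DIMENSIONS[segment_name]
    return SegmentGeometry(
        segment_name=segment_name, radius_cm=radius, length_cm=length
    )


class SoluteSpec(BaseModel):
    """A solute in an experiment: the volume marker or the model drug.

    ``permeability_cm_per_s`` is the ground-truth membrane parameter for the
    chosen segment: the in-vitro apparent permeability (Papp) for a marker,
    or the operational effective permeability (Peff, the estimand of the
    recirculation method) for a drug.
    """

    name: str
    role: Literal["marker", "drug"]
    permeability_cm_per_s: float = Field(ge=0)
    initial_concentration_uM: float = Field(gt=0)

    model_config = {"frozen": True}


class PerfusionDesign(BaseModel):
    """Recirculation-perfusion protocol constants.

    Defaults follow the standard rat protocol: a 20-mL recirculating
    perfusate, 0.4-mL samples every 10 min for 60 min, a 10-min
    stabilization with the marker solution before the t=0 sample, and
    replacement of each withdrawn aliquot with marker stock.
    """

    nominal_volume_mL: float = Field(default=20.0, gt=0)
    sample_volume_mL: float = Field(default=0.4, ge=0)
    sampling_interval_min: float = Field(default=10.0, gt=0)
    n_samples: int = Field(default=6, ge=3)
    replacement_policy: ReplacementPolicy = "marker_stock"
    true_jwater_uL_per_cm_per_h: float = 200.0
    stabilization_min: float = Field(default=10.0, ge=0)
    #: whether the aliquot added after the t=0 marker sample itself carries
    #: marker at the stock concentration (the volume-trace recursion assumes
    #: it does).
    marker_in_t0_addition: bool = True

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _sample_smaller_than_circuit(self) -> "PerfusionDesign":
        if self.sample_volume_mL >= self.nominal_volume_mL:
            raise ValueError("sample_volume_mL must be smaller than nominal_volume_mL")
        return self


class EGSDesign(BaseModel):
    """Everted-gut-sac protocol constants.

    The sac (receiver) holds ``sac_volume_mL`` of blank buffer; every
    ``sampling_interval_min`` a ``sample_volume_mL`` aliquot of receiver
    fluid is withdrawn and replaced with blank buffer.  ``sink_assumption``
    drops the receiver concentration from the driving gradient;
    ``constant_donor`` freezes the donor concentration (no depletion by
    transfer).
    """

    donor_volume_mL: float = Field(default=10.0, gt=0)
    sac_volume_mL: float = Field(default=2.0, gt=0)
    sample_volume_mL: float = Field(default=0.4, ge=0)
    sampling_interval_min: float = Field(default=15.0, gt=0)
    n_samples: int = Field(default=8, ge=3)
    sink_assumption: bool = False
    constant_donor: bool = False

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _sample_smaller_than_sac(self) -> "EGSDesign":
        if self.sample_volume_mL >= self.sac_volume_mL:
            raise ValueError("sample_volume_mL must be smaller than sac_volume_mL")
        return self


class NoiseModel(BaseModel):
    """Measurement noise and inter-animal variability.

    ``assay_cv`` is the relative SD of the multiplicative Gaussian error on
    every measured concentration (truncated at -3 SD so observations stay
    positive).  The animal CVs parameterize mean-preserving lognormal
    distributions of the per-animal water flux and permeabilities.  The same
    seed always reproduces the same experiment.
    """

    assay_cv: float = Field(default=0.05, ge=0)
    animal_cv_jwater: float = Field(default=0.4, ge=0)
    animal_cv_permeability: float = Field(default=0.3, ge=0)
    seed: int = 0

    model_config = {"frozen": True}
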
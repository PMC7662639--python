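import numpy as np
import pytest

import gutperm as gp


@pytest.fixture
def jejunum():
    return gp.default_geometry("jejunum")


@pytest.fixture
def quiet_noise():
    """No assay noise, no inter-animal variability."""
    return gp.NoiseModel(
        assay_cv=0.0, animal_cv_jwater=0.0, animal_cv_permeability=0.0, seed=0
    )


@pytest.fixture
def marker_spec():
    def make(papp=0.0, concentration=56.0, name="marker"):
        return gp.SoluteSpec(
            name=name,
            role="marker",
            permeability_cm_per_s=papp,
            initial_concentration_uM=concentration,
        )

    return make


@pytest.fixture
def drug_spec():
    def make(peff=1.0e-4, concentration=100.0, name="drug"):
        return gp.SoluteSpec(
            name=name,
            role="drug",
            permeability_cm_per_s=peff,
            initial_concentration_uM=concentration,
        )

    return make
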
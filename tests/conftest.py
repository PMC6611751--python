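import numpy as np
import pytest

from gleasongrade.datamodel import TissueClass
from gleasongrade.model import GleasonGradingModel
from gleasongrade.patches import Patch
from gleasongrade.synthetic import CohortSpec, generate_slide

# shared zero block so partition/balance tests can build many patches cheaply
_ZERO = np.zeros((299, 299, 3), dtype=np.uint8)


def make_patch(label: TissueClass, biopsy_id: str, center=(150, 150)) -> Patch:
    return Patch(pixels=_ZERO, center=center, label=label, biopsy_id=biopsy_id, slide_id="s")


@pytest.fixture(scope="session")
def four_class_slide():
    """One synthetic slide containing all four tissue classes."""
    return generate_slide((0.25, 0.25, 0.3, 0.2), size=(600, 1200), seed=7)


@pytest.fixture(scope="session")
def fitted_pipeline():
    """Full pipeline fit on the default synthetic cohort (fixed study
    conditions: 12 biopsies spanning benign and GG1-4, texture_separation
    1.0).  Session-scoped because the fit takes a few minutes."""
    spec = CohortSpec(n_biopsies=12, texture_separation=1.0, seed=1)
    model = GleasonGradingModel.from_cohort_spec(spec)
    return model.fit(seed=1)
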
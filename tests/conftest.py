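import pytest

from sigreverse import compute_differential, score_library
from sigreverse.simulate import funnel_study


@pytest.fixture(scope="session")
def study():
    """Study-scale funnel bundle (1219 drugs, exact-count allocation)."""
    return funnel_study(seed=1)


@pytest.fixture(scope="session")
def study_scored(study):
    """(signature, library result) for the study bundle, computed once."""
    records, signature = compute_differential(study.expression)
    result = score_library(signature, study.profiles)
    return signature, result
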
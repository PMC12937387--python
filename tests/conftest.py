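import numpy as np
import pytest

from cefapk import FINAL_MODEL, ModelStructure, StudyDesign, simulate_dataset

# keep the numerics quiet: padded/extreme regions of parameter space are
# handled by masking and bounds, not by warnings
np.seterr(all="ignore")


@pytest.fixture(scope="session")
def reference_params():
    """Published final-model parameter set used as simulation truth."""
    return FINAL_MODEL


@pytest.fixture(scope="session")
def final_structure():
    return ModelStructure.final()


@pytest.fixture(scope="session")
def cohort67():
    """One study-sized synthetic cohort (67 subjects, default design)."""
    return simulate_dataset(FINAL_MODEL, StudyDesign(), seed=101)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fit-based unit tests that must stay fast."""
    return simulate_dataset(FINAL_MODEL, StudyDesign(n_subjects=16), seed=7)


@pytest.fixture(scope="session")
def fast_fit_options():
    """Reduced optimizer effort for unit tests of fitting mechanics."""
    return {"rounds": 1, "use_powell": True, "powell_maxfev": 600, "maxiter": 50}
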
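import numpy as np
import pytest

from teicopk import reference
from teicopk.estimation import final_model
from teicopk.pk_core import IndividualParams
from teicopk.synthetic_data import CohortSpec, StudyDesign, generate_cohort, generate_dataset

# silence benign overflow/underflow chatter from extreme optimizer proposals
np.seterr(all="ignore")


@pytest.fixture(scope="session")
def typical_params() -> IndividualParams:
    """Final-model typical values at the reference covariates."""
    return IndividualParams(V1=2.31, V2=16.19, Q=0.23, CL=0.13)


@pytest.fixture(scope="session")
def ref_theta():
    return reference.REFERENCE_THETA.copy()


@pytest.fixture(scope="session")
def ref_omega():
    return reference.REFERENCE_OMEGA_SD.copy()


@pytest.fixture(scope="session")
def model():
    return final_model()


def make_rich_dataset(n_subjects=200, cohort_seed=1, data_seed=101, n_samples=6):
    """Steady-state rich design: ``n_samples`` samples over the day-14
    maintenance interval of the clinical regimen."""
    cohort = generate_cohort(CohortSpec(n_subjects=n_subjects), seed=cohort_seed)
    t0 = 360.0
    offsets = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 23.9])[:n_samples]
    times = [t0 + offsets for _ in range(n_subjects)]
    return generate_dataset(cohort, StudyDesign(), seed=data_seed, sample_times=times)


@pytest.fixture(scope="session")
def sparse_dataset():
    """Study-like sparse dataset: 136 children, 1-3 samples each."""
    cohort = generate_cohort(CohortSpec(), seed=7)
    return generate_dataset(cohort, StudyDesign(), seed=77)
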
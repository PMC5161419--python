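import numpy as np
import pytest
from hypothesis import settings

import gremlkin as gk

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort():
    """Small family cohort with G, K and C architecture and one binary trait."""
    return gk.generate_cohort(gk.SimulationConfig(
        n_families=40, n_snps_common=600, n_snps_rare=150, seed=11,
        traits=[gk.TraitConfig(h_g2=0.2, h_p2=0.3, e_c2=0.2, prevalence=0.13)],
    ))


@pytest.fixture(scope="session")
def matrices(cohort):
    """All five relationship matrices for the session cohort."""
    G = gk.compute_grm(cohort.genotypes)
    mats = {"G": G, "K": gk.threshold_kinship(G)}
    for kind in "FSC":
        mats[kind] = gk.build_erm(cohort.pedigree, kind,
                                  sample_ids=cohort.sample_ids)
    return mats


@pytest.fixture(scope="session")
def design(cohort):
    """Intercept + age/age^2/sex design for the session cohort."""
    return np.column_stack([np.ones(cohort.n), cohort.covariates])


@pytest.fixture(scope="session")
def trio_pedigree():
    return gk.Pedigree([
        ("F1", None, None, 1),
        ("M1", None, None, 2),
        ("C1", "F1", "M1", 2),
    ])
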
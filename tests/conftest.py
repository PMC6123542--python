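import numpy as np
import pandas as pd
import pytest

import fibromet as fm
from fibromet.pipeline import bins_pqn
from fibromet.spectra import SpectraSet


def make_spectra(ppm, intensities, groups=None, kind="custom"):
    """Small helper: SpectraSet from raw arrays with auto annotations."""
    intensities = np.atleast_2d(intensities)
    n = intensities.shape[0]
    groups = groups if groups is not None else ["g"] * n
    ann = pd.DataFrame(
        {
            "sample_id": [f"s{i:02d}" for i in range(n)],
            "group": groups,
            "matrix_kind": kind,
        }
    )
    return SpectraSet(np.asarray(ppm, float), intensities, ann)


def quantify_cohort(spectra, matrix_kind):
    """Excise -> bin -> PQN -> integrate, returning the concentration table."""
    s = fm.excise_region(spectra, 4.54, 5.18)
    bins = fm.adaptive_bin(s)
    _, factors = fm.pqn_normalize(bins)
    return fm.integrate_metabolites(
        bins_pqn(bins, factors), fm.load_default_assignments(matrix_kind)
    )


@pytest.fixture(scope="session")
def liver_library():
    return fm.load_default_library("liver")


@pytest.fixture(scope="session")
def serum_library():
    return fm.load_default_library("serum")


@pytest.fixture(scope="session")
def liver_effects():
    return fm.load_default_effects("liver")


@pytest.fixture(scope="session")
def liver_cohort(liver_library, liver_effects):
    """Control/model liver cohort, n=15/group, generator defaults, seed 1."""
    design = fm.design_from_effects(liver_effects, seed=1)
    return fm.simulate_cohort(liver_library, design)


@pytest.fixture(scope="session")
def liver_concentrations(liver_cohort):
    spectra, _ = liver_cohort
    return quantify_cohort(spectra, "liver")
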
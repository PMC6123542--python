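"""Metabolite integration and STOCSY."""

import numpy as np
import pandas as pd
import pytest

import fibromet as fm
from fibromet.binning import BinTable
from fibromet.quantify import AssignmentTable
from fibromet.synthdata import CohortDesign, MetaboliteLibrary


def _bin_table(values, bins=None):
    values = np.atleast_2d(np.asarray(values, float))
    bins = bins or [(float(k), float(k) + 1.0) for k in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"s{i}" for i in range(values.shape[0])])
    df.index.name = "sample_id"
    return BinTable(bins, df)


def _assign(rows):
    return AssignmentTable(
        pd.DataFrame(rows, columns=["metabolite", "window_lo", "window_hi", "weight"])
    )


def test_single_analyte_tracks_truth():
    """One metabolite, one window, zero noise: integrals ~ true concentrations."""
    lib = MetaboliteLibrary({"probe": [(5.0, 1.0, 0.01)]})
    design = CohortDesign(
        groups=[("control", 8), ("model", 8)],
        sigma_log2=0.4,
        noise_sd=0.0,
        baseline_amplitude=0.0,
        shift_jitter_sd=0.0,
        dilution_range=(1.0, 1.0),
        seed=2,
    )
    s, truth = fm.simulate_cohort(lib, design, np.linspace(4, 6, 3000))
    bins = fm.adaptive_bin(s)
    conc = fm.integrate_metabolites(bins, _assign([("probe", 4.8, 5.2, 1.0)]))
    r = np.corrcoef(conc.values["probe"], truth.concentrations["probe"])[0, 1]
    assert r > 0.999


def test_empty_assignment_warns():
    b = _bin_table([[1.0, 2.0]])
    with pytest.warns(UserWarning, match="empty"):
        conc = fm.integrate_metabolites(b, _assign([]))
    assert conc.values.shape[1] == 0


def test_two_windows_additive():
    b = _bin_table([[1.0, 2.0, 3.0, 4.0]])
    a = _assign([("m", 0.0, 1.0, 1.0), ("m", 2.0, 4.0, 1.0)])
    conc = fm.integrate_metabolites(b, a)
    # bins have midpoints 0.5, 1.5, 2.5, 3.5 -> windows own bins 0 and 2+3
    assert conc.values.loc["s0", "m"] == pytest.approx(1.0 + 3.0 + 4.0)


def test_window_weights_applied():
    b = _bin_table([[1.0, 2.0]])
    conc = fm.integrate_metabolites(b, _assign([("m", 0.0, 2.0, 0.5)]))
    assert conc.values.loc["s0", "m"] == pytest.approx(0.5 * 3.0)


def test_unmatched_window_dropped_with_warning():
    b = _bin_table([[1.0, 2.0]])
    a = _assign([("m", 0.0, 1.0, 1.0), ("ghost", 5.0, 6.0, 1.0)])
    with pytest.warns(UserWarning, match="matched no bin"):
        conc = fm.integrate_metabolites(b, a)
    assert list(conc.values.columns) == ["m"]
    assert conc.provenance["dropped_metabolites"] == ["ghost"]


def test_integration_linear_in_intensity(liver_concentrations, liver_cohort):
    spectra, _ = liver_cohort
    from conftest import make_spectra, quantify_cohort

    doubled = make_spectra(
        spectra.ppm, 2 * spectra.intensities, spectra.annotations["group"], "liver"
    )
    # PQN absorbs a global doubling, so compare raw bin integrals instead
    b1 = fm.adaptive_bin(fm.excise_region(spectra, 4.54, 5.18))
    b2 = fm.adaptive_bin(fm.excise_region(doubled, 4.54, 5.18))
    a = fm.load_default_assignments("liver")
    c1 = fm.integrate_metabolites(b1, a)
    c2 = fm.integrate_metabolites(b2, a)
    np.testing.assert_allclose(c2.values.to_numpy(), 2 * c1.values.to_numpy(), rtol=1e-9)


def test_overlapping_windows_between_metabolites_rejected():
    with pytest.raises(ValueError, match="overlap"):
        _assign([("a", 0.0, 1.0, 1.0), ("b", 0.5, 1.5, 1.0)])


# ---------------------------------------------------------------------------
# STOCSY

@pytest.fixture(scope="module")
def two_analyte_cohort():
    """'twin' has two resonances sharing one concentration; 'other' is
    independent."""
    lib = MetaboliteLibrary(
        {"twin": [(2.0, 1.0, 0.01), (7.0, 0.5, 0.01)], "other": [(5.0, 1.0, 0.01)]}
    )
    design = CohortDesign(
        groups=[("control", 10), ("model", 10)],
        sigma_log2=0.4,
        noise_sd=0.001,
        baseline_amplitude=0.0,
        shift_jitter_sd=0.0,
        dilution_range=(1.0, 1.0),
        seed=3,
    )
    return fm.simulate_cohort(lib, design, np.linspace(0, 10, 4000))


def test_stocsy_driver_self_correlation(two_analyte_cohort):
    s, _ = two_analyte_cohort
    profile = fm.stocsy(s, driver=2.0)
    at_driver = profile.loc[(profile["ppm"] - 2.0).abs().idxmin(), "r"]
    assert at_driver == pytest.approx(1.0)


def test_stocsy_same_molecule_peaks_correlate(two_analyte_cohort):
    s, _ = two_analyte_cohort
    profile = fm.stocsy(s, driver=2.0)
    at_partner = profile.loc[(profile["ppm"] - 7.0).abs().idxmin(), "r"]
    assert at_partner > 0.95


def test_stocsy_independent_peak_within_permutation_null(two_analyte_cohort):
    s, _ = two_analyte_cohort
    profile = fm.stocsy(s, driver=2.0)
    at_other = abs(profile.loc[(profile["ppm"] - 5.0).abs().idxmin(), "r"])
    # permutation null for |r| between the driver point and the other peak
    i = int(np.argmin(np.abs(s.ppm - 2.0)))
    j = int(np.argmin(np.abs(s.ppm - 5.0)))
    rng = np.random.default_rng(0)
    null = [
        abs(np.corrcoef(rng.permutation(s.intensities[:, i]), s.intensities[:, j])[0, 1])
        for _ in range(500)
    ]
    assert at_other < np.quantile(null, 0.95)


def test_stocsy_symmetric_and_affine_invariant(two_analyte_cohort):
    s, _ = two_analyte_cohort
    bins = fm.adaptive_bin(s)
    p_fwd = fm.stocsy(bins, driver=2.0)
    p_rev = fm.stocsy(bins, driver=7.0)
    r_fwd = p_fwd.loc[(p_fwd["ppm"] - 7.0).abs().idxmin(), "r"]
    r_rev = p_rev.loc[(p_rev["ppm"] - 2.0).abs().idxmin(), "r"]
    assert r_fwd == pytest.approx(r_rev, abs=1e-12)
    # positive affine rescaling of features leaves r untouched
    scaled = BinTable(bins.bins, bins.values * 3.7 + 0.2)
    p_scaled = fm.stocsy(scaled, driver=2.0)
    np.testing.assert_allclose(p_scaled["r"], p_fwd["r"], atol=1e-10)


def test_stocsy_driver_outside_axis_rejected(two_analyte_cohort):
    s, _ = two_analyte_cohort
    bins = fm.adaptive_bin(s)
    with pytest.raises(ValueError, match="no bin"):
        fm.stocsy(bins, driver=99.0)
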
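"""OPLS-DA: algebraic identities, cross-validated Q2, permutation test."""

import numpy as np
import pytest

import fibromet as fm
from fibromet.opls import OPLSDA, PermutationResult


def _separable(n=30, p=20, seed=0, noise=0.3):
    """One feature is the exact class indicator; the rest pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X = noise * rng.normal(size=(n, p))
    X[:, 0] = np.where(y == "a", -1.0, 1.0)
    return X, y


def test_separable_data_r2y_and_loading_correlation():
    X, y = _separable()
    model = fm.fit_oplsda(X, y, n_orth=1)
    assert model.r2y_ > 0.99
    assert abs(model.loading_correlations_[0]) > 0.99
    assert np.argmax(np.abs(model.loading_correlations_)) == 0


def test_orthogonal_scores_uncorrelated_with_y():
    X, y = _separable(seed=5)
    model = fm.fit_oplsda(X, y, n_orth=3)
    yenc = np.where(y == model.classes_[0], -1.0, 1.0)
    for _, t_o, _ in model.orth_components_:
        r = np.corrcoef(t_o, yenc)[0, 1]
        assert abs(r) < 1e-8


def test_deflation_conserves_squared_norm():
    X, y = _separable(seed=7)
    model = fm.fit_oplsda(X, y, n_orth=2)
    Xd = X.copy()
    removed = 0.0
    for _, t_o, p_o in model.orth_components_:
        removed += np.linalg.norm(np.outer(t_o, p_o)) ** 2
        Xd = Xd - np.outer(t_o, p_o)
    assert np.linalg.norm(X) ** 2 == pytest.approx(
        removed + np.linalg.norm(Xd) ** 2, rel=1e-8
    )


def test_sample_permutation_invariance():
    X, y = _separable(seed=2)
    model = fm.fit_oplsda(X, y)
    perm = np.random.default_rng(0).permutation(len(y))
    model2 = fm.fit_oplsda(X[perm], y[perm])
    assert model2.r2y_ == pytest.approx(model.r2y_, rel=1e-9)


def test_predictive_direction_matches_pls1():
    """With no orthogonal filtering the predictive scores coincide (up to
    sign) with the first component of an independent PLS1 implementation."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 12))
    y = np.array(["a", "b"] * 20)
    model = OPLSDA(n_orth=0).fit(X, y)
    yenc = np.where(y == "a", -1.0, 1.0)
    pls = PLSRegression(n_components=1, scale=False).fit(X - X.mean(0), yenc)
    r = np.corrcoef(model.t_pred_, pls.x_scores_[:, 0])[0, 1]
    assert abs(r) > 1 - 1e-8


def test_invalid_inputs_rejected():
    X, y = _separable()
    with pytest.raises(ValueError, match="two classes"):
        fm.fit_oplsda(X, np.array(["a"] * len(y)))
    with pytest.raises(ValueError, match="rank"):
        fm.fit_oplsda(X[:, :3], y, n_orth=5)
    with pytest.raises(ValueError, match="two classes"):
        fm.cross_validate_q2(X, np.array(["a"] * len(y)))


def test_q2_noise_is_low_and_below_r2y():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 25))
    y = np.array(["a"] * 15 + ["b"] * 15)
    q2 = fm.cross_validate_q2(X, y, repeats=50, seed=0)
    r2 = OPLSDA(n_orth=1, scale="pareto").fit(X, y).r2y_
    assert q2 <= 0.1
    assert q2 <= r2


def test_q2_high_on_separated_cohort(liver_concentrations, liver_cohort):
    spectra, _ = liver_cohort
    y = spectra.annotations["group"].to_numpy()
    q2 = fm.cross_validate_q2(liver_concentrations.values.to_numpy(), y, repeats=20, seed=0)
    assert q2 > 0.4


def test_permutation_p_bounds_and_null_center():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(24, 10))
    y = np.array(["a"] * 12 + ["b"] * 12)
    res = fm.permutation_test(X, y, n_perm=99, seed=0, repeats=3)
    assert isinstance(res, PermutationResult)
    assert 1 / 100 <= res.p_value <= 1
    # permuted Q2 is centered at or below zero
    assert np.mean(res.permuted_q2) < 0.05


def test_permutation_separable_data_beats_every_permutation():
    X, y = _separable(n=24, p=10, seed=9)
    res = fm.permutation_test(X, y, n_perm=99, seed=1, repeats=3)
    assert res.p_value == pytest.approx(1 / 100)


def test_scores_loadings_export_roundtrip(tmp_path):
    X, y = _separable()
    model = fm.fit_oplsda(X, y, n_orth=1)
    scores, loadings = fm.scores_loadings_export(
        model, sample_ids=[f"s{i}" for i in range(len(y))], groups=y
    )
    assert {"t_pred", "t_orth1", "group"} <= set(scores.columns)
    assert ((loadings["abs_r"] >= 0) & (loadings["abs_r"] <= 1)).all()
    assert loadings.loc[0, "abs_r"] == loadings["abs_r"].max()
    f = tmp_path / "loadings.tsv"
    loadings.to_csv(f, sep="\t", index=False)
    import pandas as pd

    back = pd.read_csv(f, sep="\t")
    np.testing.assert_allclose(back["p_pred"], loadings["p_pred"])


def test_dose_response_ordering(liver_library, liver_effects):
    """Five-group design: control vs model separates strongly, and the
    high-dose group sits farther from the model group than the low dose."""
    design = fm.design_from_effects(
        liver_effects,
        groups=(("control", 15), ("model", 15), ("low", 15), ("medium", 15), ("high", 15)),
        seed=4,
    )
    spectra, _ = fm.simulate_cohort(liver_library, design)
    from conftest import quantify_cohort

    conc = quantify_cohort(spectra, "liver")
    ann = spectra.annotations
    def q2(ga, gb):
        mask = ann["group"].isin([ga, gb]).to_numpy()
        return fm.cross_validate_q2(
            conc.values.to_numpy()[mask], ann.loc[mask, "group"].to_numpy(),
            repeats=10, seed=0,
        )
    assert q2("control", "model") > 0.4
    assert q2("low", "model") <= q2("high", "model")
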
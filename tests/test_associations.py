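"""Ridge CCA and thresholded correlation networks with reaction overlay."""

import numpy as np
import pandas as pd
import pytest

import fibromet as fm
from fibromet.associations import RidgeCCA, load_default_reactions, write_network
from fibromet.quantify import ConcentrationTable


def _table(values, names=None):
    values = np.atleast_2d(values)
    names = names or [f"m{k}" for k in range(values.shape[1])]
    df = pd.DataFrame(values, columns=names,
                      index=pd.Index([f"s{i}" for i in range(len(values))], name="sample_id"))
    return ConcentrationTable(df)


# ---------------------------------------------------------------------------
# CCA

def test_copied_column_gives_perfect_first_correlation():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 5))
    Y = np.column_stack([X[:, 2], rng.normal(size=40)])
    model = RidgeCCA(ridge=1e-6).fit(X, Y)
    assert model.canonical_correlations_[0] >= 0.999


def test_independent_blocks_below_permutation_null():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 4))
    Y = rng.normal(size=(60, 3))
    obs = RidgeCCA(ridge=0.0).fit(X, Y).canonical_correlations_[0]
    null = []
    for _ in range(200):
        null.append(
            RidgeCCA(ridge=0.0).fit(X, Y[rng.permutation(60)]).canonical_correlations_[0]
        )
    assert obs < np.quantile(null, 0.95)


def test_variable_correlations_inside_unit_circle(liver_concentrations, liver_cohort):
    spectra, _ = liver_cohort
    rng = np.random.default_rng(2)
    X = liver_concentrations.values
    # a small clinical-style panel correlated with a few metabolites
    Y = pd.DataFrame(
        {
            "marker1": X["lactate"] + rng.normal(0, 0.1, len(X)),
            "marker2": rng.normal(size=len(X)),
            "marker3": -X["hypoxanthine"] + rng.normal(0, 0.1, len(X)),
        },
        index=X.index,
    )
    model = fm.canonical_regression(liver_concentrations, Y, ridge=0.1)
    tab = model.variable_correlation_table()
    norms = np.hypot(tab["r1"], tab["r2"])
    assert (norms <= 1 + 1e-8).all()
    assert sorted(model.canonical_correlations_, reverse=True) == list(
        model.canonical_correlations_
    )


def test_cca_matches_bruteforce_eigen_oracle_and_affine_invariance():
    """At ridge=0 and n >> p the canonical correlations equal the classic
    generalized-eigenvalue solution and survive invertible affine maps."""
    rng = np.random.default_rng(3)
    n, p, q = 300, 4, 3
    Z = rng.normal(size=(n, 2))
    X = Z @ rng.normal(size=(2, p)) + 0.7 * rng.normal(size=(n, p))
    Y = Z @ rng.normal(size=(2, q)) + 0.7 * rng.normal(size=(n, q))
    model = RidgeCCA(ridge=0.0).fit(X, Y)

    # brute force: eig of Cxx^-1 Cxy Cyy^-1 Cyx on standardized blocks
    def std(V):
        return (V - V.mean(0)) / V.std(0, ddof=1)

    Xs, Ys = std(X), std(Y)
    Cxx = np.cov(Xs, rowvar=False)
    Cyy = np.cov(Ys, rowvar=False)
    Cxy = (Xs.T @ Ys) / (n - 1)
    M = np.linalg.solve(Cxx, Cxy) @ np.linalg.solve(Cyy, Cxy.T)
    eigvals = np.sort(np.linalg.eigvals(M).real)[::-1]
    np.testing.assert_allclose(
        model.canonical_correlations_ ** 2, eigvals[:2], rtol=1e-8
    )

    A = rng.normal(size=(p, p)) + 3 * np.eye(p)
    B = rng.normal(size=(q, q)) + 3 * np.eye(q)
    model2 = RidgeCCA(ridge=0.0).fit(X @ A, Y @ B + 5.0)
    np.testing.assert_allclose(
        model2.canonical_correlations_, model.canonical_correlations_, rtol=1e-6
    )


def test_cca_constant_column_dropped():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"a": rng.normal(size=20), "b": np.full(20, 2.0)})
    Y = pd.DataFrame({"c": rng.normal(size=20)})
    with pytest.warns(UserWarning, match="constant"):
        model = RidgeCCA().fit(X, Y)
    assert model.x_names_ == ["a"]


# ---------------------------------------------------------------------------
# networks

def _latent_block_cohort(n=15, seed=0):
    """m0 and m1 share a latent driver; m2 and m3 are independent."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    vals = np.column_stack(
        [
            np.exp(z + 0.05 * rng.normal(size=n)),
            np.exp(z + 0.05 * rng.normal(size=n)),
            np.exp(rng.normal(size=n)),
            np.exp(rng.normal(size=n)),
        ]
    )
    return _table(vals)


def test_network_recovers_planted_block():
    net = fm.build_network(_latent_block_cohort(), threshold=0.6)
    assert net.has_edge("m0", "m1")
    data = net.get_edge_data("m0", "m1")["pearson"]
    assert data["r"] > 0.9 and data["kind"] == "pearson"


def test_network_rejects_independent_pairs_mostly():
    hits = 0
    for seed in range(40):
        net = fm.build_network(_latent_block_cohort(seed=seed), threshold=0.6)
        hits += net.has_edge("m2", "m3")
    assert hits <= 2  # >= 95% rejection at n=15


def test_threshold_one_connects_only_exact_duplicates():
    c = _latent_block_cohort()
    dup = c.values.copy()
    dup["m4"] = dup["m0"]
    net = fm.build_network(ConcentrationTable(dup), threshold=1.0)
    assert net.has_edge("m0", "m4")
    assert net.number_of_edges() == 1


def test_threshold_monotone_nesting_and_affine_invariance():
    c = _latent_block_cohort(seed=7)
    lo = fm.build_network(c, threshold=0.3)
    hi = fm.build_network(c, threshold=0.7)
    hi_edges = {frozenset(e[:2]) for e in hi.edges}
    lo_edges = {frozenset(e[:2]) for e in lo.edges}
    assert hi_edges <= lo_edges
    scaled = ConcentrationTable(c.values * 3.0 + 1.0)
    same = fm.build_network(scaled, threshold=0.3)
    assert {frozenset(e[:2]) for e in same.edges} == lo_edges


def test_node_attributes_from_stats():
    c = _latent_block_cohort()
    st = pd.DataFrame(
        {"log2fc": [1.2, -0.5, 0.1, 0.0], "star": ["**", "*", "", ""]},
        index=["m0", "m1", "m2", "m3"],
    )
    net = fm.build_network(c, st, threshold=0.6)
    assert net.nodes["m0"]["log2fc"] == pytest.approx(1.2)
    assert net.nodes["m1"]["star"] == "*"


def test_reaction_overlay_known_purine_chain():
    names = ["hypoxanthine", "xanthine", "inosine", "lactate"]
    rng = np.random.default_rng(5)
    c = _table(np.exp(rng.normal(size=(10, 4))), names)
    net = fm.build_network(c, threshold=0.99)
    reactions = pd.DataFrame(
        {
            "metabolite_a": ["hypoxanthine", "inosine", "inosine"],
            "metabolite_b": ["xanthine", "hypoxanthine", "hypoxanthine"],  # dup pair
        }
    )
    out = fm.overlay_reactions(net, reactions)
    assert out.get_edge_data("hypoxanthine", "xanthine")["reaction"]["kind"] == "reaction"
    assert out.get_edge_data("inosine", "hypoxanthine")["reaction"]["kind"] == "reaction"
    # duplicate deduplicated: exactly two reaction edges
    kinds = [d["kind"] for _, _, d in out.edges(data=True)]
    assert kinds.count("reaction") == 2


def test_reaction_overlay_empty_and_unresolved():
    c = _latent_block_cohort()
    net = fm.build_network(c, threshold=0.6)
    out = fm.overlay_reactions(net, pd.DataFrame(columns=["metabolite_a", "metabolite_b"]))
    assert out.number_of_edges() == net.number_of_edges()
    with pytest.warns(UserWarning, match="unresolvable"):
        fm.overlay_reactions(
            net,
            pd.DataFrame({"metabolite_a": ["nosuch"], "metabolite_b": ["m0"]}),
        )


def test_packaged_reactions_resolve_on_liver_names(liver_library):
    reactions = load_default_reactions()
    names = set(liver_library.names)
    endpoint_hits = sum(
        (a in names) and (b in names)
        for a, b in zip(reactions["metabolite_a"], reactions["metabolite_b"])
    )
    assert endpoint_hits >= 25  # most curated pairs live on the liver panel


def test_graphml_export_roundtrip(tmp_path):
    import networkx as nx

    c = _latent_block_cohort()
    st = pd.DataFrame(
        {"log2fc": [1.2, -0.5, 0.1, 0.0], "star": ["**", "*", "", ""]},
        index=["m0", "m1", "m2", "m3"],
    )
    reactions = pd.DataFrame({"metabolite_a": ["m0"], "metabolite_b": ["m2"]})
    net = fm.overlay_reactions(fm.build_network(c, st, threshold=0.6), reactions)
    p = tmp_path / "net.graphml"
    write_network(net, p)
    back = nx.read_graphml(p)
    assert set(back.nodes) == set(net.nodes)
    assert back.number_of_edges() == net.number_of_edges()
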
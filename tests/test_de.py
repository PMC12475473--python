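"""Hurdle DE, BH-FDR, marker selection and aging-DEG filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

import striaging as st
from conftest import make_count_matrix


def _nb_matrix(rng, n, mu, dispersion=2.0):
    lam = rng.gamma(dispersion, mu / dispersion)
    return rng.poisson(lam)


def test_detection_rate_basic():
    counts = np.zeros((3, 100), dtype=int)
    counts[0, :50] = 1
    counts[2, :] = 1
    cdr = st.detection_rate(make_count_matrix(counts))
    assert cdr[0] == 0.5
    assert cdr[1] == 0.0
    assert cdr[2] == 1.0


def test_detection_rate_rank_stable_under_duplicated_gene():
    rng = np.random.default_rng(0)
    counts = rng.poisson(0.5, size=(30, 40))
    dup = np.hstack([counts, counts[:, [0]]])
    r1 = st.detection_rate(make_count_matrix(counts))
    r2 = st.detection_rate(make_count_matrix(dup))
    # the duplicate may create ties but never reverses the order of cells
    d1 = r1[:, None] - r1[None, :]
    d2 = r2[:, None] - r2[None, :]
    assert (d1 * d2 >= 0).all()


def test_bh_fdr_worked_example():
    out = st.bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])
    assert st.bh_fdr([0.3]) == pytest.approx([0.3])
    assert np.allclose(st.bh_fdr([1.0, 1.0, 1.0]), 1.0)


def test_bh_fdr_matches_reference_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(300):
        p = rng.random(rng.integers(1, 60))
        expected = fdrcorrection(p, alpha=0.05, method="indep")[1]
        assert np.allclose(st.bh_fdr(p), expected, atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st_h.lists(st_h.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
def test_bh_fdr_properties(pvals):
    adj = st.bh_fdr(pvals)
    assert ((adj >= 0) & (adj <= 1)).all()
    # monotone in the p-value order
    order = np.argsort(pvals, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-15).all()
    assert np.allclose(adj, fdrcorrection(np.asarray(pvals))[1], atol=1e-12)


def test_bh_fdr_rejects_nan():
    with pytest.raises(ValueError):
        st.bh_fdr([0.1, np.nan])


def _two_group_norm(rng, n_per=200, n_genes=400, planted=0, log2fc=1.0, mu=0.8):
    mu_g = np.exp(rng.normal(np.log(mu) - 0.5, 1.0, n_genes))
    if planted:
        mu_g[:planted] = mu
    M = np.tile(mu_g, (2 * n_per, 1)).copy()
    if planted:
        M[n_per:, :planted] *= 2.0 ** log2fc
    counts = _nb_matrix(rng, 2 * n_per, M)
    cm = make_count_matrix(counts)
    groups = np.array(["ref"] * n_per + ["test"] * n_per)
    return st.normalize_log(cm), groups


def test_hurdle_null_type_one_error():
    norm, groups = _two_group_norm(np.random.default_rng(3), n_genes=1000)
    res = st.hurdle_de(norm, groups, test_group="test")
    rate = (res["p_value"] < 0.05).mean()
    assert 0.03 <= rate <= 0.07


def test_hurdle_detects_planted_effect():
    norm, groups = _two_group_norm(np.random.default_rng(4), n_genes=1000, planted=50)
    res = st.hurdle_de(norm, groups, test_group="test")
    assert (res["fdr"].iloc[:50] < 0.05).mean() >= 0.8
    assert (res["log2fc"].iloc[:50] > 0).all()


def test_hurdle_exchangeable_groups_uniform_pvalues():
    rng = np.random.default_rng(5)
    norm, _ = _two_group_norm(rng, n_per=150, n_genes=600)
    labels = rng.permutation(np.array(["a"] * 150 + ["b"] * 150))
    res = st.hurdle_de(norm, labels, test_group="b")
    ks = stats.kstest(res["p_value"], "uniform")
    assert ks.pvalue > 0.01


def test_hurdle_invariances():
    rng = np.random.default_rng(6)
    counts = _nb_matrix(rng, 120, np.full((120, 80), 0.8))
    groups = np.array(["a"] * 60 + ["b"] * 60)
    cm = make_count_matrix(counts)
    base = st.hurdle_de(st.normalize_log(cm), groups, test_group="b")
    # gene order permutation
    perm = rng.permutation(80)
    cm_p = cm.subset_genes(perm)
    res_p = st.hurdle_de(st.normalize_log(cm_p), groups, test_group="b")
    assert np.allclose(base["p_value"].to_numpy()[perm], res_p["p_value"].to_numpy())
    # per-cell scalar multiplication of raw counts before normalization
    scale = rng.integers(1, 5, size=120)
    cm_s = make_count_matrix(counts * scale[:, None])
    res_s = st.hurdle_de(st.normalize_log(cm_s), groups, test_group="b")
    assert np.allclose(base["p_value"], res_s["p_value"], atol=1e-8)


def test_hurdle_degenerate_gene_flagged():
    rng = np.random.default_rng(7)
    counts = _nb_matrix(rng, 80, np.full((80, 30), 1.0))
    counts[:, 0] = 0  # detected nowhere
    groups = np.array(["a"] * 40 + ["b"] * 40)
    res = st.hurdle_de(st.normalize_log(make_count_matrix(counts)), groups, test_group="b")
    assert res.iloc[0]["degenerate"]
    assert res.iloc[0]["p_value"] == 1.0
    assert res.iloc[0]["log2fc"] == 0.0


def test_hurdle_logistic_part_matches_statsmodels():
    """Dual route: our IRLS logistic LRT vs statsmodels Logit on one gene."""
    import statsmodels.api as sm
    from striaging.de import _logit_nll
    rng = np.random.default_rng(8)
    n = 300
    x = rng.normal(size=n)
    g = np.repeat([0.0, 1.0], n // 2)
    eta = -0.5 + 0.8 * g + 0.5 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    X_full = np.column_stack([np.ones(n), g, x])
    ours = _logit_nll(X_full, y)
    ref = -sm.Logit(y, X_full).fit(disp=0).llf
    assert ours == pytest.approx(ref, abs=1e-6)


def test_marker_ratio_worked_example():
    """In-cluster detection 0.50 vs 0.25 outside gives ratio exactly 2.0."""
    rng = np.random.default_rng(9)
    n_in, n_out = 200, 200
    counts = rng.poisson(1.0, size=(n_in + n_out, 60))
    counts[:, 0] = 0
    counts[:n_in // 2, 0] = 5          # 50% detection inside
    counts[n_in:n_in + n_out // 4, 0] = 5  # 25% detection outside
    groups = np.array(["in"] * n_in + ["out"] * n_out)
    res = st.hurdle_de(st.normalize_log(make_count_matrix(counts)), groups, test_group="in")
    assert res.iloc[0]["pct_in"] == 0.5
    assert res.iloc[0]["pct_out"] == 0.25
    assert res.iloc[0]["ratio"] == 2.0
    assert res.iloc[0]["ratio"] >= 2.0  # passes the marker threshold


def test_ratio_zero_outside_uses_smoothing():
    rng = np.random.default_rng(10)
    counts = rng.poisson(1.0, size=(100, 30))
    counts[:, 0] = 0
    counts[:25, 0] = 3  # detected only inside
    groups = np.array(["in"] * 50 + ["out"] * 50)
    res = st.hurdle_de(st.normalize_log(make_count_matrix(counts)), groups, test_group="in")
    assert res.iloc[0]["ratio"] == pytest.approx(0.5 / (1 / 51))


def test_planted_markers_selected(sep3, sep3_norm):
    _, _, _, truth = sep3
    tab = st.select_cluster_markers(sep3_norm, truth.subtype_labels, top_n=10)
    for name, planted in truth.markers.items():
        got = tab.loc[tab["cluster"] == name, "gene"]
        assert len(got) > 0
        assert set(got) <= set(planted)


def test_select_aging_degs_boundaries():
    de = pd.DataFrame({
        "log2fc": [0.25, 0.26, -0.5, 0.1],
        "fdr": [0.001, 0.001, 0.01, 0.001],
    }, index=["on_boundary", "up", "down", "weak"])
    all_g, top = st.select_aging_degs(de, top_k=1)
    assert "on_boundary" not in all_g   # strict > 0.25
    assert set(all_g) == {"up", "down"}  # absolute fold change, both directions
    assert top == ["up"]
    assert st.select_aging_degs(pd.DataFrame()) == ([], [])


def test_planted_aging_program_all_recovered():
    cfg = st.SimulationConfig(seed=12, n_cells_per_age=400, n_genes=250)
    cells, counts, truth = st.simulate_dataset(cfg)
    norm = st.normalize_log(counts)
    age = cells.set_index("cell_id")["age"]
    res = st.hurdle_de(norm, age.reindex(norm.cell_ids), test_group="aged")
    all_g, _ = st.select_aging_degs(res)
    assert set(truth.aging_program) <= set(all_g)
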
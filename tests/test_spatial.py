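"""Dorsal-ventral binning, the regional enrichment statistic, age shifts,
densities, and the two-way profile test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import striaging as st
from striaging.spatial import _interaction_f


def _cells(y_values, origin=0.0):
    return pd.DataFrame({
        "x_um": np.zeros(len(y_values)),
        "y_um": np.asarray(y_values, dtype=float) + origin,
    }, index=[f"c{i}" for i in range(len(y_values))])


def test_assign_subregions_half_open():
    binning = st.SubregionBinning(origin_y=0.0)
    bins = st.assign_subregions(_cells([750.0, 1000.0, -5.0, 2999.0, 3000.0]), binning)
    assert list(bins) == [1, 2, -1, 5, -1]


def test_assign_subregions_respects_origin():
    binning = st.SubregionBinning(origin_y=200.0)
    bins = st.assign_subregions(_cells([100.0, 250.0]), binning)
    assert list(bins) == [-1, 0]


def test_expression_probability_hand_example():
    # subtype A has (8, 2) cells in bins with totals (10, 40)
    counts = st.SubregionCounts(np.array([[8.0, 2.0], [2.0, 38.0]]), ["A", "B"])
    prof = st.expression_probability(counts)
    assert prof.P[0] == pytest.approx([0.8 / 0.85, 0.05 / 0.85], abs=1e-4)
    literal = st.expression_probability(counts, mode="literal")
    assert literal.P[0] == pytest.approx([0.8 / 10, 0.05 / 10])


def test_uniformly_mixed_subtype_flat_profile():
    # same subtype fraction in every bin, arbitrary bin totals
    n = np.array([[30.0, 60.0, 15.0], [70.0, 140.0, 35.0]])
    prof = st.expression_probability(st.SubregionCounts(n, ["A", "B"]))
    assert np.allclose(prof.P, 1 / 3)


def test_renormalized_invariant_to_abundance_and_density():
    rng = np.random.default_rng(0)
    n = rng.integers(5, 50, size=(3, 6)).astype(float)
    base = st.expression_probability(st.SubregionCounts(n, list("ABC"))).P
    # doubling every count
    doubled = st.expression_probability(st.SubregionCounts(2 * n, list("ABC"))).P
    assert np.allclose(base, doubled)
    # scaling one subtype's abundance leaves its own profile unchanged only
    # through the bin totals; verified as the full rescaling experiment:
    # multiply every subtype count and every bin total consistently
    col_scale = rng.uniform(0.5, 2.0, size=6)  # per-bin density change
    scaled = st.expression_probability(
        st.SubregionCounts(n * col_scale[None, :] * 3.0, list("ABC"))).P
    assert np.allclose(base, scaled)


def test_empty_bin_share_zero():
    n = np.array([[5.0, 0.0], [5.0, 0.0]])
    prof = st.expression_probability(st.SubregionCounts(n, ["A", "B"]))
    assert np.allclose(prof.P[:, 1], 0.0)


def test_age_shift_zero_for_identical_and_sums_to_zero(sim_default):
    _, cells, _, truth = sim_default
    meta = cells.set_index("cell_id")
    binning = st.SubregionBinning(0.0)
    bins = st.assign_subregions(meta, binning)
    young = (meta["age"] == "young").to_numpy()
    cy = st.count_subregions(truth.subtype_labels[young], bins[young], 6)
    ca = st.count_subregions(truth.subtype_labels[~young], bins[~young], 6)
    py, pa = st.expression_probability(cy), st.expression_probability(ca)
    same = st.age_shift(py, py)
    assert np.allclose(same.to_numpy(), 0.0)
    common = sorted(set(py.subtypes) & set(pa.subtypes))
    iy = [py.subtypes.index(s) for s in common]
    ia = [pa.subtypes.index(s) for s in common]
    delta = st.age_shift(
        st.EnrichmentProfile(py.P[iy], common, py.mode),
        st.EnrichmentProfile(pa.P[ia], common, pa.mode),
    )
    assert np.abs(delta.to_numpy().sum(axis=1)).max() < 1e-9


def test_age_shift_sign_for_planted_dorsal_shift():
    cfg = st.SimulationConfig.dorsal_shift(seed=0)
    cells, _, truth = st.simulate_dataset(cfg)
    meta = cells.set_index("cell_id")
    bins = st.assign_subregions(meta, st.SubregionBinning(0.0))
    young = (meta["age"] == "young").to_numpy()
    py = st.expression_probability(
        st.count_subregions(truth.subtype_labels[young], bins[young], 6))
    pa = st.expression_probability(
        st.count_subregions(truth.subtype_labels[~young], bins[~young], 6))
    delta = st.age_shift(py, pa).loc["A4"].to_numpy()
    occupied = np.where(cfg.spatial_weights_young[3] > 0.01)[0]
    assert delta[occupied.min()] > 0  # gains dorsally
    assert delta[occupied.max()] < 0  # loses ventrally


def test_age_shift_mismatched_bins_error():
    a = st.EnrichmentProfile(np.full((1, 3), 1 / 3), ["A"], "renormalized")
    b = st.EnrichmentProfile(np.full((1, 4), 0.25), ["A"], "renormalized")
    with pytest.raises(ValueError):
        st.age_shift(a, b)


def test_density_per_area():
    binning = st.SubregionBinning(0.0, n_bins=3)
    rng = np.random.default_rng(1)
    n = 6000
    cells = pd.DataFrame({"x_um": rng.uniform(0, 1000, n),
                          "y_um": rng.uniform(0, 1500, n)})
    mask = np.ones(n, dtype=bool)
    dens = st.density_per_area(cells, mask, binning)
    # uniform density: equal per-window counts within Poisson error
    expected = n / 3 / 2  # 2 windows of 500x500 per bin row
    assert np.abs(dens - expected).max() < 4 * np.sqrt(expected)
    # empty subset
    assert np.allclose(st.density_per_area(cells, ~mask, binning), 0.0)
    # translation by one bin height shifts the profile by one bin
    shifted = cells.copy()
    shifted["y_um"] += binning.bin_height
    d2 = st.density_per_area(shifted, mask, binning)
    assert np.allclose(d2[1:], dens[:-1])


def test_interaction_f_matches_statsmodels():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    rng = np.random.default_rng(2)
    Y = rng.normal(size=(8, 4))
    groups = np.array(["y"] * 4 + ["a"] * 4)
    f_g, f_b, f_i = _interaction_f(Y, groups)
    long = pd.DataFrame({
        "score": Y.ravel(),
        "group": np.repeat(groups, 4),
        "bin": np.tile(np.arange(4), 8).astype(str),
    })
    fit = ols("score ~ C(group) * C(bin)", data=long).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    assert f_g == pytest.approx(tab.loc["C(group)", "F"], rel=1e-8)
    assert f_b == pytest.approx(tab.loc["C(bin)", "F"], rel=1e-8)
    assert f_i == pytest.approx(tab.loc["C(group):C(bin)", "F"], rel=1e-8)


def test_profile_test_identical_groups_f_near_zero():
    rng = np.random.default_rng(7)
    young = np.array([0.4, 0.3, 0.2, 0.1]) + rng.normal(0, 0.05, size=(4, 4))
    Y = np.vstack([young, young])  # aged samples are exact copies
    groups = np.array(["y"] * 4 + ["a"] * 4)
    out = st.profile_test(Y, groups, n_perm=99, seed=0)
    assert out["F_interaction"] == pytest.approx(0.0, abs=1e-6)


def test_profile_test_detects_planted_shift():
    rng = np.random.default_rng(3)
    young = np.array([0.4, 0.3, 0.2, 0.1])
    aged = np.array([0.6, 0.25, 0.1, 0.05])
    Y = np.vstack([young + rng.normal(0, 0.02, 4) for _ in range(4)]
                  + [aged + rng.normal(0, 0.02, 4) for _ in range(4)])
    groups = np.array(["y"] * 4 + ["a"] * 4)
    out = st.profile_test(Y, groups, n_perm=999, seed=0)
    assert out["p_interaction"] < 0.05


def test_profile_test_null_pvalues_uniform():
    rng = np.random.default_rng(4)
    groups = np.array(["y"] * 4 + ["a"] * 4)
    pvals = []
    for i in range(100):
        Y = rng.normal(size=(8, 5))
        pvals.append(st.profile_test(Y, groups, n_perm=99, seed=i)["p_interaction"])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_profile_test_single_sample_group_warns_nan():
    Y = np.random.default_rng(5).normal(size=(3, 4))
    out = st.profile_test(Y, np.array(["y", "a", "a"]), n_perm=99, seed=0)
    assert np.isnan(out["p_interaction"])
    assert np.isfinite(out["F_interaction"])
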
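"""Spearman screening, grouping and class-proportion profiles."""

import numpy as np
import pytest

from ctg_interpret import feature_screen as fs
from ctg_interpret.ctg_data import CTG_FEATURES

from conftest import make_dataset, random_dataset


def midranks(x: np.ndarray) -> np.ndarray:
    """Hand-written mid-rank assignment (independent of scipy)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def oracle_spearman(X: np.ndarray) -> np.ndarray:
    R = np.column_stack([midranks(col) for col in X.T])
    k = X.shape[1]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pearson(R[:, i], R[:, j])
    return out


def test_spearman_matches_rank_then_pearson_oracle(rng):
    ds = random_dataset(rng, 40, list(CTG_FEATURES), levels=6)
    corr = fs.spearman_matrix(ds)
    X = ds.frame[corr.variables].to_numpy(float)
    keep = [i for i, v in enumerate(corr.variables) if v not in corr.flagged]
    expected = oracle_spearman(X[:, keep])
    got = corr.rho.to_numpy()[np.ix_(keep, keep)]
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_spearman_invariant_under_monotone_transform():
    ds = make_dataset(ASTV=[3, 1, 4, 1, 5, 9, 2, 6], LB=[2, 7, 1, 8, 2, 8, 1, 8],
                      NSP=[1, 1, 2, 2, 3, 3, 1, 2])
    rho1 = fs.spearman_matrix(ds).rho
    ds2 = ds.copy()
    ds2.frame["ASTV"] = np.exp(ds2.frame["ASTV"] / 3.0)  # strictly increasing
    rho2 = fs.spearman_matrix(ds2).rho
    np.testing.assert_allclose(rho1.loc["ASTV"], rho2.loc["ASTV"], atol=1e-12)


def test_spearman_perfect_monotone_is_unit():
    ds = make_dataset(ASTV=[1, 2, 3, 4, 5], LB=[10, 20, 30, 40, 50],
                      MSTV=[5, 4, 3, 2, 1], NSP=[1, 1, 2, 2, 3])
    rho = fs.spearman_matrix(ds).rho
    assert rho.loc["ASTV", "LB"] == pytest.approx(1.0, abs=1e-12)
    assert rho.loc["ASTV", "MSTV"] == pytest.approx(-1.0, abs=1e-12)


def test_spearman_flags_constant_columns(small_dataset):
    corr = fs.spearman_matrix(small_dataset)
    assert "LB" in corr.flagged            # all-zero default column
    assert "ASTV" not in corr.flagged


def test_spearman_needs_three_records():
    with pytest.raises(ValueError, match="3 records"):
        fs.spearman_matrix(make_dataset(LB=[1, 2], NSP=[1, 2]))


def test_nsp_correlations_ranked_by_abs_rho(small_dataset):
    table = fs.nsp_correlations(fs.spearman_matrix(small_dataset))
    assert list(table.columns) == ["feature", "rho", "p", "p_bonferroni"]
    r = table["rho"].abs().to_numpy()
    finite = r[np.isfinite(r)]
    assert np.all(np.diff(finite) <= 1e-15)
    assert (table["p_bonferroni"].dropna() <= 1.0).all()


def test_correlated_groups_recovers_planted_blocks(rng):
    n = 300
    base1 = rng.normal(size=n)
    base2 = rng.normal(size=n)
    ds = make_dataset(
        LB=base1, Mode=base1 + 0.1 * rng.normal(size=n),
        Median=base1 + 0.1 * rng.normal(size=n),
        Width=base2, Variance=base2 + 0.1 * rng.normal(size=n),
        ASTV=rng.normal(size=n),  # uncorrelated singleton
        NSP=rng.integers(1, 4, size=n),
    )
    groups = fs.correlated_groups(fs.spearman_matrix(ds), threshold=0.7)
    as_sets = [set(g) for g in groups]
    assert {"LB", "Mode", "Median"} in as_sets
    assert {"Width", "Variance"} in as_sets
    assert all("ASTV" not in g for g in groups)   # singletons dropped
    assert all("NSP" not in g for g in groups)    # label never grouped


def test_correlated_groups_canonical_order(small_dataset):
    corr = fs.spearman_matrix(small_dataset)
    for g in fs.correlated_groups(corr, threshold=0.5):
        order = [CTG_FEATURES.index(f) for f in g]
        assert order == sorted(order)


def test_correlated_groups_threshold_domain(small_dataset):
    corr = fs.spearman_matrix(small_dataset)
    for bad in (0.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            fs.correlated_groups(corr, threshold=bad)


def test_stacked_proportions_hand_computed():
    ds = make_dataset(ASTV=[5, 10, 25, 30, 90, 95],
                      NSP=[1, 1, 1, 2, 3, 3])
    bp = fs.stacked_proportions(ds, "ASTV", [0.0, 18.0, 80.0, 100.0])
    assert bp.counts == [2, 2, 2]
    assert bp.proportions[0] == (1.0, 0.0, 0.0)
    assert bp.proportions[1] == (0.5, 0.5, 0.0)
    assert bp.proportions[2] == (0.0, 0.0, 1.0)


def test_stacked_proportions_last_bin_closed():
    ds = make_dataset(ASTV=[0, 100], NSP=[1, 3])
    bp = fs.stacked_proportions(ds, "ASTV", [0.0, 50.0, 100.0])
    assert bp.counts == [1, 1]  # the value 100 lands in the last (closed) bin


def test_stacked_proportions_empty_bin_is_none():
    ds = make_dataset(ASTV=[5, 95], NSP=[1, 3])
    bp = fs.stacked_proportions(ds, "ASTV", [0.0, 18.0, 80.0, 100.0])
    assert bp.proportions[1] is None and bp.counts[1] == 0


def test_stacked_proportions_extends_edges_with_warning():
    ds = make_dataset(ASTV=[5, 95], NSP=[1, 3])
    with pytest.warns(UserWarning, match="extending"):
        bp = fs.stacked_proportions(ds, "ASTV", [10.0, 50.0, 90.0])
    assert bp.edges[0] <= 5 and bp.edges[-1] >= 95
    assert sum(bp.counts) == 2


def test_stacked_proportions_validates_input(small_dataset):
    with pytest.raises(ValueError, match="unknown feature"):
        fs.stacked_proportions(small_dataset, "XYZ", [0, 1])
    with pytest.raises(ValueError, match="increasing"):
        fs.stacked_proportions(small_dataset, "ASTV", [0.0, 0.0, 1.0])


def test_proportions_table_shape(small_dataset):
    bp = fs.stacked_proportions(small_dataset, "ASTV", fs.LANDMARK_EDGES["ASTV"])
    table = fs.proportions_table(bp)
    assert list(table.columns) == ["bin", "count", "normal", "suspicious", "pathology"]
    assert len(table) == len(bp.counts)
    assert table["count"].sum() == small_dataset.n


def test_equal_width_edges_cover_range(small_dataset):
    edges = fs.equal_width_edges(small_dataset, "ASTV", bins=4)
    v = small_dataset.frame["ASTV"]
    assert len(edges) == 5
    assert edges[0] == v.min() and edges[-1] == v.max()
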
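import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from secretomap.plasma import (
    STANDARD_ROW, average_linkage, hcluster, normalize_to_standard,
    pregnancy_fold_change, row_zscore, spearman_distance_matrix,
)
from tests._oracles import normalize_oracle


def quant_frame(values, columns=None, with_standard=True, standard=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    idx = [f"p{i}" for i in range(len(arr))]
    cols = columns or [f"c{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=idx, columns=cols)
    if with_standard:
        df.loc[STANDARD_ROW] = standard if standard is not None else 1.0
    return df


def test_unit_standard_is_identity():
    q = quant_frame([[1.0, 2.0], [3.0, 4.0]])
    out = normalize_to_standard(q)
    assert STANDARD_ROW not in out.index
    assert np.allclose(out.to_numpy(), [[1, 2], [3, 4]])


def test_per_column_rescaling_is_removed():
    """Doubling a column's raw values and its standard leaves output unchanged."""
    q = quant_frame([[1.0, 2.0], [3.0, 4.0]], standard=[5.0, 7.0])
    ref = normalize_to_standard(q)
    q2 = q.copy()
    q2["c1"] *= 2.0
    assert np.allclose(normalize_to_standard(q2).to_numpy(), ref.to_numpy(),
                       atol=1e-15)


def test_normalization_matches_division_oracle(rng):
    """Random 50x11 matrices equal the element-wise division loop."""
    for _ in range(10):
        vals = rng.uniform(0.1, 100, (51, 11))
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(50)] + [STANDARD_ROW],
                          columns=[f"c{j}" for j in range(11)])
        out = normalize_to_standard(df)
        assert np.allclose(out.to_numpy(), normalize_oracle(vals, 50))


def test_zero_standard_rejected_naming_column():
    q = quant_frame([[1.0, 2.0]], standard=[1.0, 0.0])
    with pytest.raises(ValueError, match="c1"):
        normalize_to_standard(q)


GROUPS = {"n1": "NP", "n2": "NP", "p1": "P", "p2": "P"}


def test_planted_folds_recovered_exactly_without_noise():
    folds = [0.8, 1.0, 2.0, 10.0, 52.0]
    rows = [[1.0, 1.0, f, f] for f in folds]
    df = pd.DataFrame(rows, index=[f"p{i}" for i in range(5)],
                      columns=list(GROUPS))
    out = pregnancy_fold_change(df, GROUPS)
    assert np.allclose(out["fold_p_vs_np"], folds)
    assert list(out["higher_in_pregnancy"]) == [False, False, True, True, True]


def test_fold_exactly_at_threshold_is_classified_higher():
    df = pd.DataFrame([[1.0, 1.0, 1.5, 1.5]], index=["p0"], columns=list(GROUPS))
    out = pregnancy_fold_change(df, GROUPS, threshold=1.5)
    assert bool(out.loc["p0", "higher_in_pregnancy"])


def test_identical_group_means_give_fold_one():
    df = pd.DataFrame([[2.0, 4.0, 1.0, 5.0]], index=["p0"], columns=list(GROUPS))
    out = pregnancy_fold_change(df, GROUPS)
    assert out.loc["p0", "fold_p_vs_np"] == pytest.approx(1.0)
    assert not bool(out.loc["p0", "higher_in_pregnancy"])


def test_undetected_in_np_gets_finite_fold_via_floor():
    df = pd.DataFrame([[0.0, 0.0, 4.0, 4.0], [1.0, 1.0, 1.0, 1.0]],
                      index=["p0", "p1"], columns=list(GROUPS))
    out = pregnancy_fold_change(df, GROUPS)
    assert np.isfinite(out.loc["p0", "fold_p_vs_np"])
    assert out.loc["p0", "fold_p_vs_np"] == pytest.approx(4.0 / 0.5)


def test_nonpositive_threshold_rejected():
    df = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["p0"], columns=list(GROUPS))
    with pytest.raises(ValueError):
        pregnancy_fold_change(df, GROUPS, threshold=0.0)


def test_row_zscore_hand_computed_population_sd():
    """(1,2,3) standardized with the population SD sqrt(2/3)."""
    out = row_zscore(pd.DataFrame([[1.0, 2.0, 3.0]]))
    expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3 / 2)
    assert np.allclose(out.to_numpy().ravel(), expected, atol=1e-12)


def test_constant_row_maps_to_zeros():
    out = row_zscore(pd.DataFrame([[5.0, 5.0, 5.0]]))
    assert np.all(out.to_numpy() == 0.0)


def test_zscore_rows_have_zero_mean_unit_sd(rng):
    out = row_zscore(pd.DataFrame(rng.normal(size=(30, 8))))
    vals = out.to_numpy()
    assert np.abs(vals.mean(axis=1)).max() < 1e-12
    assert np.abs(vals.std(axis=1, ddof=0) - 1).max() < 1e-12


def _distinct_distance_matrix(rng, n=6, m=12):
    """Random rows whose pairwise Spearman distances are all distinct."""
    for _ in range(100):
        vals = rng.normal(size=(n, m))
        d = spearman_distance_matrix(vals, [str(i) for i in range(n)])
        tri = d[np.triu_indices(n, k=1)]
        if len(np.unique(np.round(tri, 12))) == len(tri):
            return vals
    raise AssertionError("could not build a tie-free instance")


def test_identical_rows_merge_first_at_height_zero(rng):
    vals = rng.normal(size=(5, 10))
    vals[3] = vals[1]
    df = pd.DataFrame(vals, index=list("abcde"))
    tree = hcluster(df, axis="rows")
    i, j, h = tree.merges[0]
    assert h == pytest.approx(0.0, abs=1e-12)
    assert {tree.labels[i], tree.labels[j]} == {"b", "d"}


def test_anticorrelated_pair_has_distance_two_and_merges_last(rng):
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    rows = {"x": x, "y": -2 * x + 7, "z": rng.normal(size=5)}
    df = pd.DataFrame(rows).T
    d = spearman_distance_matrix(df.to_numpy(), list(df.index))
    assert d[0, 1] == pytest.approx(2.0)
    tree = hcluster(df, axis="rows")
    # the final merge joins the anticorrelated partner into the rest
    assert tree.merges[-1][2] >= d.max() / 2


def test_merge_tree_matches_scipy_average_linkage(rng):
    """>=100 random continuous distance matrices agree with scipy's linkage.

    Continuous distances are tie-free almost surely, so both linkages are
    forced to the unique average-linkage tree.
    """
    for _ in range(100):
        n = int(rng.integers(4, 9))
        tri = rng.uniform(0.1, 2.0, n * (n - 1) // 2)
        d = squareform(tri)
        labels = [f"r{i}" for i in range(n)]
        tree = average_linkage(d, labels)
        Z = linkage(tri, method="average")
        assert np.allclose(tree.cophenetic(), cophenet(Z), atol=1e-10)


def test_hcluster_composes_spearman_distance_and_linkage(rng):
    vals = _distinct_distance_matrix(rng)
    labels = [f"r{i}" for i in range(len(vals))]
    tree = hcluster(pd.DataFrame(vals, index=labels), axis="rows")
    d = spearman_distance_matrix(vals, labels)
    assert tree.merges == average_linkage(d, labels).merges


def test_merge_heights_non_decreasing(rng):
    vals = rng.normal(size=(8, 10))
    tree = hcluster(pd.DataFrame(vals), axis="rows")
    heights = [h for _, _, h in tree.merges]
    assert heights == sorted(heights)


def test_invariant_to_strictly_monotone_transform(rng):
    """Spearman distance depends only on ranks."""
    vals = _distinct_distance_matrix(rng)
    df = pd.DataFrame(vals, index=[f"r{i}" for i in range(len(vals))])
    tree1 = hcluster(df, axis="rows")
    tree2 = hcluster(np.exp(df * 0.5) + 3, axis="rows")
    assert tree1.merges == tree2.merges


def test_constant_vector_rejected_by_name(rng):
    vals = rng.normal(size=(3, 5))
    vals[1] = 2.5
    df = pd.DataFrame(vals, index=["a", "bad", "c"])
    with pytest.raises(ValueError, match="bad"):
        hcluster(df, axis="rows")


def test_column_axis_clusters_samples(rng):
    vals = rng.normal(size=(10, 5))
    tree = hcluster(pd.DataFrame(vals, columns=list("vwxyz")), axis="columns")
    assert sorted(tree.leaf_order) == list("vwxyz")
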
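"""Ingestion, mol% normalization, Z-scores, clustering, NZV filter, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage

from lipidisc.core import (
    LipidomicsDataset,
    SampleDesign,
    class_composition,
    group_summary,
    hierarchical_cluster,
    normalize_molpct,
    pca,
    read_lipidomics_table,
    remove_near_zero_variance,
    write_lipidomics_long,
    zscore_by_species,
)
from lipidisc.nomenclature import parse_species_annotation


def make_dataset(abundance, species_names=None, sample_ids=None):
    abundance = np.asarray(abundance, dtype=float)
    n, p = abundance.shape
    species_names = species_names or [f"Cer – {30 + j}:1:2" for j in range(p)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    return LipidomicsDataset(
        [SampleDesign(sid) for sid in sample_ids],
        [parse_species_annotation(a) for a in species_names],
        abundance,
    )


# ---------------------------------------------------------------------------
# ingestion

def test_read_long_table(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(
        "sample\tlipid\tpmol\n"
        "s1\tCer – 34:1:2\t5\n"
        "s1\tPC – 16:0:0;18:1:0\t10\n"
        "s1\tSM – 34:1:2\t1\n"
    )
    ds = read_lipidomics_table(path)
    assert ds.abundance.shape == (1, 3)
    assert ds.abundance.sum() == 16


def test_read_long_sums_duplicates_and_zero_fills(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(
        "sample\tlipid\tpmol\n"
        "s1\tCer – 34:1:2\t5\n"
        "s1\tCer – 34:1:2\t3\n"
        "s2\tPC – 16:0:0;18:1:0\t4\n"
    )
    ds = read_lipidomics_table(path)
    frame = ds.to_frame()
    assert frame.loc["s1", "Cer – 34:1:2"] == 8          # duplicates summed
    assert frame.loc["s2", "Cer – 34:1:2"] == 0          # absent pair is zero


def test_read_long_reports_bad_annotation_row(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("sample\tlipid\tpmol\ns1\tFoobar – 1:2:3\t5\n")
    with pytest.raises(Exception, match="row 2"):
        read_lipidomics_table(path)


def test_read_wide_requires_matching_sidecar(tmp_path):
    wide = tmp_path / "w.tsv"
    wide.write_text("lipid\ts1\ts2\nCer – 34:1:2\t1\t2\n")
    side = tmp_path / "d.tsv"
    side.write_text("sample\ttimepoint\ts1\t0\n")
    with pytest.raises(ValueError, match="s2"):
        read_lipidomics_table(wide, layout="wide", design_path=side)


def test_long_roundtrip_through_writer(tmp_path):
    ds = make_dataset([[1.0, 2.0], [3.0, 4.0]])
    path = tmp_path / "out.tsv"
    write_lipidomics_long(ds, path)
    back = read_lipidomics_table(path)
    pd.testing.assert_frame_equal(back.to_frame(), ds.to_frame())


# ---------------------------------------------------------------------------
# normalization

def test_molpct_arithmetic():
    mp = normalize_molpct(make_dataset([[2.0, 3.0, 5.0]]))
    assert np.allclose(mp.to_numpy(), [[20.0, 30.0, 50.0]])
    single = normalize_molpct(make_dataset([[5.0]]))
    assert single.iloc[0, 0] == 100.0


def test_molpct_scale_invariance_and_conservation(rng):
    pmol = np.exp(rng.normal(0, 1, size=(6, 20)))
    ds = make_dataset(pmol, species_names=[f"Cer – {30 + j}:1:2" for j in range(20)])
    mp = normalize_molpct(ds)
    assert np.allclose(mp.sum(axis=1), 100.0, atol=1e-9)
    scaled = make_dataset(pmol * rng.uniform(0.5, 2.0, size=(6, 1)),
                          species_names=ds.species_names)
    pd.testing.assert_frame_equal(mp, normalize_molpct(scaled))


def test_molpct_all_zero_sample_errors():
    with pytest.raises(ValueError, match="s1"):
        normalize_molpct(make_dataset([[1.0, 1.0], [0.0, 0.0]],
                                      sample_ids=["s0", "s1"]))


# ---------------------------------------------------------------------------
# class composition

def test_class_composition_sums_species_by_class():
    ds = make_dataset(
        [[30.0, 30.0, 40.0]],
        species_names=["Cer – 34:1:2", "Cer – 36:1:2", "PC – 16:0:0;18:1:0"],
    )
    table = class_composition(normalize_molpct(ds))
    assert table.loc["Cer", "s0"] == 60.0
    assert table.loc["PC", "s0"] == 40.0
    assert np.allclose(table.sum(axis=0), 100.0, atol=1e-9)

    only_cer = class_composition(normalize_molpct(
        make_dataset([[1.0, 2.0], [3.0, 4.0]])))
    assert (only_cer.loc["Cer"] == 100.0).all()


def test_group_summary_matches_hand_computation():
    # 4 samples, two (timepoint, treatment) groups; expectations by hand:
    # group (0, control): values 10, 20 -> mean 15, sd |20-15|*sqrt(2)... =7.0710678
    ds = make_dataset([[10.0], [20.0], [30.0], [50.0]])
    for d, (tp, tr) in zip(ds.designs, [(0, "control"), (0, "control"),
                                        (4, "PKCi"), (4, "PKCi")]):
        d.timepoint, d.treatment = tp, tr
    table = pd.DataFrame([[10.0, 20.0, 30.0, 50.0]], index=["x"],
                         columns=ds.sample_ids)
    out = group_summary(table, ds.designs)
    assert out.loc[(0, "control"), ("mean", "x")] == 15.0
    assert out.loc[(4, "PKCi"), ("mean", "x")] == 40.0
    assert out.loc[(0, "control"), ("sd", "x")] == pytest.approx(7.0710678)
    assert out.loc[(4, "PKCi"), ("sd", "x")] == pytest.approx(14.1421356)


# ---------------------------------------------------------------------------
# Z-scores

def test_zscore_closed_form_and_standardization(rng):
    mp = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": rng.uniform(1, 2, 3)})
    z = zscore_by_species(mp)
    assert np.allclose(z["a"], [-1.0, 0.0, 1.0])
    assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=0, ddof=1), 1.0)


def test_zscore_drops_constant_columns():
    mp = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
    z = zscore_by_species(mp)
    assert list(z.columns) == ["a"]
    with pytest.raises(ValueError, match="zero-SD"):
        zscore_by_species(mp, on_zero_sd="error")
    with pytest.raises(ValueError, match="2 samples"):
        zscore_by_species(mp.iloc[:1])


# ---------------------------------------------------------------------------
# clustering

def test_cluster_identical_rows_merge_at_zero():
    mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                       index=["a", "b", "c"])
    res = hierarchical_cluster(mat)
    assert res.linkage[0, 2] == 0.0
    assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}


def test_cluster_three_points_on_a_line():
    mat = pd.DataFrame([[0.0], [1.0], [10.0]])
    res = hierarchical_cluster(mat)
    assert res.linkage[0, 2] == 1.0      # {0,1} merge first
    assert res.linkage[1, 2] == 10.0     # complete linkage: max(9, 10)


def test_cluster_invariant_to_row_permutation(rng):
    data = rng.normal(size=(8, 4))
    mat = pd.DataFrame(data, index=[f"s{i}" for i in range(8)])
    ref = hierarchical_cluster(mat)
    perm = rng.permutation(8)
    permuted = mat.iloc[perm]
    res = hierarchical_cluster(permuted)
    assert np.allclose(sorted(ref.linkage[:, 2]), sorted(res.linkage[:, 2]))
    assert [ref.labels[i] for i in ref.leaf_order] == \
        [res.labels[i] for i in res.leaf_order]


def test_cluster_heights_match_scipy(rng):
    data = rng.normal(size=(10, 5))
    ours = hierarchical_cluster(pd.DataFrame(data))
    theirs = scipy_linkage(data, method="complete", metric="euclidean")
    assert np.allclose(sorted(ours.linkage[:, 2]), sorted(theirs[:, 2]))


def test_cluster_rejects_nan():
    with pytest.raises(ValueError, match="NaN"):
        hierarchical_cluster(pd.DataFrame([[1.0], [np.nan]]))


# ---------------------------------------------------------------------------
# near-zero variance

def test_nzv_constant_removed_spread_retained():
    mat = pd.DataFrame({
        "const": [3.0] * 6,
        "spread": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    })
    reduced, report = remove_near_zero_variance(mat)
    assert report.removed == ["const"]
    assert "zero variance" in report.reasons["const"]
    assert list(reduced.columns) == ["spread"]


def test_nzv_frequency_rule_boundaries(rng):
    # 19-of-20 equal sits exactly on both rule boundaries -> retained;
    # 39-of-40 equal satisfies both strict inequalities -> removed.
    # (behavior cross-checked against the reference R implementation)
    m20 = pd.DataFrame({"a": [1.0] * 19 + [2.0], "b": rng.normal(size=20)})
    _, rep20 = remove_near_zero_variance(m20)
    assert rep20.removed == []
    m40 = pd.DataFrame({"a": [1.0] * 39 + [2.0], "b": rng.normal(size=40)})
    _, rep40 = remove_near_zero_variance(m40)
    assert rep40.removed == ["a"]


def test_nzv_variance_mode():
    mat = pd.DataFrame({"tiny": 1.0 + 1e-9 * np.arange(6.0),
                        "big": np.arange(6.0)})
    _, report = remove_near_zero_variance(mat, mode="variance", var_tol=1e-12)
    assert report.removed == ["tiny"]


# ---------------------------------------------------------------------------
# PCA

def test_pca_two_samples_single_component():
    mat = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], columns=["a", "b"])
    fit = pca(mat, ncomp=1, scale=False)
    assert fit.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_scores_orthogonal(small_matrix):
    fit = pca(small_matrix, ncomp=4, scale=True)
    gram = fit.scores.T @ fit.scores
    off = gram.to_numpy() - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_pca_matches_svd_oracle(small_matrix):
    """Scores/loadings from an independent SVD of the centered, scaled matrix."""
    X = (small_matrix - small_matrix.mean()) / small_matrix.std(ddof=1)
    U, S, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
    expected_scores = U * S
    expected_evr = S ** 2 / np.sum(S ** 2)
    fit = pca(small_matrix, ncomp=3, scale=True)
    for k in range(3):
        assert np.allclose(np.abs(fit.scores.iloc[:, k]),
                           np.abs(expected_scores[:, k]), atol=1e-8)
        assert np.allclose(np.abs(fit.loadings.iloc[:, k]), np.abs(Vt[k]),
                           atol=1e-8)
    assert np.allclose(fit.explained_variance_ratio, expected_evr[:3], atol=1e-10)


def test_pca_full_reconstruction(small_matrix):
    fit = pca(small_matrix, ncomp=4, scale=True)
    X = ((small_matrix - fit.means) / fit.scales).to_numpy()
    recon = fit.scores.to_numpy() @ fit.loadings.to_numpy().T
    assert np.linalg.norm(X - recon) < 1e-8


def test_pca_ncomp_out_of_range(small_matrix):
    with pytest.raises(ValueError, match="ncomp"):
        pca(small_matrix, ncomp=5)  # n-1 = 4
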
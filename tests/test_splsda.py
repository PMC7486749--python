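"""Sparse PLS-DA: oracles, sparsity contracts, deflation, orientation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from lipidisc.splsda import (
    component_loadings,
    dummy_encode,
    fit_splsda,
    orient_component,
)


def frame(X):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])],
                        columns=[f"v{j}" for j in range(X.shape[1])])


def test_dummy_encode():
    d = dummy_encode(["a", "b", "a"])
    assert d.classes == ("a", "b")
    assert np.array_equal(d.dummy, [[1, 0], [0, 1], [1, 0]])
    assert dummy_encode(["d", "c", "b", "a"]).dummy.shape == (4, 4)
    with pytest.raises(ValueError, match="2 distinct"):
        dummy_encode(["a", "a", "a"])


def test_dense_limit_weights_match_cross_covariance(rng):
    """keepX = p, 2 classes: component-1 weights ∝ Xᵀy (centered contrast)."""
    X = frame(rng.normal(size=(6, 10)))
    labels = ["a", "a", "a", "b", "b", "b"]
    model = fit_splsda(X, labels, ncomp=1, keepX=10, scale=False)
    # oracle: direct matrix product on the centered data and centered dummy
    Xc = X - X.mean()
    Y = dummy_encode(labels).dummy
    Yc = Y - Y.mean(axis=0)
    # with q=2 the cross-covariance is rank 1: u ∝ Xcᵀ (Yc v) for any v
    expected = Xc.to_numpy().T @ Yc[:, 0]
    expected = expected / np.linalg.norm(expected)
    got = model.x_weights["comp1"].to_numpy()
    cos = abs(float(got @ expected))
    assert cos > 1 - 1e-10


def test_dense_limit_matches_svd_oracle(rng):
    """comp-1 weights equal the leading right singular vector of Yᵀ X."""
    X = frame(rng.normal(size=(8, 12)))
    labels = ["a", "b", "c", "a", "b", "c", "a", "b"]
    model = fit_splsda(X, labels, ncomp=1, keepX=12, scale=True)
    Xc = (X - X.mean()) / X.std(ddof=1)
    Y = dummy_encode(labels).dummy
    Yc = Y - Y.mean(axis=0)
    _, _, Vt = np.linalg.svd(Yc.T @ Xc.to_numpy())
    cos = abs(float(model.x_weights["comp1"].to_numpy() @ Vt[0]))
    assert cos > 1 - 1e-8


def test_top1_selection_is_argmax_covariance(rng):
    """keepX=1 with one planted informative species: brute-force argmax |cov|."""
    n = 8
    labels = ["a"] * 4 + ["b"] * 4
    X = rng.normal(size=(n, 10))
    X[:4, 3] += 3.0  # planted shift on species 3
    X = frame(X)
    model = fit_splsda(X, labels, ncomp=1, keepX=1, scale=True)
    w = model.x_weights["comp1"]
    assert (w != 0).sum() == 1
    # brute force: covariance of each scaled column with the class contrast
    Xc = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
    y = np.array([1.0] * 4 + [-1.0] * 4)
    assert int(np.argmax(np.abs(Xc.T @ y))) == 3
    assert w.index[w != 0][0] == "v3"


def test_sparsity_contract_exact(rng):
    X = frame(rng.normal(size=(9, 20)))
    labels = ["a", "b", "c"] * 3
    model = fit_splsda(X, labels, ncomp=3, keepX=[5, 7, 20])
    for comp, k in zip(("comp1", "comp2", "comp3"), (5, 7, 20)):
        assert int((model.x_weights[comp] != 0).sum()) == k


def test_keepx_clamped_to_p(rng):
    X = frame(rng.normal(size=(6, 4)))
    model = fit_splsda(X, ["a", "a", "a", "b", "b", "b"], ncomp=1, keepX=250)
    assert model.keepX == (4,)


def test_deflation_orthogonality(rng):
    """Residual X after extraction has ~zero covariance with earlier scores."""
    X = frame(rng.normal(size=(10, 15)))
    labels = ["a", "b"] * 5
    model = fit_splsda(X, labels, ncomp=3, keepX=10)
    T = model.scores.to_numpy()
    gram = T.T @ T
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_permutation_equivariance(rng):
    X = frame(rng.normal(size=(8, 12)))
    labels = ["a", "b", "a", "b", "a", "b", "a", "b"]
    model = fit_splsda(X, labels, ncomp=2, keepX=6)
    perm = rng.permutation(8)
    Xp = X.iloc[perm]
    model_p = fit_splsda(Xp, [labels[i] for i in perm], ncomp=2, keepX=6)
    pd.testing.assert_frame_equal(model.x_weights, model_p.x_weights)
    pd.testing.assert_frame_equal(model.scores.iloc[perm].reset_index(drop=True),
                                  model_p.scores.reset_index(drop=True))


def test_orientation(rng):
    X = frame(rng.normal(size=(6, 8)))
    labels = ["a", "a", "a", "b", "b", "b"]
    model = fit_splsda(X, labels, ncomp=2, keepX=8)
    mask = np.array([lab == "a" for lab in model.labels])
    oriented = orient_component(model, 1, "a")
    assert float(oriented.scores.loc[mask, "comp1"].mean()) >= 0
    again = orient_component(oriented, 1, "a")
    pd.testing.assert_frame_equal(again.scores, oriented.scores)
    # flipping toward the other class negates everything consistently
    other = orient_component(oriented, 1, "b")
    if float(oriented.scores.loc[~mask, "comp1"].mean()) < 0:
        assert np.allclose(other.scores["comp1"], -oriented.scores["comp1"])
        assert np.allclose(other.x_weights["comp1"], -oriented.x_weights["comp1"])
    with pytest.raises(ValueError, match="reference class"):
        orient_component(model, 1, "missing")


def test_component_loadings_reporting(rng):
    X = frame(rng.normal(size=(6, 10)))
    model = fit_splsda(X, ["a", "a", "a", "b", "b", "b"], ncomp=2, keepX=5)
    full, ranked = component_loadings(model, 1)
    assert len(full) == 10 and int((full != 0).sum()) == 5
    assert list(ranked.abs()) == sorted(ranked.abs(), reverse=True)
    _, top3 = component_loadings(model, 1, top=3)
    assert len(top3) == 3
    with pytest.raises(ValueError, match="out of range"):
        component_loadings(model, 4)


def test_input_validation(rng):
    X = frame(rng.normal(size=(6, 5)))
    labels = ["a", "a", "a", "b", "b", "b"]
    with pytest.raises(ValueError, match="at least 3"):
        fit_splsda(X.iloc[:2], ["a", "b"], ncomp=1, keepX=2)
    with pytest.raises(ValueError, match="keepX"):
        fit_splsda(X, labels, ncomp=2, keepX=[3])
    with pytest.raises(ValueError, match="≥ 1"):
        fit_splsda(X, labels, ncomp=2, keepX=[3, 0])
    with pytest.raises(ValueError, match="zero-variance"):
        Xz = X.copy()
        Xz["v0"] = 1.0
        fit_splsda(Xz, labels, ncomp=1, keepX=3)


def test_four_class_separation_recovery():
    """Planted class-specific species at 2× separate all four classes.

    12 samples (3/class), 200 species of which each class owns 8 planted at
    a 2× abundance shift; the silhouette of the true classes on the three
    latent components must exceed 0.5 in every one of 20 seeded runs.
    """
    scores = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n_per, p = 3, 200
        labels = sum(([c] * n_per for c in "abcd"), [])
        log_abund = rng.normal(0.0, 0.3, size=(12, p))
        for k in range(4):
            planted = slice(8 * k, 8 * (k + 1))
            log_abund[n_per * k: n_per * (k + 1), planted] += np.log(2.0)
        pmol = np.exp(log_abund)
        molpct = 100 * pmol / pmol.sum(axis=1, keepdims=True)
        model = fit_splsda(frame(molpct), labels, ncomp=3, keepX=250)
        scores.append(silhouette_score(model.scores.to_numpy(), labels))
    assert min(scores) > 0.5
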
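"""PCA, OPLS-DA, VIP and permutation validation.

The oracle checks use scikit-learn decompositions as the independent
implementation: exact-SVD PCA against sklearn.decomposition.PCA, and the
0-orthogonal-component OPLS-DA (a plain PLS2-DA) against
sklearn.cross_decomposition.PLSRegression on identically prepared matrices.
"""

import numpy as np
import pandas as pd
import pytest

import flavoromics as fl
from flavoromics.multivariate import (
    _dummy,
    fit_oplsda,
    pca,
    permutation_test,
    predict,
    scale_matrix,
    to_matrix,
    vip,
)
from flavoromics.synthetic import SimulationConfig, default_enose_profile

from conftest import flat_table


def _three_group_data(seed=0, n_per=6, p=8, sep=3.0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["a", "b", "c"], n_per)
    centers = rng.normal(0, sep, (3, p))
    X = np.vstack([rng.normal(centers[i], 1.0, (n_per, p)) for i in range(3)])
    return X, y


def _separable_table(seed):
    """All 17 variables group-structured (each with its own breakpoint)."""
    base = flat_table(17)
    sim = fl.simulate_replicates(SimulationConfig(means=base, n_replicates=3,
                                                  seed=seed))
    return fl.inject_discrimination(sim, [f"V{i:02d}" for i in range(17)], 5.0)


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_matrix():
    t = np.linspace(-1, 1, 10)
    X = np.outer(t, [1.0, 2.0, -0.5])
    m = pca(X, 2)
    assert m.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_full_reconstruction():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (10, 5))
    m = pca(X, 5)
    recon = m.scores @ m.loadings.T * m.scale + m.mean
    assert np.abs(recon - X).max() < 1e-10
    assert np.allclose(m.loadings.T @ m.loadings, np.eye(5), atol=1e-8)


def test_pca_constant_matrix_errors():
    with pytest.raises(fl.ValidationError, match="variance"):
        pca(np.ones((6, 3)), 2)


def test_pca_component_budget():
    with pytest.raises(fl.ValidationError):
        pca(np.random.default_rng(0).normal(size=(4, 10)), 4)


def test_pca_matches_sklearn_oracle():
    from sklearn.decomposition import PCA as SkPCA

    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (12, 6))
    mine = pca(X, 4)
    sk = SkPCA(n_components=4).fit(X)
    assert np.allclose(mine.explained_variance_ratio,
                       sk.explained_variance_ratio_, atol=1e-10)
    for k in range(4):
        s = np.sign(mine.loadings[:, k] @ sk.components_[k])
        assert np.abs(mine.loadings[:, k] - s * sk.components_[k]).max() < 1e-6


def test_pca_separates_enose_profiles(fx):
    """Two well-separated sensor profiles put >85% of the variance on the
    first two components."""
    prof = default_enose_profile()
    low, high = prof["A"].copy(), prof["D"] * 1.5
    for g, v in [("A", low), ("B", low), ("C", low), ("D", high), ("E", high)]:
        prof[g] = v
    cfg = SimulationConfig(means=fx.faa_table, seed=0, enose_profile=prof)
    X, _ = to_matrix(fl.simulate_enose(cfg))
    m = pca(X, 2, scaling="unit_variance")
    assert m.explained_variance_ratio.sum() > 0.85


# ---------------------------------------------------------------------------
# OPLS-DA


def test_plsda_matches_sklearn_oracle():
    from sklearn.cross_decomposition import PLSRegression

    X, y = _three_group_data()
    Xs, _ = scale_matrix(X, "unit_variance")
    Y, _ = _dummy(y)
    m = fit_oplsda(Xs, y, n_orthogonal=0, cv_folds=None, seed=0,
                   scaling="none", n_predictive=2)
    sk = PLSRegression(n_components=2, scale=False, tol=1e-10,
                       max_iter=10000).fit(Xs, Y - Y.mean(axis=0))
    mine, _ = predict(m, Xs)
    theirs = sk.predict(Xs) + Y.mean(axis=0)
    assert np.abs(mine - theirs).max() < 1e-8


def test_single_class_rejected():
    X = np.random.default_rng(0).normal(size=(6, 3))
    with pytest.raises(fl.ValidationError, match="2 groups"):
        fit_oplsda(X, np.repeat("a", 6), cv_folds=None)


def test_stratification_error():
    X, y = _three_group_data(n_per=3)
    with pytest.raises(fl.ValidationError, match="stratification"):
        fit_oplsda(X, y, cv_folds=5)


def test_score_orthogonality_invariants():
    X, y = to_matrix(_separable_table(11))
    m = fit_oplsda(X, y, n_orthogonal=2, cv_folds=3, seed=1)
    Y, _ = _dummy(np.asarray(y))
    Yc = Y - Y.mean(axis=0)
    # orthogonal scores carry no class information
    assert np.abs(m.ortho_scores.T @ Yc).max() < 1e-8
    # predictive and orthogonal scores mutually orthogonal
    both = np.column_stack([m.scores, m.ortho_scores])
    G = both.T @ both
    assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
    # predictive weights unit norm
    assert np.allclose(np.linalg.norm(m.weights, axis=0), 1.0, atol=1e-10)


@pytest.mark.parametrize("seed", [3, 17, 42])
def test_q2_bounded_by_r2y(seed):
    X, y = to_matrix(_separable_table(seed))
    m = fit_oplsda(X, y, n_orthogonal=1, cv_folds=3, seed=seed)
    assert m.q2 <= m.r2y + 1e-8


def test_strong_separation_gives_high_q2():
    """Fully group-structured triplicate data reaches the Q2 magnitude a
    supervised model shows on real cooking-time volatile profiles."""
    q2s = []
    for seed in (97, 194, 291, 388, 485):
        X, y = to_matrix(_separable_table(seed))
        q2s.append(fit_oplsda(X, y, n_orthogonal=1, cv_folds=3, seed=seed).q2)
    assert np.median(q2s) > 0.9


def test_vip_uniform_for_identical_variables():
    rng = np.random.default_rng(5)
    col = np.repeat([0.0, 3.0, 6.0], 4) + rng.normal(0, 0.5, 12)
    X = np.column_stack([col] * 6)  # all variables identical
    y = np.repeat(["a", "b", "c"], 4)
    m = fit_oplsda(X, y, n_orthogonal=0, cv_folds=None, seed=0)
    assert np.allclose(m.vip, 1.0, atol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_vip_mean_square_identity(seed):
    X, y = to_matrix(_separable_table(seed))
    m = fit_oplsda(X, y, n_orthogonal=1, cv_folds=None, seed=seed)
    assert np.mean(m.vip**2) == pytest.approx(1.0, abs=1e-8)


def test_single_shifted_analyte_ranks_first():
    base = flat_table(17)
    sim = fl.simulate_replicates(SimulationConfig(means=base, n_replicates=8,
                                                  seed=42))
    X, y = to_matrix(fl.inject_discrimination(sim, ["V09"], 5.0))
    v = vip(fit_oplsda(X, y, cv_folds=None, seed=0))
    assert v.idxmax() == "V09"


def test_two_of_twenty_recovery_rate():
    """Binary-design recovery: the two shifted variables, and only they,
    exceed VIP 1 in at least 90% of 50 seeded runs."""
    base = flat_table(20, groups="AB")
    targets = ["V03", "V12"]
    ok = 0
    for s in range(50):
        sim = fl.simulate_replicates(SimulationConfig(means=base,
                                                      n_replicates=50,
                                                      seed=3000 + s))
        X, y = to_matrix(fl.inject_discrimination(sim, targets, 5.0))
        v = vip(fit_oplsda(X, y, cv_folds=None, seed=s))
        if (v[targets] > 1).all() and (v.drop(targets) <= 1).all():
            ok += 1
    assert ok >= 45


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_determinism():
    X, y = to_matrix(_separable_table(7))
    kw = dict(n_permutations=25, seed=4, cv_folds=3)
    a = permutation_test(X, y, **kw)
    b = permutation_test(X, y, **kw)
    assert np.array_equal(a.q2_perm, b.q2_perm)
    assert np.array_equal(a.r2y_perm, b.r2y_perm)


def test_permutation_warns_when_few():
    X, y = _three_group_data()
    with pytest.warns(UserWarning, match="permutations"):
        permutation_test(X, y, n_permutations=5, seed=0, cv_folds=3)


def test_structured_data_beats_permuted_null():
    X, y = to_matrix(_separable_table(97))
    p = permutation_test(X, y, n_permutations=50, seed=1, cv_folds=3)
    assert p.q2 > np.quantile(p.q2_perm, 0.95)
    assert p.q2 > p.q2_intercept  # validation-plot sanity


def test_noise_data_has_negative_permuted_q2():
    rng = np.random.default_rng(8)
    X = rng.normal(0, 1, (15, 17))
    y = np.repeat(list("ABCDE"), 3)
    p = permutation_test(X, y, n_permutations=50, seed=2, cv_folds=3)
    assert np.median(p.q2_perm) <= 0
    # the unpermuted fit is indistinguishable from the null
    assert p.q2 < np.quantile(p.q2_perm, 0.95)


def test_model_json_export(tmp_path):
    import json

    X, y = to_matrix(_separable_table(5))
    m = fit_oplsda(X, y, n_orthogonal=1, cv_folds=3, seed=5)
    p = tmp_path / "model.json"
    m.to_json(p)
    doc = json.loads(p.read_text())
    assert doc["Q2"] == m.q2
    assert set(doc["vip"]) == set(m.variables)
    assert len(doc["scores"]) == X.shape[0]


def test_auto_orthogonal_selection():
    X, y = to_matrix(_separable_table(13))
    m = fit_oplsda(X, y, n_orthogonal="auto", cv_folds=3, seed=3)
    fixed = [fit_oplsda(X, y, k, cv_folds=3, seed=3).q2 for k in range(4)]
    assert m.q2 == max(fixed)
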
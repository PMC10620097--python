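"""Voxel-wise encoding, noise-ceiling correction and RSA."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

import metamerlab as ml
from metamerlab.encoding import RIDGE_GRID, train_test_splits
from metamerlab.signals import ValidationError


def test_lambda_grid_is_81_powers_of_ten():
    grid = ml.ridge_lambda_grid()
    assert len(grid) == 81
    np.testing.assert_allclose(np.log10(grid), np.arange(-40, 41))


def test_reliability_floors_reproduce_printed_values():
    assert ml.critical_pearson(83) == pytest.approx(0.182, abs=5e-4)
    assert ml.critical_pearson(82) == pytest.approx(0.183, abs=5e-4)
    with pytest.raises(ValidationError):
        ml.critical_pearson(2)


@pytest.mark.parametrize("r,n,expected", [
    (1.0, 3, 1.0), (1.0, 2, 1.0), (0.0, 3, 0.0), (0.5, 3, 0.75), (0.5, 2, 2 / 3),
])
def test_spearman_brown(r, n, expected):
    assert ml.spearman_brown(r, n) == pytest.approx(expected)


def test_spearman_brown_validation():
    with pytest.raises(ValidationError):
        ml.spearman_brown(-1.0, 3)


@pytest.mark.parametrize("seed,n,p", [(0, 8, 3), (1, 12, 5), (2, 10, 15)])
def test_loo_matches_explicit_refits(seed, n, p):
    """Closed-form LOO errors equal brute-force leave-one-out ridge refits."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    grid = np.array([1e-4, 1e-2, 1.0, 1e2])
    fit = ml.ridge_loo_select(X, y, grid)
    explicit = np.zeros((len(grid), n))
    for li, lam in enumerate(grid):
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            model = Ridge(alpha=lam, fit_intercept=True).fit(X[tr], y[tr])
            explicit[li, i] = y[i] - model.predict(X[i:i + 1])[0]
    np.testing.assert_allclose(fit["loo_mse"], np.mean(explicit ** 2, axis=1),
                               atol=1e-8)


def test_noiseless_selects_smallest_lambda():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 10))
    w = rng.normal(size=10)
    y = X @ w + 1.0
    fit = ml.ridge_loo_select(X, y)
    assert fit["lambda"] == RIDGE_GRID[0]
    te = rng.normal(size=(30, 10))
    pred = te @ fit["weights"] + fit["intercept"]
    truth = te @ w + 1.0
    r2 = np.corrcoef(pred, truth)[0, 1] ** 2
    assert r2 > 0.999


def test_pure_noise_selects_large_lambda():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 30))
    y = rng.normal(size=40)
    fit = ml.ridge_loo_select(X, y)
    assert fit["lambda"] >= 1.0
    te_pred = rng.normal(size=(40, 30)) @ fit["weights"] + fit["intercept"]
    assert np.var(te_pred) < np.var(y)  # heavy shrinkage toward the mean


def test_loo_validation():
    with pytest.raises(ValidationError):
        ml.ridge_loo_select(np.ones((2, 3)), np.ones(2))
    X = np.ones((5, 2))
    y = np.array([1.0, np.nan, 0, 0, 0])
    with pytest.raises(ValidationError):
        ml.ridge_loo_select(X, y)


def _linear_voxels(rng, n_stim=40, n_feat=12, n_vox=6, noise=0.0, n_scans=3):
    X = rng.normal(size=(n_stim, n_feat))
    W = rng.uniform(0.2, 1.0, size=(n_feat, n_vox))
    signal = X @ W
    signal = (signal - signal.mean(0)) / signal.std(0)
    V = signal[:, :, None] + rng.normal(0, noise, (n_stim, n_vox, n_scans))
    return X, V


def test_pipeline_perfect_reliability_reduces_to_r2():
    """Noise-free scans: r'_v = r'_v̂ = 1 exactly, so r²* = r²."""
    rng = np.random.default_rng(5)
    X, V = _linear_voxels(rng, noise=0.0)
    score = ml.corrected_variance_pipeline(X, V, n_splits=4, seed=0)
    np.testing.assert_allclose(score.r_v, 1.0)
    np.testing.assert_allclose(score.r_vhat, 1.0)
    np.testing.assert_allclose(score.r2_corrected, score.r2)
    assert np.all(score.r2 > 0.999)


def test_pipeline_floors_low_reliability():
    """Voxels that are pure noise get their reliability floored, keeping the
    corrected variance denominator bounded away from zero."""
    rng = np.random.default_rng(6)
    n_stim = 40
    X = rng.normal(size=(n_stim, 8))
    V = rng.normal(size=(n_stim, 5, 3))  # no signal at all
    score = ml.corrected_variance_pipeline(X, V, n_splits=4, seed=1)
    splits = train_test_splits(n_stim, 4, 1)
    floor_v = ml.critical_pearson(len(splits[0][0]))
    floor_vh = ml.critical_pearson(len(splits[0][1]))
    assert np.all(score.r_v >= floor_v - 1e-12)
    assert np.all(score.r_vhat >= floor_vh - 1e-12)
    assert np.all(score.r2_corrected < 0.5)


def test_pipeline_validation():
    X = np.zeros((10, 3))
    with pytest.raises(ValidationError):
        ml.corrected_variance_pipeline(X, np.zeros((9, 4, 3)))
    with pytest.raises(ValidationError):
        ml.corrected_variance_pipeline(X, np.zeros((10, 4, 1)))


def test_best_stage_agreement_and_masking():
    S = np.array([[0.1, 0.9, 0.3],
                  [0.2, 0.8, 0.4],
                  [0.15, 0.85, 0.2]])
    res = ml.best_stage_cross_validated(S, ["a", "b", "c"])
    assert res["modal_stage_name"] == "b"
    np.testing.assert_array_equal(res["chosen_stage"], [1, 1, 1])
    np.testing.assert_allclose(res["per_participant"], S[:, 1])
    # masking: a participant whose own favorite differs still gets the
    # stage chosen by the others
    S2 = np.array([[0.0, 1.0], [0.9, 0.1], [0.9, 0.1], [0.9, 0.1]])
    res2 = ml.best_stage_cross_validated(S2)
    assert res2["chosen_stage"][0] == 0  # others prefer stage 0
    assert res2["per_participant"][0] == pytest.approx(0.0)


def test_best_stage_needs_two_participants():
    with pytest.raises(ValidationError):
        ml.best_stage_cross_validated(np.ones((1, 3)))


def test_rdm_basic_properties():
    rng = np.random.default_rng(7)
    R = rng.normal(size=(12, 9))
    rdm = ml.compute_rdm(R)
    np.testing.assert_allclose(rdm, rdm.T, atol=1e-12)
    np.testing.assert_allclose(np.diagonal(rdm), 0.0, atol=1e-12)
    assert rdm.min() >= -1e-12 and rdm.max() <= 2 + 1e-12
    # identical patterns -> 0; anticorrelated -> 2
    R2 = np.vstack([R[0], R[0], -R[0]])
    rdm2 = ml.compute_rdm(R2)
    assert rdm2[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert rdm2[0, 2] == pytest.approx(2.0, abs=1e-12)


def test_rdm_drops_zero_variance_units():
    rng = np.random.default_rng(8)
    R = rng.normal(size=(6, 4))
    R[:, 2] = 5.0
    rdm = ml.compute_rdm(R)
    R_kept = np.delete(R, 2, axis=1)
    np.testing.assert_allclose(rdm, ml.compute_rdm(R_kept))


def test_rdm_similarity_identity_and_ceiling():
    """A participant whose responses equal a stage's features scores test
    ρ = 1 on that stage; identical participants give ceiling 1."""
    rng = np.random.default_rng(9)
    feats = {"s1": rng.normal(size=(24, 10)), "s2": rng.normal(size=(24, 10))}
    parts = [feats["s2"].copy(), feats["s2"].copy()]
    res = ml.rdm_similarity_cv(feats, parts, n_splits=4, seed=0)
    assert res["chosen_stage"] == ["s2", "s2"]
    np.testing.assert_allclose(res["per_participant_rho"], 1.0, atol=1e-12)
    np.testing.assert_allclose(res["ceiling"], 1.0, atol=1e-12)


def test_rdm_similarity_recovers_generating_geometry():
    rng = np.random.default_rng(10)
    feats = {"s1": rng.normal(size=(30, 8)), "s2": rng.normal(size=(30, 8))}
    parts = [feats["s1"] + rng.normal(0, 0.3, (30, 8)) for _ in range(3)]
    res = ml.rdm_similarity_cv(feats, parts, n_splits=5, seed=1)
    assert res["chosen_stage"] == ["s1", "s1", "s1"]
    assert res["mean_rho"] > 0.3


def test_split_proportions_scale():
    for n in (165, 60, 40):
        tr, te = train_test_splits(n, 1, 0)[0]
        assert len(tr) + len(te) == n
        assert abs(len(tr) / n - 83 / 165) < 0.05
    tr, te = train_test_splits(165, 1, 0)[0]
    assert len(tr) == 83 and len(te) == 82
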
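"""PLS-DA screening: NIPALS, VIP, sevenfold Q2 and the differential rule."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from metabofe.exceptions import ConfigurationError, InputError, StratificationError
from metabofe.plsda import (
    PLSDA,
    autoscale,
    call_differentials,
    compute_vip,
    q2_sevenfold,
    student_t_per_feature,
)


def _two_class_data(n=24, p=10, effect=3.0, seed=0, n_signal=2):
    rng = np.random.default_rng(seed)
    y = np.array(["lean", "fat"] * (n // 2))
    X = rng.standard_normal((n, p))
    X[y == "fat", :n_signal] += effect
    return X, y


# ---------------------------------------------------------------- autoscale


def test_autoscale_centers_and_scales_to_unit_variance():
    rng = np.random.default_rng(1)
    X = rng.normal(50.0, 9.0, size=(30, 4))
    Xs, mean, scale, kept = autoscale(X)
    assert kept.all()
    np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, rtol=1e-12)


def test_autoscale_two_point_column_uses_sample_sd():
    Xs, *_ = autoscale(np.array([[1.0], [3.0]]))
    # sample SD (ddof=1) of (1, 3) is sqrt(2): scaled values +/- 1/sqrt(2)
    np.testing.assert_allclose(Xs.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])


def test_autoscale_drops_constant_columns_with_warning():
    X = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.warns(UserWarning, match="constant"):
        Xs, mean, scale, kept = autoscale(X)
    assert kept.tolist() == [False, True]
    assert Xs.shape == (5, 1)


def test_autoscale_needs_two_samples():
    with pytest.raises(InputError):
        autoscale(np.ones((1, 3)))


# ------------------------------------------------------------------- NIPALS


def test_single_component_matches_hand_nipals():
    # one NIPALS pass done by hand: w = X'y / ||X'y||, t = X w
    X = np.array([[1.0, 0.0, 2.0], [2.0, 1.0, 0.0], [3.0, 2.0, 1.0], [4.0, 3.0, 3.0]])
    y = np.array(["a", "a", "b", "b"])
    model = PLSDA(n_components=1, scale=False).fit(X, y)
    Xc = X - X.mean(axis=0)
    y_coded = np.array([-1.0, -1.0, 1.0, 1.0])
    w_hand = Xc.T @ y_coded
    w_hand /= np.linalg.norm(w_hand)
    t_hand = Xc @ w_hand
    np.testing.assert_allclose(model.x_weights_[:, 0], w_hand, atol=1e-12)
    np.testing.assert_allclose(model.x_scores_[:, 0], t_hand, atol=1e-12)


def test_scores_of_successive_components_are_orthogonal():
    X, y = _two_class_data(seed=2)
    model = PLSDA(n_components=3).fit(X, y)
    gram = model.x_scores_.T @ model.x_scores_
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-9


def test_perfect_single_feature_separation_gives_full_r2y():
    y = np.array(["lean", "fat"] * 10)
    x0 = np.where(y == "fat", 1.0, -1.0) * 3.7 + 0.4
    model = PLSDA(n_components=1).fit(x0[:, None], y)
    assert model.r2y_ == pytest.approx(1.0, abs=1e-9)


def test_r2_nondecreasing_in_components():
    X, y = _two_class_data(seed=4)
    model = PLSDA(n_components=4).fit(X, y)
    assert np.all(np.diff(model.r2x_per_component_) >= -1e-12)
    assert np.all(np.diff(model.r2y_per_component_) >= -1e-12)


def test_matches_sklearn_pls_regression():
    # independent implementation check: same latent model, same predictions
    X, y = _two_class_data(seed=5, p=8)
    model = PLSDA(n_components=3).fit(X, y)
    y_coded = np.where(y == model.classes_[1], 1.0, -1.0)
    sk = PLSRegression(n_components=3, scale=True).fit(X, y_coded)
    np.testing.assert_allclose(
        model.decision_function(X), sk.predict(X).ravel(), atol=1e-10
    )


def test_label_swap_negates_scores_keeps_vip_and_p():
    X, y = _two_class_data(seed=6)
    m1 = PLSDA(n_components=2).fit(X, y)
    swapped = np.where(y == "lean", "a", "z")  # the +1-coded class flips to fat
    m2 = PLSDA(n_components=2).fit(X, swapped)
    np.testing.assert_allclose(m1.x_scores_[:, 0], -m2.x_scores_[:, 0], atol=1e-9)
    np.testing.assert_allclose(m1.vip_, m2.vip_, atol=1e-9)
    _, p1 = student_t_per_feature(X, y)
    _, p2 = student_t_per_feature(X, swapped)
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_single_class_and_oversized_components_rejected():
    X, y = _two_class_data()
    with pytest.raises(InputError):
        PLSDA(n_components=1).fit(X, np.repeat("lean", len(y)))
    with pytest.raises(ConfigurationError):
        PLSDA(n_components=100).fit(X, y)


# ---------------------------------------------------------------------- VIP


def test_vip_all_equal_weights_gives_unit_vip():
    # both features carry the identical signal, so |w| is equal and symmetry
    # forces VIP = 1 everywhere (and sum VIP^2 = p)
    y = np.array(["lean", "fat"] * 8)
    x0 = np.where(y == "fat", 1.0, -1.0)
    rng = np.random.default_rng(7)
    noise = rng.standard_normal(16) * 1e-9
    X = np.column_stack([x0 + noise, x0 - noise])
    model = PLSDA(n_components=1).fit(X, y)
    np.testing.assert_allclose(model.vip_, 1.0, atol=1e-6)


def test_vip_matches_direct_formula_evaluation():
    X, y = _two_class_data(seed=8, p=3)
    model = PLSDA(n_components=2).fit(X, y)
    w, t, b = model.x_weights_, model.x_scores_, model.y_loadings_
    ssy = b**2 * (t * t).sum(axis=0)
    expected = np.sqrt(3 * ((w**2) @ ssy) / ssy.sum())
    np.testing.assert_allclose(compute_vip(model), expected, atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("n_components", [1, 2, 3])
def test_vip_squares_sum_to_feature_count(seed, n_components):
    X, y = _two_class_data(seed=seed, p=12)
    model = PLSDA(n_components=n_components).fit(X, y)
    assert (model.vip_**2).sum() == pytest.approx(12.0, abs=1e-8)


# ------------------------------------------------------------------ t-tests


def test_t_test_identical_samples_gives_p_one():
    X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
    t, p = student_t_per_feature(X, np.array(["a", "a", "a", "b", "b", "b"]))
    assert t[0] == pytest.approx(0.0)
    assert p[0] == pytest.approx(1.0)


def test_t_test_matches_pooled_variance_hand_computation():
    # groups (1,2,3) vs (4,5,6): pooled s^2 = 1, t = -3 / sqrt(2/3), df = 4
    X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
    t, p = student_t_per_feature(X, np.array(["a", "a", "a", "b", "b", "b"]))
    from scipy import stats

    t_hand = -3.0 * np.sqrt(3.0 / 2.0)
    assert t[0] == pytest.approx(t_hand, rel=1e-12)
    assert p[0] == pytest.approx(2 * stats.t.sf(abs(t_hand), df=4), rel=1e-12)


def test_t_test_needs_two_per_group():
    with pytest.raises(InputError):
        student_t_per_feature(np.ones((3, 1)), np.array(["a", "b", "b"]))


# ----------------------------------------------------------------------- Q2


def test_q2_near_one_for_noiseless_separation_and_below_r2y():
    X, y = _two_class_data(n=28, p=5, effect=20.0, seed=9)
    q2 = q2_sevenfold(X, y, n_components=2, seed=0)
    model = PLSDA(n_components=2).fit(X, y)
    assert q2 >= 0.99
    assert q2 <= model.r2y_ + 1e-9


def test_q2_nonpositive_in_expectation_under_the_null():
    # pure-noise X: held-out prediction cannot beat the training mean
    rng = np.random.default_rng(10)
    y = np.array(["lean", "fat"] * 35)
    q2s = [
        q2_sevenfold(rng.standard_normal((70, 20)), y, n_components=2, seed=s)
        for s in range(10)
    ]
    assert np.mean(q2s) < 0.0


def test_q2_deterministic_for_fixed_seed_and_stratification_guard():
    X, y = _two_class_data(n=28, seed=11)
    assert q2_sevenfold(X, y, seed=3) == q2_sevenfold(X, y, seed=3)
    unbalanced = y.copy()
    unbalanced[:] = "lean"
    unbalanced[0] = "fat"  # a single fat bird cannot reach every training fold
    with pytest.raises((StratificationError, InputError)):
        q2_sevenfold(X, unbalanced, seed=0)


# ------------------------------------------------------------ differentials


@pytest.mark.parametrize(
    "vip, p, expected",
    [
        (1.2, 0.01, True),
        (1.0, 0.001, False),  # VIP boundary is strict
        (2.0, 0.05, False),  # p boundary is strict
    ],
)
def test_differential_rule_is_strict(vip, p, expected):
    calls = call_differentials(["f"], [vip], [p], mean_fat=[2.0], mean_lean=[1.0])
    assert bool(calls["is_differential"].iloc[0]) is expected
    assert calls["direction"].iloc[0] == "higher-in-fat"


def test_differential_misaligned_inputs_rejected():
    with pytest.raises(InputError):
        call_differentials(["f"], [1.0, 2.0], [0.01], [1.0], [2.0])
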
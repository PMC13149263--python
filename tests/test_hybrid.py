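"""Splitting, base models, convex combination and the weight grid search."""

import numpy as np
import pandas as pd
import pytest

import riskstrat.hybrid as hy
from conftest import fast_config


def banded_data(n=300, seed=0, margin=2.0):
    """Three linearly separable bands along one direction."""
    rng = np.random.default_rng(seed)
    per = n // 3
    X = rng.normal(size=(n, 2))
    y = np.repeat([0, 1, 2], per)
    X[:, 0] += y * margin * 2
    return X, y


def xor_band_data(n=600, seed=0):
    """Class depends on an XOR of two sign bands: unlearnable linearly."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
    return X, y


# --------------------------------------------------------------------- split


def test_balanced_split_arithmetic():
    labels = np.repeat([0, 1, 2], 100)
    plan = hy.make_split(labels, ratio=0.7, seed=0)
    assert len(plan.train_indices) == 210 and len(plan.test_indices) == 90
    for c in (0, 1, 2):
        assert (labels[plan.train_indices] == c).sum() == 70


def test_split_deterministic_under_seed():
    labels = np.repeat([0, 1, 2], 50)
    a = hy.make_split(labels, seed=3)
    b = hy.make_split(labels, seed=3)
    np.testing.assert_array_equal(a.train_indices, b.train_indices)
    np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)


def test_split_respects_unbalanced_strata():
    labels = np.repeat([0, 1, 2], [500, 300, 200])
    plan = hy.make_split(labels, ratio=0.7, seed=1)
    counts = [(labels[plan.train_indices] == c).sum() for c in (0, 1, 2)]
    for got, want in zip(counts, (350, 210, 140)):
        assert abs(got - want) <= 1


def test_split_rejects_tiny_class_by_name():
    labels = np.array([0] * 50 + [1] * 50 + [2] * 3)
    with pytest.raises(ValueError, match="2"):
        hy.make_split(labels, ratio=0.7, seed=0, folds=5)


def test_split_partitions_are_disjoint_and_exhaustive():
    labels = np.repeat([0, 1], 60)
    plan = hy.make_split(labels, seed=5)
    joined = np.sort(np.concatenate([plan.train_indices, plan.test_indices]))
    np.testing.assert_array_equal(joined, np.arange(120))


# --------------------------------------------------------------- base models


def test_linear_model_separates_margin_bands():
    X, y = banded_data(seed=1)
    linear, _ = hy.fit_base_models(X, y, fast_config(), seed=1)
    assert (linear.predict(X) == y).mean() >= 0.95


def test_single_class_input_rejected():
    X = np.zeros((20, 2))
    with pytest.raises(ValueError, match="single class"):
        hy.fit_base_models(X, np.zeros(20, dtype=int), fast_config(), seed=0)


def test_forest_deterministic_under_seed():
    X, y = banded_data(seed=2)
    probe = np.linspace(-2, 8, 30).reshape(-1, 2)
    _, f1 = hy.fit_base_models(X, y, fast_config(), seed=7)
    _, f2 = hy.fit_base_models(X, y, fast_config(), seed=7)
    np.testing.assert_array_equal(f1.predict_proba(probe), f2.predict_proba(probe))


# ------------------------------------------------------------------- combine


def test_combine_endpoint_returns_first_model():
    P1 = np.array([[0.7, 0.2, 0.1]])
    P2 = np.array([[0.1, 0.1, 0.8]])
    combined, pred, R = hy.combine(P1, P2, w=1.0)
    np.testing.assert_array_equal(combined, P1)
    assert pred[0] == 0


def test_combine_midpoint_arithmetic_and_expected_class():
    combined, pred, R = hy.combine(
        np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 0.0, 1.0]]), w=0.5
    )
    np.testing.assert_allclose(combined, [[0.5, 0.0, 0.5]])
    assert R[0] == pytest.approx(1.0)
    assert pred[0] == 0  # argmax tie resolves to the lower class


def test_combined_rows_remain_distributions_and_bounded():
    rng = np.random.default_rng(3)
    P1 = rng.dirichlet(np.ones(3), size=50)
    P2 = rng.dirichlet(np.ones(3), size=50)
    for w in (0.0, 0.3, 0.9):
        combined, _, _ = hy.combine(P1, P2, w)
        np.testing.assert_allclose(combined.sum(axis=1), 1.0, atol=1e-9)
        assert (combined >= np.minimum(P1, P2) - 1e-12).all()
        assert (combined <= np.maximum(P1, P2) + 1e-12).all()


def test_combine_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shapes"):
        hy.combine(np.ones((2, 3)) / 3, np.ones((2, 2)) / 2, 0.5)


# ------------------------------------------------------------- weight search


def test_xor_band_structure_selects_pure_nonlinear():
    X, y = xor_band_data(seed=4)
    result = hy.search_weights(
        X, y, grid=(0.0, 0.5, 1.0), seed=4, config=fast_config(), C=1.0
    )
    assert result.best_w == 0.0  # all weight on the forest


def test_singleton_grid_needs_no_search():
    X, y = banded_data(seed=5)
    result = hy.search_weights(X, y, grid=(0.3,), seed=5, config=fast_config(), C=1.0)
    assert result.best_w == 0.3


def test_weight_tie_breaks_toward_larger_nonlinear_share():
    # constant losses across the grid must return the smallest w
    order = np.lexsort((np.array([0.0, 0.5, 1.0]), np.zeros(3)))
    assert [0.0, 0.5, 1.0][order[0]] == 0.0
    # end-to-end: duplicate candidates in the grid give identical losses
    X, y = banded_data(seed=6)
    result = hy.search_weights(
        X, y, grid=(0.7, 0.7), seed=6, config=fast_config(), C=1.0
    )
    assert result.best_w == 0.7
    np.testing.assert_allclose(result.mean_loss[0], result.mean_loss[1])


def test_invalid_grid_rejected():
    X, y = banded_data()
    with pytest.raises(ValueError, match="grid"):
        hy.search_weights(X, y, grid=(1.2,), config=fast_config(), C=1.0)


# ------------------------------------------------------------- fitted model


@pytest.fixture(scope="module")
def fitted_hybrid():
    X, y = banded_data(n=450, seed=8)
    frame = pd.DataFrame(X, columns=["s1", "s2"])
    model = hy.HybridModel(config=fast_config(weight_grid=(0.0, 0.5, 1.0)), seed=8)
    model.fit(frame, y)
    return model, frame, y


def test_weight_vector_is_on_the_simplex(fitted_hybrid):
    model, _, _ = fitted_hybrid
    w = model.weights
    assert w.sum() == pytest.approx(1.0) and (w >= 0).all()


def test_degenerate_grids_reproduce_pure_base_models():
    X, y = banded_data(n=300, seed=9)
    frame = pd.DataFrame(X, columns=["s1", "s2"])
    for grid, attr in (((1.0,), "linear_"), ((0.0,), "forest_")):
        model = hy.HybridModel(config=fast_config(weight_grid=grid), seed=9)
        model.fit(frame, y)
        np.testing.assert_array_equal(
            model.predict(frame), getattr(model, attr).predict(X)
        )
        np.testing.assert_allclose(
            model.predict_proba(frame), getattr(model, attr).predict_proba(X)
        )


def test_training_accuracy_tracks_cv_estimate(fitted_hybrid):
    model, frame, y = fitted_hybrid
    cv_f1 = max(model.training_metadata["cv_mean_f1_macro"])
    train_acc = (model.predict(frame) == y).mean()
    assert train_acc >= cv_f1 - 0.05


def test_predict_is_column_order_invariant(fitted_hybrid):
    model, frame, _ = fitted_hybrid
    permuted = frame[["s2", "s1"]]
    np.testing.assert_array_equal(model.predict(frame), model.predict(permuted))


def test_single_record_probability_row_sums_to_one(fitted_hybrid):
    model, frame, _ = fitted_hybrid
    proba = model.predict_proba(frame.iloc[[0]])
    assert proba.shape[0] == 1
    assert proba.sum() == pytest.approx(1.0)


def test_unfitted_model_refuses_to_predict():
    model = hy.HybridModel()
    with pytest.raises(ValueError, match="not fitted"):
        model.predict(np.zeros((1, 2)))


def test_model_archive_round_trip(tmp_path, fitted_hybrid):
    model, frame, _ = fitted_hybrid
    path = tmp_path / "model.joblib"
    model.save(path)
    loaded = hy.HybridModel.load(path)
    np.testing.assert_allclose(loaded.predict_proba(frame), model.predict_proba(frame))
    assert loaded.w_ == model.w_
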
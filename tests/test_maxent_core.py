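"""Feature expansion, convex fitting, KKT certificates, predictions, gain."""

import numpy as np
import pandas as pd
import pytest

from cnm.maxent_core import (
    MaxentModel,
    build_features,
    default_betas,
    fit_maxent,
    predict_raw,
    response_curve,
    to_logistic,
    training_gain,
)


def rng_tables(seed, n_pres=40, n_bg=300, k=2):
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(k)]
    bg = pd.DataFrame(rng.normal(size=(n_bg, k)), columns=names)
    pres = pd.DataFrame(
        rng.normal(loc=0.8, size=(n_pres, k)), columns=names
    )
    return pres, bg


def newton_gibbs_moment(f_bg, target, tol=1e-12):
    """1-D Newton oracle: solve E_q[f] = target for q prop to exp(lam*f)."""
    lam = 0.0
    for _ in range(200):
        w = np.exp(lam * f_bg - np.max(lam * f_bg))
        q = w / w.sum()
        mean = float(q @ f_bg)
        var = float(q @ (f_bg - mean) ** 2)
        step = (target - mean) / var
        lam += step
        if abs(step) < tol:
            break
    return lam


# -- feature expansion -------------------------------------------------------


def test_linear_feature_scaling_to_unit_interval():
    df = pd.DataFrame({"x": [2.0, 4.0, 10.0]})
    expansion, F = build_features(df, kinds=("linear",))
    assert F.shape == (3, 1)
    assert F[:, 0] == pytest.approx([0.0, 0.25, 1.0])


def test_feature_counts():
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [5.0, 3.0, 1.0]})
    _, F = build_features(df, kinds=("linear", "quadratic"))
    assert F.shape[1] == 4
    _, F2 = build_features(df, kinds=("linear", "product"))
    assert F2.shape[1] == 3
    _, F3 = build_features(df, kinds=("hinge",), n_hinge_knots=5)
    assert F3.shape[1] == 10
    assert np.all(F3 >= 0) and np.all(F3 <= 1)


def test_constant_variable_dropped_with_warning(caplog):
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "c": [7.0, 7.0, 7.0]})
    with caplog.at_level("WARNING"):
        expansion, F = build_features(df, kinds=("linear",))
    assert expansion.variable_names == ["x"]
    assert "constant" in caplog.text


def test_no_hinge_knot_at_variable_max():
    df = pd.DataFrame({"x": np.linspace(0, 1, 20)})
    expansion, F = build_features(df, kinds=("hinge",), n_hinge_knots=10)
    assert all(f.knot < 1.0 for f in expansion.features)
    assert not np.any(np.all(F == 0.0, axis=0))


# -- fitting ----------------------------------------------------------------


def test_intercept_only_model_is_uniform():
    pres = np.empty((5, 0))
    bg = np.empty((100, 0))
    model = fit_maxent(pres, bg)
    raw = predict_raw(model, np.empty((100, 0)))
    np.testing.assert_allclose(raw, 0.01, rtol=1e-12)
    np.testing.assert_allclose(to_logistic(model, raw), 0.5, rtol=1e-12)
    assert training_gain(model, pres) == pytest.approx(0.0, abs=1e-12)


def test_single_feature_unregularized_matches_newton_oracle():
    rng = np.random.default_rng(0)
    f_bg = rng.random(500)
    f_pres = rng.random(60) ** 0.4  # presence mean above background mean
    P, B = f_pres[:, None], f_bg[:, None]
    model = fit_maxent(P, B, betas=np.array([0.0]), tol=1e-9)
    lam_oracle = newton_gibbs_moment(f_bg, f_pres.mean())
    assert model.converged
    assert model.weights[0] == pytest.approx(lam_oracle, abs=1e-6)
    # moment condition itself
    q = predict_raw(model, B)
    assert float(q @ f_bg) == pytest.approx(f_pres.mean(), abs=1e-6)


def test_l1_activates_kkt_boundary():
    rng = np.random.default_rng(1)
    f_bg = rng.random(400)
    f_pres = np.clip(rng.normal(0.9, 0.05, 50), 0, 1)
    model = fit_maxent(f_pres[:, None], f_bg[:, None],
                       betas=np.array([0.1]), tol=1e-8)
    q = predict_raw(model, f_bg[:, None])
    gap = abs(float(q @ f_bg) - f_pres.mean())
    assert model.weights[0] != 0.0
    assert gap == pytest.approx(0.1, abs=1e-6)


def test_kkt_certificate_on_random_fits():
    for seed in range(3):
        pres, bg = rng_tables(seed)
        expansion, B = build_features(bg, kinds=("linear", "quadratic", "hinge"),
                                      n_hinge_knots=5)
        P = expansion.transform(pres)
        model = fit_maxent(P, B, expansion=expansion, tol=1e-6)
        assert model.converged
        q = predict_raw(model, B)
        gap = np.abs(P.mean(axis=0) - q @ B)
        assert np.all(gap <= model.betas + 1e-5)


def test_objective_beats_random_weight_vectors():
    pres, bg = rng_tables(7)
    expansion, B = build_features(bg, kinds=("linear", "quadratic"))
    P = expansion.transform(pres)
    model = fit_maxent(P, B, expansion=expansion)

    def objective(lam):
        from scipy.special import logsumexp
        return (-P.mean(axis=0) @ lam + logsumexp(B @ lam)
                + model.betas @ np.abs(lam))

    f_fit = objective(model.weights)
    rng = np.random.default_rng(0)
    for _ in range(100):
        assert f_fit <= objective(rng.normal(size=model.weights.size)) + 1e-9


def test_shift_invariance_of_fitted_distribution():
    pres, bg = rng_tables(3, k=1)
    expansion, B = build_features(bg, kinds=("linear",))
    P = expansion.transform(pres)
    m1 = fit_maxent(P, B, expansion=expansion, tol=1e-8)
    shifted_bg = bg + 100.0
    shifted_pres = pres + 100.0
    e2, B2 = build_features(shifted_bg, kinds=("linear",))
    P2 = e2.transform(shifted_pres)
    m2 = fit_maxent(P2, B2, expansion=e2, tol=1e-8)
    np.testing.assert_allclose(
        predict_raw(m1, B), predict_raw(m2, B2), atol=1e-6
    )


# -- prediction and transforms ----------------------------------------------


def test_raw_normalizes_and_is_monotone():
    pres, bg = rng_tables(5)
    expansion, B = build_features(bg, kinds=("linear",))
    P = expansion.transform(pres)
    model = fit_maxent(P, B, expansion=expansion)
    raw = predict_raw(model, B)
    assert raw.sum() == pytest.approx(1.0, abs=1e-9)
    scores = B @ model.weights
    order = np.argsort(scores)
    assert np.all(np.diff(raw[order]) >= -1e-15)
    # logistic transform preserves the ordering
    p = to_logistic(model, raw)
    assert np.all(np.diff(p[order]) >= -1e-15)


def test_predict_raw_rejects_wrong_width():
    pres, bg = rng_tables(2)
    expansion, B = build_features(bg, kinds=("linear",))
    model = fit_maxent(expansion.transform(pres), B, expansion=expansion)
    with pytest.raises(ValueError, match="columns"):
        predict_raw(model, np.zeros((4, 9)))


def test_logistic_limits():
    pres, bg = rng_tables(2)
    expansion, B = build_features(bg, kinds=("linear",))
    model = fit_maxent(expansion.transform(pres), B, expansion=expansion)
    assert to_logistic(model, 1e-300) == pytest.approx(0.0, abs=1e-12)
    assert float(to_logistic(model, np.array([1e300]))[0]) == pytest.approx(1.0)


def test_training_gain_nonnegative_at_mle_and_matches_resummation():
    pres, bg = rng_tables(9)
    expansion, B = build_features(bg, kinds=("linear", "quadratic"))
    P = expansion.transform(pres)
    model = fit_maxent(P, B, expansion=expansion,
                       betas=np.zeros(B.shape[1]), tol=1e-8)
    gain = training_gain(model, P)
    assert gain >= -1e-9
    # independent re-summation of the log-likelihood
    raw = predict_raw(model, P)
    oracle = np.log(model.n_background * raw).mean()
    assert gain == pytest.approx(float(oracle), abs=1e-10)


def test_response_curve_shapes():
    pres, bg = rng_tables(4, k=2)
    expansion, B = build_features(bg, kinds=("linear",))
    model = fit_maxent(expansion.transform(pres), B, expansion=expansion,
                       background_means={c: float(bg[c].mean())
                                         for c in bg.columns})
    xs, ys = response_curve(model, "v0", n_points=50)
    assert len(xs) == len(ys) == 50
    if model.weights[0] > 0:
        assert np.all(np.diff(ys) >= -1e-12)
    # endpoints equal direct predictions at min/max with others at bg means
    table = pd.DataFrame({
        "v0": [bg["v0"].min(), bg["v0"].max()],
        "v1": [bg["v1"].mean()] * 2,
    })
    from cnm.maxent_core import predict_logistic
    direct = predict_logistic(model, table)
    assert ys[0] == pytest.approx(direct[0], abs=1e-12)
    assert ys[-1] == pytest.approx(direct[1], abs=1e-12)
    with pytest.raises(KeyError):
        response_curve(model, "nope")


def test_flat_model_response_curve_is_half():
    pres = pd.DataFrame({"x": [0.3, 0.5, 0.7]})
    bg = pd.DataFrame({"x": np.linspace(0, 1, 200)})
    expansion, B = build_features(bg, kinds=("linear",))
    model = fit_maxent(expansion.transform(pres), B, expansion=expansion,
                       betas=np.array([np.inf]),
                       background_means={"x": 0.5})
    # infinite penalty pins the weight at zero: the uniform model
    assert model.weights[0] == 0.0
    _, ys = response_curve(model, "x", n_points=10)
    np.testing.assert_allclose(ys, 0.5, atol=1e-12)


def test_model_json_round_trip():
    pres, bg = rng_tables(6)
    expansion, B = build_features(bg, kinds=("linear", "hinge"),
                                  n_hinge_knots=4)
    P = expansion.transform(pres)
    model = fit_maxent(P, B, expansion=expansion,
                       background_means={c: 0.0 for c in bg.columns})
    clone = MaxentModel.from_json(model.to_json())
    np.testing.assert_array_equal(clone.weights, model.weights)
    np.testing.assert_allclose(
        predict_raw(clone, clone.expansion.transform(bg)),
        predict_raw(model, expansion.transform(bg)),
    )
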
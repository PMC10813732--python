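"""Sip-interval volume features, threshold-count invariants, and the
general / sip-size-dependent regression machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sipsense import (
    N_VOLUME_FEATURES,
    N_VOLUME_FEATURES_NO_FILL,
    VOLUME_FEATURE_NAMES,
    RegressorSpec,
    extract_volume_features,
    predict_volume,
    train_volume_models,
)
from sipsense.evaluation import segment_features, regression_metrics
from sipsense.signal_core import DerivedSeries
from sipsense.volume_estimation import (
    ABS_THRESHOLDS_DEG,
    REL_THRESHOLDS_PCT,
    fit_regressor,
)


def _incl_series(incl, fs=128.0):
    n = len(incl)
    z = np.zeros((n, 3))
    return DerivedSeries("container", np.arange(n) / fs, z, z, z,
                         np.asarray(incl, dtype=float), np.zeros(n, np.int8), fs)


def _counts(vec, block):
    """Slice the 27 absolute or relative threshold counts as (9, 3)."""
    base = {"abs": 10, "rel": 37}[block]
    return vec[base : base + 27].reshape(9, 3)


def test_feature_lengths_with_and_without_fill():
    d = _incl_series(np.full((64, 3), 30.0))
    assert extract_volume_features((0, 64), d).shape == (N_VOLUME_FEATURES_NO_FILL,)
    assert extract_volume_features((0, 64), d, 250.0).shape == (N_VOLUME_FEATURES,)
    assert N_VOLUME_FEATURES_NO_FILL == 64 and N_VOLUME_FEATURES == 65
    assert len(set(VOLUME_FEATURE_NAMES)) == 65


def test_constant_inclination_closed_form():
    """45 deg over exactly 1 s at 128 Hz."""
    d = _incl_series(np.full((128, 3), 45.0))
    v = extract_volume_features((0, 128), d)
    assert v[0] == pytest.approx(1.0)           # duration
    assert np.allclose(v[1:4], 45.0)            # average
    assert np.allclose(v[4:7], 45.0)            # maximum
    assert np.allclose(v[7:10], 45.0)           # integral = value x duration
    abs_counts = _counts(v, "abs")
    assert np.all(abs_counts[ABS_THRESHOLDS_DEG.index(40)] == 128)  # 45 > 40
    assert np.all(abs_counts[ABS_THRESHOLDS_DEG.index(50)] == 0)    # 45 < 50
    rel_counts = _counts(v, "rel")
    assert np.all(rel_counts == 128)            # incl/max = 1 > every p%


def test_ramp_threshold_counts_match_bruteforce():
    n = 256
    ramp = np.linspace(0.0, 90.0, n)
    incl = np.column_stack([ramp, ramp / 2, np.full(n, 10.0)])
    v = extract_volume_features((0, n), _incl_series(incl))
    abs_counts = _counts(v, "abs")
    rel_counts = _counts(v, "rel")
    mx = incl.max(axis=0)
    for i, k in enumerate(ABS_THRESHOLDS_DEG):
        for ax in range(3):
            assert abs_counts[i, ax] == sum(1 for x in incl[:, ax] if x > k)
    for i, p in enumerate(REL_THRESHOLDS_PCT):
        for ax in range(3):
            expect = sum(1 for x in incl[:, ax] if x / mx[ax] > p / 100.0)
            assert rel_counts[i, ax] == expect


def test_zero_maximum_gives_zero_relative_counts():
    v = extract_volume_features((0, 32), _incl_series(np.zeros((32, 3))))
    assert np.all(_counts(v, "rel") == 0)


def test_empty_interval_rejected():
    d = _incl_series(np.full((16, 3), 1.0))
    with pytest.raises(ValueError):
        extract_volume_features((8, 8), d)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=30)
def test_threshold_counts_monotone_on_random_inclination(seed):
    rng = np.random.default_rng(seed)
    incl = rng.uniform(0, 180, size=(rng.integers(2, 200), 3))
    v = extract_volume_features((0, len(incl)), _incl_series(incl))
    for block in ("abs", "rel"):
        c = _counts(v, block)
        assert np.all(np.diff(c, axis=0) <= 0)  # non-increasing in k and p
    assert np.all(v[1:4] <= v[4:7] + 1e-12)     # avg <= max per direction
    assert np.all(v[7:10] >= 0)                 # integral >= 0


def test_spec_validation():
    with pytest.raises(ValueError):
        RegressorSpec(kernel="poly")
    with pytest.raises(ValueError):
        RegressorSpec(target="fill_level", with_fill_level=True)
    with pytest.raises(ValueError):
        RegressorSpec(target="fill_level", scope="small")


def test_general_model_ignores_category(rng):
    X = rng.normal(size=(60, 5))
    y = rng.normal(30, 5, size=60)
    ms = train_volume_models(X, y, np.array(["small"] * 60), RegressorSpec())
    a = predict_volume(ms, X[:5], np.array(["small"] * 5))
    b = predict_volume(ms, X[:5], np.array(["large"] * 5))
    assert np.array_equal(a, b)


def test_size_dependent_routing_and_unknown_category(rng):
    X = rng.normal(size=(90, 4))
    sizes = np.array(["small", "medium", "large"] * 30)
    y = np.where(sizes == "small", 10.0, np.where(sizes == "medium", 27.0, 54.0))
    y = y + rng.normal(0, 0.5, 90)
    ms = train_volume_models(X, y, sizes, RegressorSpec(), size_dependent=True)
    pred = predict_volume(ms, X, sizes)
    # each category's model pulls towards its own mean
    assert abs(pred[sizes == "small"].mean() - 10) < 3
    assert abs(pred[sizes == "large"].mean() - 54) < 3
    with pytest.raises(ValueError):
        predict_volume(ms, X[:3], np.array(["huge"] * 3))
    with pytest.raises(ValueError):
        predict_volume(ms, X[:3], None)


def test_interpolation_sanity(rng):
    """A near-interpolating configuration reproduces a training target."""
    X = rng.normal(size=(40, 6))
    y = rng.uniform(100, 400, 40)
    model = fit_regressor(X, y, RegressorSpec(kernel="gaussian", C=1e4, epsilon=0.01))
    pred = model.predict(X)
    assert np.mean(np.abs(pred - y)) < 5.0


def test_linear_model_recovers_duration_law(full_events):
    """amount = a + b*duration + noise is recovered with MAD < noise SD,
    cross-checked against an ordinary-least-squares oracle."""
    sf = segment_features(full_events[:504], "container")
    rng = np.random.default_rng(0)
    sd = 2.0
    y = 5.0 + 12.0 * sf.sip_X[:, 0] + rng.normal(0, sd, len(sf.sip_X))
    model = fit_regressor(sf.sip_X, y, RegressorSpec(kernel="linear"))
    mad_svr = np.mean(np.abs(model.predict(sf.sip_X) - y))
    A = np.column_stack([np.ones(len(y)), sf.sip_X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    mad_ols = np.mean(np.abs(A @ coef - y))
    assert mad_ols < sd          # oracle: OLS fits within the noise floor
    assert mad_svr < sd          # the SVR pipeline matches that recovery


def test_combination_study_shape(small_events):
    """8 columns: 2 arms x {true, recognized} x {no fill, fill}, with
    per-event predictions carrying full model provenance."""
    from sipsense import run_combination_study

    tab = run_combination_study(small_events, train_cap=800)
    assert len(tab) == 8
    assert set(tab["arm"]) == {"wrist", "container"}
    assert set(tab["data_source"]) == {"true", "recognized"}
    assert set(tab["fill_source"]) == {"none", "true", "estimated"}
    # true segments pair with true fill, recognized with estimated
    with_fill = tab[tab["fill_source"] != "none"]
    assert all(
        (r.data_source, r.fill_source) in
        {("true", "true"), ("recognized", "estimated")}
        for r in with_fill.itertuples()
    )
    preds = tab.attrs["predictions"]
    assert {"event_id", "arm", "data_source", "fill_source", "model_scope",
            "kernel", "true_g", "est_g"} <= set(preds.columns)
    assert np.all(np.isfinite(preds["est_g"]))


def test_predictions_finite_for_all_events(small_events):
    sf = segment_features(small_events, "wrist")
    est = fit_regressor(
        sf.sip_X, sf.amounts, RegressorSpec(kernel="gaussian")
    ).predict(sf.sip_X)
    assert np.all(np.isfinite(est))
    rep = regression_metrics(sf.amounts, est)
    assert rep.n == len(small_events)
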
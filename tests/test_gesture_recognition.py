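"""Window features, SVM gesture classifier, label postprocessing, and the
window->segment mapping, against textbook-formula and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from sipsense import (
    N_GESTURE_FEATURES,
    GESTURE_FEATURE_NAMES,
    WindowingConfig,
    derive_channels,
    extract_gesture_features,
    postprocess_labels,
    segments_from_labels,
    train_gesture_classifier,
)
from sipsense.gesture_recognition import (
    extract_gesture_features_batch,
    window_statistics,
)
from sipsense.signal_core import WindowSegment, window_starts, majority_labels
from sipsense.synthetic_data import GESTURES


def test_feature_vector_length_and_names(small_events):
    e = small_events[0]
    d = derive_channels(e.wrist)
    seg = WindowSegment(0, 32, "wrist", 0)
    v = extract_gesture_features(seg, d)
    assert v.shape == (96,)
    assert len(GESTURE_FEATURE_NAMES) == N_GESTURE_FEATURES == 96
    assert len(set(GESTURE_FEATURE_NAMES)) == 96
    assert np.all(np.isfinite(v))


def test_constant_window_statistics():
    c = 3.7
    stats_out = window_statistics(np.full((1, 1, 16), c))[0]
    mean, sd, var, mx, mn, rng_, skew, kurt = stats_out
    assert mean == pytest.approx(c)
    assert sd == 0 and var == 0 and rng_ == 0
    assert mx == mn == pytest.approx(c)
    assert skew == 0 and kurt == 0  # zero-variance convention


def test_moments_match_direct_summation_oracle():
    """{1,2,3,4,10}: population moment ratios vs. textbook formulas."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
    out = window_statistics(x[None, None, :])[0]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    expect = [mean, var**0.5, var, max(x), min(x), max(x) - min(x),
              m3 / var**1.5, m4 / var**2]
    assert np.allclose(out, expect, rtol=1e-12)
    # independent library oracle for the shape statistics
    assert out[6] == pytest.approx(stats.skew(x, bias=True))
    assert out[7] == pytest.approx(stats.kurtosis(x, bias=True, fisher=False))


def test_gaussian_window_kurtosis_near_three(rng):
    x = rng.normal(size=(1, 1, 100000))
    kurt = window_statistics(x)[0, 7]
    assert kurt == pytest.approx(3.0, abs=0.1)  # non-excess convention


def test_batch_matches_single_window(small_events):
    e = small_events[0]
    d = derive_channels(e.container)
    cfg = WindowingConfig(24, 50.0)
    starts = window_starts(len(d), cfg)
    batch = extract_gesture_features_batch(d, starts, 24)
    for i in (0, len(starts) // 2, len(starts) - 1):
        seg = WindowSegment(int(starts[i]), 24, "container", 0)
        assert np.array_equal(batch[i], extract_gesture_features(seg, d))


def test_feature_extraction_independent_of_event_order(small_events):
    d = derive_channels(small_events[2].wrist)
    seg = WindowSegment(10, 32, "wrist", 0)
    first = extract_gesture_features(seg, d)
    # extract other events in between, then re-extract
    for e in reversed(small_events[:2]):
        extract_gesture_features(seg, derive_channels(e.wrist))
    assert np.array_equal(first, extract_gesture_features(seg, d))


def test_separable_toy_classifier_is_perfect(rng):
    X = np.vstack([rng.normal(0, 0.1, (20, 5)), rng.normal(10, 0.1, (20, 5))])
    y = np.array([0] * 20 + [1] * 20)
    model = train_gesture_classifier(X, y)
    assert (model.predict(X) == y).mean() == 1.0


def test_single_class_training_rejected(rng):
    X = rng.normal(size=(10, 5))
    with pytest.raises(ValueError):
        train_gesture_classifier(X, np.zeros(10))


# ---------------------------------------------------------------------------
# Postprocessing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expect",
    [
        # one deviating fragment between agreeing neighbors
        (list("GGOGG"), list("GGGGG")),
        # two consecutive deviating fragments
        (list("GGOOGG"), list("GGGGGG")),
        # uniform sequence unchanged
        (list("GGGG"), list("GGGG")),
        # deviation at position 0 has no preceding fragment: unchanged
        (list("OGGG"), list("OGGG")),
        # trailing deviation has no subsequent fragment: unchanged
        (list("GGGO"), list("GGGO")),
        # run of three is never corrected
        (list("GGOOOGG"), list("GGOOOGG")),
        # flanking fragments disagree: unchanged
        (list("GGOSS"), list("GGOSS")),
        # cascade: first correction enables the second
        (list("ABABA"), list("AAAAA")),
    ],
)
def test_postprocess_rule(seq, expect):
    assert postprocess_labels(seq) == expect


def test_postprocess_preserves_length_and_rejects_empty(rng):
    for _ in range(50):
        seq = rng.integers(0, 3, size=rng.integers(1, 30)).tolist()
        assert len(postprocess_labels(seq)) == len(seq)
    with pytest.raises(ValueError):
        postprocess_labels([])


def test_postprocess_no_short_runs_unchanged():
    seq = [0] * 3 + [1] * 4 + [2] * 3 + [1] * 5
    assert postprocess_labels(seq) == seq


def test_postprocess_improves_noisy_ground_truth(small_events):
    """Isolated 5% label flips are repaired, strictly raising accuracy."""
    rng = np.random.default_rng(99)
    cfg = WindowingConfig(16, 75.0)  # step 4: long label runs per phase
    improved, total_acc_noisy, total_acc_post = 0, [], []
    for e in small_events:
        starts = window_starts(len(e.wrist), cfg)
        truth = majority_labels(e.wrist.labels, starts, 16, 5).tolist()
        noisy = list(truth)
        n = len(noisy)
        n_flips = max(1, int(0.05 * n))
        positions = rng.choice(np.arange(2, n - 2, 3), size=min(n_flips, (n - 4) // 3),
                               replace=False)
        for p in positions:
            if truth[p - 1] == truth[p] == truth[p + 1]:  # interior of a run
                noisy[p] = (truth[p] + 1) % 5
        fixed = postprocess_labels(noisy)
        acc_noisy = np.mean(np.array(noisy) == truth)
        acc_post = np.mean(np.array(fixed) == truth)
        total_acc_noisy.append(acc_noisy)
        total_acc_post.append(acc_post)
        improved += acc_post > acc_noisy
    assert np.mean(total_acc_post) > np.mean(total_acc_noisy)
    assert improved >= 0.9 * len(small_events)


# ---------------------------------------------------------------------------
# Window labels -> sample segments
# ---------------------------------------------------------------------------

def test_segments_from_labels_midpoint_convention():
    cfg = WindowingConfig(16, 50.0)  # step 8, center offset 8
    labels = [GESTURES.index(g) for g in
              ["pre-sip", "pre-sip", "sip", "sip", "sip", "post-sip"]]
    starts = np.arange(6) * cfg.step
    seg = segments_from_labels(labels, starts, cfg, series_len=200, event_id="e")
    assert not seg.flagged
    # centers: 8,16,24,32,40,48 -> run boundaries at (16+24)//2=20, (40+48)//2=44
    assert seg.pre_sip == (0, 20)
    assert seg.sip == (20, 44)
    assert seg.post_sip == (44, 56)
    assert seg.pre_to_post == (0, 56)


def test_segments_longest_sip_run_kept():
    cfg = WindowingConfig(16, 50.0)
    g = GESTURES.index
    labels = [g("pre-sip"), g("sip"), g("post-sip"), g("sip"), g("sip"), g("sip"),
              g("post-sip")]
    starts = np.arange(7) * cfg.step
    seg = segments_from_labels(labels, starts, cfg, series_len=300)
    # second (longer) sip run wins; its flanks give the triple
    assert seg.sip[0] > 20
    assert seg.post_sip is not None and seg.post_sip[0] >= seg.sip[1]


def test_segments_no_sip_flagged():
    cfg = WindowingConfig(16, 50.0)
    labels = [GESTURES.index("pre-sip")] * 4
    seg = segments_from_labels(labels, np.arange(4) * 8, cfg, series_len=100)
    assert seg.flagged and seg.sip is None and seg.pre_to_post is None
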
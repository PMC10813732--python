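"""Gesture-recognition arm: statistical window features, an RBF-SVM
classifier, and run-based label postprocessing.

Eight statistics (mean, standard deviation, variance, maximum, minimum,
range, skewness, kurtosis) over each of the 12 channels (tri-axial
acceleration, angular velocity, angular acceleration, inclination) give a
96-dimensional feature vector per window.  Skewness and kurtosis use the
population (biased) moment-ratio definitions; kurtosis is non-excess
(a Gaussian window scores 3) and a zero-variance window maps both to 0.

Postprocessing corrects isolated mislabeled fragments: an interior run of one
or two windows whose flanking fragments agree with each other is rewritten to
the preceding fragment's label, scanning left to right so that a correction
can enable later ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .signal_core import CHANNEL_NAMES, DerivedSeries, WindowingConfig, WindowSegment
from .synthetic_data import GESTURES

STAT_NAMES: tuple[str, ...] = (
    "mean", "std", "var", "max", "min", "range", "skew", "kurt"
)

#: Names of the 96 gesture features, in extraction order (stat-major:
#: all 12 channels for each statistic in turn).
GESTURE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{ch}" for stat in STAT_NAMES for ch in CHANNEL_NAMES
)

N_GESTURE_FEATURES = len(GESTURE_FEATURE_NAMES)  # 8 stats x 12 channels = 96

_VAR_EPS = 1e-12  # below this the window counts as constant


def window_statistics(x: np.ndarray) -> np.ndarray:
    """The eight statistics along the last axis of ``x`` (..., C, w).

    Returns (..., 8*C): the C channels for each statistic in turn.
    """
    mean = x.mean(axis=-1)
    mx = x.max(axis=-1)
    mn = x.min(axis=-1)
    d = x - mean[..., None]
    m2 = (d * d).mean(axis=-1)
    m3 = (d * d * d).mean(axis=-1)
    m4 = (d * d * d * d).mean(axis=-1)
    sd = np.sqrt(m2)
    ok = m2 > _VAR_EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(ok, m4 / np.where(ok, m2, 1.0) ** 2, 0.0)
    return np.concatenate(
        [mean, sd, m2, mx, mn, mx - mn, skew, kurt], axis=-1
    )


def extract_gesture_features_batch(
    d: DerivedSeries, starts: np.ndarray, window: int
) -> np.ndarray:
    """Feature matrix (n_windows, 96) for all windows of one series."""
    ch = d.channels()                                   # (n, 12)
    win = sliding_window_view(ch, window, axis=0)[starts]  # (n_win, 12, w)
    return window_statistics(win)


def extract_gesture_features(seg: WindowSegment, d: DerivedSeries) -> np.ndarray:
    """The 96-feature vector of a single window, in GESTURE_FEATURE_NAMES order."""
    if seg.start_idx + seg.window_samples > len(d):
        raise ValueError("window extends past the end of the series")
    feats = extract_gesture_features_batch(
        d, np.array([seg.start_idx]), seg.window_samples
    )[0]
    assert feats.shape == (N_GESTURE_FEATURES,)
    return feats


@dataclass(frozen=True)
class ClassifierSpec:
    """RBF-SVM hyperparameters; standardization is fitted per training fold."""

    C: float = 1.0
    gamma: str | float = "scale"    # 1 / (n_features * feature variance)

    def build(self) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                            decision_function_shape="ovo")),
            ]
        )


def train_gesture_classifier(
    features: np.ndarray, labels: np.ndarray, spec: ClassifierSpec | None = None
) -> Pipeline:
    """Fit the gesture classifier on labeled window features.

    Deterministic given data order and spec. Requires at least two classes.
    """
    if spec is None:
        spec = ClassifierSpec()
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain at least two gesture classes")
    model = spec.build()
    model.fit(features, labels)
    return model


# --------------------------------------------------------------------------
# Label-sequence postprocessing
# --------------------------------------------------------------------------

def postprocess_labels(seq) -> list:
    """Correct isolated 1- or 2-fragment label deviations.

    An interior run of length one or two whose immediately preceding and
    following fragments carry the same label is rewritten to the preceding
    fragment's label.  The scan proceeds left to right and corrections are
    visible to later positions (cascades allowed); runs touching either end
    of the sequence are never modified.  Idempotent on its own output.
    """
    out = list(seq)
    if not out:
        raise ValueError("empty label sequence")
    n = len(out)
    i = 1
    while i < n:
        if out[i] == out[i - 1]:
            i += 1
            continue
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if j - i <= 2 and j < n and out[j] == out[i - 1]:
            out[i:j] = [out[i - 1]] * (j - i)
        i = j
    return out


# --------------------------------------------------------------------------
# From window labels back to sample intervals
# --------------------------------------------------------------------------

@dataclass
class GestureSegmentation:
    """Sample intervals of the recognized pre-sip / sip / post-sip phases."""

    event_id: str
    sip: tuple[int, int] | None
    pre_sip: tuple[int, int] | None
    post_sip: tuple[int, int] | None
    flagged: bool = False          # True when no sip run was recognized
    runs: list = field(default_factory=list)  # (label, start_sample, stop_sample)

    @property
    def pre_to_post(self) -> tuple[int, int] | None:
        """The recognized pre-sip…post-sip interval (fill-level feature span)."""
        if self.sip is None:
            return None
        start = self.pre_sip[0] if self.pre_sip else self.sip[0]
        stop = self.post_sip[1] if self.post_sip else self.sip[1]
        return start, stop


def segments_from_labels(
    labels,
    starts: np.ndarray,
    cfg: WindowingConfig,
    series_len: int,
    event_id: str = "",
) -> GestureSegmentation:
    """Merge contiguous equal-label windows into sample intervals.

    Window midpoint convention: the boundary between two adjacent runs is the
    midpoint of the two transition windows' centers; the first run starts at
    the first window's start and the last run ends at the last window's end.
    If several sip runs exist the longest is kept (first on ties); the
    nearest preceding pre-sip run and nearest following post-sip run complete
    the triple.  An event with no sip run is flagged.
    """
    labels = list(labels)
    starts = np.asarray(starts)
    if len(labels) != len(starts) or not labels:
        raise ValueError("labels and starts must be equal-length and nonempty")
    centers = starts + cfg.window_samples // 2

    # Run-length encode the window labels.
    runs_w: list[tuple[int, int, int]] = []  # (label, first_win, last_win)
    a = 0
    for b in range(1, len(labels) + 1):
        if b == len(labels) or labels[b] != labels[a]:
            runs_w.append((labels[a], a, b - 1))
            a = b

    runs: list[tuple[int, int, int]] = []  # (label, start_sample, stop_sample)
    for k, (lab, wa, wb) in enumerate(runs_w):
        lo = int(starts[0]) if k == 0 else int(
            (centers[runs_w[k - 1][2]] + centers[wa]) // 2
        )
        hi = (
            int(starts[-1]) + cfg.window_samples
            if k == len(runs_w) - 1
            else int((centers[wb] + centers[runs_w[k + 1][1]]) // 2)
        )
        hi = min(hi, series_len)
        runs.append((lab, lo, hi))

    sip_code = GESTURES.index("sip")
    pre_code = GESTURES.index("pre-sip")
    post_code = GESTURES.index("post-sip")
    sip_runs = [k for k, r in enumerate(runs) if r[0] == sip_code]
    if not sip_runs:
        return GestureSegmentation(event_id, None, None, None, flagged=True, runs=runs)
    k_sip = max(sip_runs, key=lambda k: runs[k][2] - runs[k][1])
    pre = next(
        (runs[k][1:] for k in range(k_sip - 1, -1, -1) if runs[k][0] == pre_code), None
    )
    post = next(
        (runs[k][1:] for k in range(k_sip + 1, len(runs)) if runs[k][0] == post_code),
        None,
    )
    return GestureSegmentation(
        event_id,
        sip=runs[k_sip][1:],
        pre_sip=tuple(pre) if pre else None,
        post_sip=tuple(post) if post else None,
        runs=runs,
    )
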
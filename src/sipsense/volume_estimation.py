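"""Volume-estimation arm: inclination features over recognized segments,
fill-level regression, and general vs. sip-size-dependent intake regression.

The sip interval yields a 64/65-feature vector: duration, per-direction
average / maximum / integral of inclination, per-direction counts of samples
above nine absolute tilt thresholds (10°…90°) and nine relative thresholds
(10%…90% of that interval's per-direction maximum), and optionally the fill
level.  Fill-level estimation applies the same 64 features to the
pre-sip…post-sip interval.  All regressors are support-vector machines with
linear or Gaussian kernels; sip-size-dependent estimation trains one model
per size category and routes each event by its category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVR

from .signal_core import AXES, DerivedSeries
from .synthetic_data import SIP_SIZES

ABS_THRESHOLDS_DEG: tuple[int, ...] = tuple(range(10, 91, 10))
REL_THRESHOLDS_PCT: tuple[int, ...] = tuple(range(10, 91, 10))

VOLUME_FEATURE_NAMES: tuple[str, ...] = (
    ("duration_s",)
    + tuple(f"avg_incl_{a}" for a in AXES)
    + tuple(f"max_incl_{a}" for a in AXES)
    + tuple(f"int_incl_{a}" for a in AXES)
    + tuple(f"n_over_{k}deg_{a}" for k in ABS_THRESHOLDS_DEG for a in AXES)
    + tuple(f"n_over_{p}pct_max_{a}" for p in REL_THRESHOLDS_PCT for a in AXES)
    + ("fill_level_g",)
)

N_VOLUME_FEATURES = len(VOLUME_FEATURE_NAMES)            # 65 with fill level
N_VOLUME_FEATURES_NO_FILL = N_VOLUME_FEATURES - 1        # 64 without


def extract_volume_features(
    interval: tuple[int, int],
    d: DerivedSeries,
    fill_level_g: float | None = None,
) -> np.ndarray:
    """Feature vector of one sample interval ``[start, stop)`` of a series.

    Duration is ``n_samples / sample_rate``; the integral uses the
    trapezoidal rule extended half a sample at each end, so a constant
    signal integrates to value x duration (deg·s); threshold counts are raw
    sample counts, strict
    ``>``; relative thresholds are taken against the interval's own
    per-direction maximum (a zero maximum gives zero counts).  Returns 64
    values, or 65 with the fill level appended.
    """
    lo, hi = int(interval[0]), int(interval[1])
    if hi <= lo:
        raise ValueError(f"empty sip interval [{lo}, {hi})")
    incl = d.incl[lo:hi]                                  # (n, 3) degrees
    n = hi - lo
    duration = n / d.sample_rate_hz
    avg = incl.mean(axis=0)
    mx = incl.max(axis=0)
    dx = 1.0 / d.sample_rate_hz
    # trapezoid over the samples plus the two half-sample end caps; for a
    # uniform grid this reduces to sum * dx
    integral = np.trapezoid(incl, dx=dx, axis=0) + 0.5 * dx * (incl[0] + incl[-1])
    abs_counts = np.array(
        [(incl > k).sum(axis=0) for k in ABS_THRESHOLDS_DEG], dtype=float
    ).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mx > 0, incl / np.where(mx > 0, mx, 1.0), 0.0)
    rel_counts = np.array(
        [(rel > p / 100.0).sum(axis=0) for p in REL_THRESHOLDS_PCT], dtype=float
    ).ravel()
    feats = np.concatenate([[duration], avg, mx, integral, abs_counts, rel_counts])
    if fill_level_g is not None:
        feats = np.concatenate([feats, [float(fill_level_g)]])
    return feats


@dataclass(frozen=True)
class RegressorSpec:
    """SVR configuration for fill-level or volume regression."""

    kernel: str = "gaussian"          # "linear" | "gaussian"
    target: str = "volume"            # "fill_level" | "volume"
    scope: str = "general"            # "general" | "small" | "medium" | "large"
    with_fill_level: bool = False
    C: float = 10.0
    epsilon: float = 1.0              # grams

    def __post_init__(self):
        if self.kernel not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.target == "fill_level" and self.with_fill_level:
            raise ValueError("fill-level regression never uses the fill-level feature")
        if self.scope != "general" and self.target != "volume":
            raise ValueError("sip-size-dependent scope applies to the volume target only")
        if self.scope not in ("general",) + SIP_SIZES:
            raise ValueError(f"unknown scope {self.scope!r}")

    def build(self) -> Pipeline:
        if self.kernel == "linear":
            # liblinear solves the linear case orders of magnitude faster
            # than the kernelized solver; seeded for determinism.
            svr = LinearSVR(C=self.C, epsilon=self.epsilon,
                            loss="epsilon_insensitive", dual=True,
                            max_iter=200000, random_state=0)
        else:
            svr = SVR(kernel="rbf", C=self.C, epsilon=self.epsilon, gamma="scale")
        return Pipeline([("scale", StandardScaler()), ("svr", svr)])


def fit_regressor(X: np.ndarray, y: np.ndarray, spec: RegressorSpec) -> Pipeline:
    """Fit one SVR on standardized features; targets stay in grams."""
    if len(X) == 0:
        raise ValueError(f"empty training set for scope {spec.scope!r}")
    model = spec.build()
    model.fit(X, y)
    return model


def estimate_fill_level(model: Pipeline, features: np.ndarray) -> np.ndarray:
    """Predict continuous fill levels (g) from pre-sip…post-sip features."""
    return model.predict(np.atleast_2d(features))


@dataclass
class VolumeModelSet:
    """A general model or one model per sip-size category."""

    spec: RegressorSpec
    models: dict                      # {"general": m} or {size: m, ...}

    @property
    def is_size_dependent(self) -> bool:
        return "general" not in self.models


def train_volume_models(
    X: np.ndarray,
    y: np.ndarray,
    sizes: np.ndarray,
    spec: RegressorSpec,
    size_dependent: bool = False,
) -> VolumeModelSet:
    """Fit the general model, or one model per sip-size category.

    For size-dependent training each category's model sees only that
    category's events; an empty category raises.
    """
    if not size_dependent:
        return VolumeModelSet(spec, {"general": fit_regressor(X, y, spec)})
    sizes = np.asarray(sizes)
    present = [s for s in SIP_SIZES if (sizes == s).any()]
    if not present:
        raise ValueError("no training events in any sip-size category")
    models = {
        size: fit_regressor(X[sizes == size], y[sizes == size], spec)
        for size in present
    }
    return VolumeModelSet(spec, models)


@dataclass
class VolumePrediction:
    """Estimated vs. true intake for one event, with model provenance."""

    event_id: str
    true_amount_g: float
    estimated_amount_g: float
    arm: str                       # "wrist" | "container"
    kernel: str
    scope: str                     # "general" or the routed size category
    data_source: str               # "true" | "recognized" segments
    fill_source: str               # "none" | "true" | "estimated"


def predict_volume(
    model_set: VolumeModelSet,
    features: np.ndarray,
    sizes: np.ndarray | None = None,
) -> np.ndarray:
    """Predict intake volumes, routing by sip-size category when size-dependent.

    The general model ignores the category; size-dependent sets require one
    category per event (ground-truth dispatch).
    """
    X = np.atleast_2d(features)
    if not model_set.is_size_dependent:
        return model_set.models["general"].predict(X)
    if sizes is None:
        raise ValueError("size-dependent prediction requires a sip-size per event")
    sizes = np.asarray(sizes)
    out = np.empty(len(X))
    for size in np.unique(sizes):
        if size not in model_set.models:
            raise ValueError(f"unknown sip-size category {size!r}")
        mask = sizes == size
        out[mask] = model_set.models[size].predict(X[mask])
    return out


def run_combination_study(events, window_cfg=None, seed: int = 0, train_cap: int = 2000):
    """Volume-estimation errors for all segment-source / fill-source pairings.

    Eight columns — 2 arms x {true, recognized} segments x {without, with
    fill level} — where true-segment columns pair with true fill levels and
    recognized-segment columns with estimated fill levels.  Thin wrapper
    over the evaluation module's LOSO machinery.
    """
    from . import evaluation

    return evaluation.combination_study(
        events, window_cfg=window_cfg, seed=seed, train_cap=train_cap
    )
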
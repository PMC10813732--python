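"""Derived-channel computation and sliding-window segmentation.

Both recognition arms work on four tri-axial channel groups: raw acceleration
and angular velocity plus two derived ones — angular acceleration (finite
difference of the gyroscope) and inclination (per-axis angle between the
acceleration vector and each sensor axis, using the acceleration direction as
a gravity proxy).  Windowing slides a fixed-length fragment with configurable
overlap and assigns each fragment the majority of its per-sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic_data import SensorSeries

#: The window-size / overlap grid explored for gesture recognition.
WINDOW_SIZES: tuple[int, ...] = (16, 24, 32, 40, 48, 56)
OVERLAP_PCTS: tuple[float, ...] = (25.0, 50.0, 75.0, 87.5)

#: Channel layout of a derived series, fixed everywhere downstream.
CHANNEL_GROUPS: tuple[str, ...] = ("acc", "gyr", "ang_acc", "incl")
AXES: tuple[str, ...] = ("x", "y", "z")
CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"{g}_{a}" for g in CHANNEL_GROUPS for a in AXES
)


@dataclass
class DerivedSeries:
    """A sensor series extended with angular acceleration and inclination."""

    placement: str
    t: np.ndarray
    acc: np.ndarray        # (n, 3) g
    gyr: np.ndarray        # (n, 3) deg/s
    ang_acc: np.ndarray    # (n, 3) deg/s^2
    incl: np.ndarray       # (n, 3) degrees, in [0, 180]
    labels: np.ndarray
    sample_rate_hz: float

    def __len__(self) -> int:
        return len(self.t)

    def channels(self) -> np.ndarray:
        """All 12 channels as one (n, 12) array, in CHANNEL_NAMES order."""
        return np.concatenate([self.acc, self.gyr, self.ang_acc, self.incl], axis=1)


def inclination_deg(acc: np.ndarray) -> np.ndarray:
    """Per-axis inclination: angle between the acceleration vector and each axis.

    ``incl_i = arccos(acc_i / ||acc||)`` in degrees; a zero-norm acceleration
    maps to 90 degrees on every axis (no information about direction).
    Invariant to uniform rescaling of the acceleration vector.
    """
    acc = np.asarray(acc, dtype=float)
    norm = np.linalg.norm(acc, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(norm > 0, acc / np.where(norm > 0, norm, 1.0), 0.0)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def derive_channels(s: SensorSeries) -> DerivedSeries:
    """Compute angular acceleration and inclination for one sensor series.

    Angular acceleration is the central finite difference of the angular
    velocity (one-sided at the series ends) scaled by the sample rate.
    """
    if len(s) == 0:
        raise ValueError("cannot derive channels from an empty series")
    if len(s) == 1:
        ang_acc = np.zeros_like(s.gyr, dtype=float)
    else:
        ang_acc = np.gradient(s.gyr.astype(float), 1.0 / s.sample_rate_hz, axis=0)
    return DerivedSeries(
        placement=s.placement,
        t=s.t,
        acc=s.acc,
        gyr=s.gyr,
        ang_acc=ang_acc,
        incl=inclination_deg(s.acc),
        labels=s.labels,
        sample_rate_hz=s.sample_rate_hz,
    )


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window parameters; step must come out a positive integer."""

    window_samples: int = 40
    overlap_pct: float = 50.0

    @property
    def step(self) -> int:
        step = self.window_samples * (1.0 - self.overlap_pct / 100.0)
        istep = int(round(step))
        if istep <= 0 or abs(step - istep) > 1e-9:
            raise ValueError(
                f"window {self.window_samples} with overlap {self.overlap_pct}% "
                f"gives non-integer or non-positive step {step}"
            )
        return istep


def window_grid() -> list[WindowingConfig]:
    """All 24 (window, overlap) combinations of the standard grid."""
    return [WindowingConfig(w, o) for w in WINDOW_SIZES for o in OVERLAP_PCTS]


@dataclass
class WindowSegment:
    """One fixed-length fragment of a series."""

    start_idx: int
    window_samples: int
    placement: str
    true_label: int
    predicted_label: int | None = None


def window_starts(n_samples: int, cfg: WindowingConfig) -> np.ndarray:
    """Start indices of all complete windows; trailing partials discarded."""
    if n_samples < cfg.window_samples:
        raise ValueError(
            f"series of {n_samples} samples shorter than window {cfg.window_samples}"
        )
    return np.arange(0, n_samples - cfg.window_samples + 1, cfg.step)


def majority_labels(
    labels: np.ndarray, starts: np.ndarray, window: int, n_classes: int
) -> np.ndarray:
    """Majority per-sample label per window; ties go to the earlier-starting run.

    Vectorized: per-window label counts via scatter-add; among the tied
    maximal counts the label whose first occurrence inside the window is
    earliest wins (that occurrence starts the earlier run).
    """
    win = sliding_window_view(labels, window)[starts]          # (n_win, window)
    n_win = len(starts)
    counts = np.zeros((n_win, n_classes), dtype=np.int32)
    rows = np.repeat(np.arange(n_win), window)
    np.add.at(counts, (rows, win.ravel()), 1)
    best = counts.max(axis=1, keepdims=True)
    # First-occurrence position of each label in each window (inf if absent).
    first = np.full((n_win, n_classes), np.inf)
    pos = np.broadcast_to(np.arange(window), win.shape)
    for c in range(n_classes):
        hit = win == c
        any_hit = hit.any(axis=1)
        first[any_hit, c] = np.where(hit, pos, window)[any_hit].min(axis=1)
    first[counts < best] = np.inf
    return first.argmin(axis=1).astype(np.int8)


def slide_windows(d: DerivedSeries, cfg: WindowingConfig,
                  n_classes: int = 5) -> list[WindowSegment]:
    """Segment a derived series into labeled fixed-length fragments."""
    starts = window_starts(len(d), cfg)
    labs = majority_labels(d.labels, starts, cfg.window_samples, n_classes)
    return [
        WindowSegment(int(s), cfg.window_samples, d.placement, int(l))
        for s, l in zip(starts, labs)
    ]
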
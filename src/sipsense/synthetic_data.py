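"""Synthetic dual-placement IMU drinking-session generator.

Generates labeled drinking events as recorded by two inertial sensors — one on
the right wrist, one on the bottom of a drinking container — following a fixed
study protocol: every participant drinks at each fill level and sip-size
category a fixed number of times, and each event is the five-gesture sequence
grasp -> pre-sip -> sip -> post-sip -> release.

The generator encodes the physical couplings the downstream analysis relies on:

* the sip amount is drawn from a per-category truncated normal;
* the sip-phase duration grows monotonically with the drawn amount
  (concave law, per-participant rate factor);
* the peak container tilt during the sip grows as the fill level drops
  (an emptier cup must be tipped further);
* the container sensor is stationary (gravity only) outside pre-sip…post-sip;
* the wrist channels are the container motion seen through a constant
  per-participant orientation offset, plus wrist-only reach/retract motion in
  grasp/release and Gaussian noise with 3x the container's noise SD.

Axis convention: container sensor +Z points up when the cup rests on the
table, so the resting accelerometer reads (0, 0, 1) g; the sip tilt rotates
gravity into the Y/Z plane (rotation about the sensor X axis).

All signals are quantized to 1e-7 at generation so that the plain-text
serialization below round-trips exactly and identical seeds produce
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Constants and configuration
# --------------------------------------------------------------------------

#: Gesture phases in their fixed temporal order.
GESTURES: tuple[str, ...] = ("grasp", "pre-sip", "sip", "post-sip", "release")

#: The subset of phases during which the container itself moves.
CONTAINER_GESTURES: tuple[str, ...] = ("pre-sip", "sip", "post-sip")

GESTURE_CODES = {g: i for i, g in enumerate(GESTURES)}

SIP_SIZES: tuple[str, ...] = ("small", "medium", "large")

#: Sensor saturation limits.
ACC_RANGE_G = 16.0
GYR_RANGE_DPS = 2000.0

#: Dataset serialization format version (readers reject anything else).
FORMAT_VERSION = "1"

#: Decimal places kept in generated signals / CSV output.
_QUANT_DECIMALS = 7


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass(frozen=True)
class ProtocolConfig:
    """The study protocol grid: who drinks what, how often, sampled how."""

    n_participants: int = 12
    fill_levels_g: tuple[float, ...] = (100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0)
    sip_sizes: tuple[str, ...] = SIP_SIZES
    repetitions: int = 4
    sample_rate_hz: float = 128.0
    cup_capacity_g: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError(f"n_participants must be >= 1, got {self.n_participants}")
        if self.repetitions < 1:
            raise ConfigError(f"repetitions must be >= 1, got {self.repetitions}")
        if self.sample_rate_hz <= 0:
            raise ConfigError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.cup_capacity_g <= 0:
            raise ConfigError(f"cup_capacity_g must be > 0, got {self.cup_capacity_g}")
        for f in self.fill_levels_g:
            if not 0 < f <= self.cup_capacity_g:
                raise ConfigError(
                    f"fill_levels_g entries must lie in (0, cup_capacity_g], got {f}"
                )
        for s in self.sip_sizes:
            if s not in SIP_SIZES:
                raise ConfigError(f"sip_sizes entries must be one of {SIP_SIZES}, got {s!r}")

    @property
    def n_events(self) -> int:
        return (
            self.n_participants
            * len(self.fill_levels_g)
            * len(self.sip_sizes)
            * self.repetitions
        )


@dataclass(frozen=True)
class SipSizeModel:
    """Truncated-normal sip-amount model per category (grams)."""

    means_g: dict = field(
        default_factory=lambda: {"small": 10.71, "medium": 27.23, "large": 53.82}
    )
    sds_g: dict = field(
        default_factory=lambda: {"small": 5.56, "medium": 6.20, "large": 8.58}
    )
    floor_g: float = 1.0

    def validate(self) -> None:
        if self.floor_g <= 0:
            raise ConfigError(f"floor_g must be > 0, got {self.floor_g}")
        for s in SIP_SIZES:
            if s not in self.means_g:
                raise ConfigError(f"means_g missing category {s!r}")
            if s not in self.sds_g:
                raise ConfigError(f"sds_g missing category {s!r}")
            if self.sds_g[s] <= 0:
                raise ConfigError(f"sds_g[{s!r}] must be > 0, got {self.sds_g[s]}")
        if not (self.means_g["small"] < self.means_g["medium"] < self.means_g["large"]):
            raise ConfigError("means_g must be strictly ordered small < medium < large")

    def draw_amount(self, size: str, upper_g: float, rng: np.random.Generator) -> float:
        """Rejection-sample one sip amount in (floor_g, upper_g]."""
        mu, sd = self.means_g[size], self.sds_g[size]
        for _ in range(1000):
            a = rng.normal(mu, sd)
            if self.floor_g < a <= upper_g:
                return a
        # Pathological bounds; clamp to the feasible interval midpoint.
        return 0.5 * (self.floor_g + min(upper_g, mu))


# Generator noise/motion scales. Container noise is the reference; the wrist
# carries 3x that plus a constant per-participant orientation offset.
_ACC_NOISE_SD_G = 0.01
_GYR_NOISE_SD_DPS = 1.0
_WRIST_NOISE_FACTOR = 3.0
_WRIST_OFFSET_MAX_DEG = 15.0
_WRIST_WOBBLE_SD_DEG = 4.0   # slow orientation jitter of the hand (never rigid)
_WRIST_WOBBLE_HZ = 4.0       # node rate of the wobble process

_TILT_BASE_DEG = 35.0      # peak sip tilt at a brim-full cup
_TILT_FILL_GAIN_DEG = 55.0  # extra tilt as the cup empties (linear in 1 - fill/capacity)
_TILT_NOISE_SD_DEG = 4.0
_TILT_CARRY_DEG = 15.0     # tilt held while carrying the cup to/from the mouth

_LIFT_ACC_G = 0.25         # vertical acceleration amplitude of the lift/lower motion
_REACH_GYR_DPS = 80.0      # wrist reach/retract angular-velocity amplitude
_REACH_ACC_G = 0.3

# Sip duration law: d = (d0 + c * amount**p) * participant_factor + noise.
_SIP_DUR_BASE_S = 0.6
_SIP_DUR_COEF = 0.35
_SIP_DUR_POW = 0.6
_SIP_DUR_PF_SD = 0.06      # per-participant multiplicative rate spread
_SIP_DUR_NOISE_SD_S = 0.10
_SIP_DUR_MIN_S = 0.5

_PHASE_DUR_BOUNDS_S = {"grasp": (0.5, 1.5), "pre-sip": (1.0, 2.0),
                       "post-sip": (1.0, 2.0), "release": (0.5, 1.5)}


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------

@dataclass
class SensorSeries:
    """One placement's tri-axial accel + gyro stream with per-sample labels."""

    placement: str                # "wrist" | "container"
    t: np.ndarray                 # (n,) seconds, strictly increasing
    acc: np.ndarray               # (n, 3) in g
    gyr: np.ndarray               # (n, 3) in deg/s
    labels: np.ndarray            # (n,) int codes into GESTURES
    sample_rate_hz: float

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class DrinkingEvent:
    """One labeled drinking activity seen from both placements."""

    event_id: str
    participant_id: int
    fill_level_g: float
    sip_size: str
    repetition: int
    true_amount_g: float
    wrist: SensorSeries
    container: SensorSeries
    #: Six sample indices: starts of the five phases plus the series end.
    phase_boundaries: np.ndarray

    def phase_interval(self, phase: str) -> tuple[int, int]:
        """Sample interval [start, stop) of one gesture phase."""
        i = GESTURE_CODES[phase]
        return int(self.phase_boundaries[i]), int(self.phase_boundaries[i + 1])


def series_equal(a: SensorSeries, b: SensorSeries) -> bool:
    return (
        a.placement == b.placement
        and a.sample_rate_hz == b.sample_rate_hz
        and np.array_equal(a.t, b.t)
        and np.array_equal(a.acc, b.acc)
        and np.array_equal(a.gyr, b.gyr)
        and np.array_equal(a.labels, b.labels)
    )


def events_equal(a: DrinkingEvent, b: DrinkingEvent) -> bool:
    return (
        a.event_id == b.event_id
        and a.participant_id == b.participant_id
        and a.fill_level_g == b.fill_level_g
        and a.sip_size == b.sip_size
        and a.repetition == b.repetition
        and a.true_amount_g == b.true_amount_g
        and np.array_equal(a.phase_boundaries, b.phase_boundaries)
        and series_equal(a.wrist, b.wrist)
        and series_equal(a.container, b.container)
    )


# --------------------------------------------------------------------------
# Event synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant latent traits, fixed across that participant's events."""

    participant_id: int
    wrist_offset_x_deg: float   # constant wrist-vs-container orientation offset
    wrist_offset_y_deg: float
    sip_rate_factor: float      # multiplicative sip-duration factor
    tilt_offset_deg: float      # personal tilt habit


def make_profile(participant_id: int, rng: np.random.Generator) -> ParticipantProfile:
    return ParticipantProfile(
        participant_id=participant_id,
        wrist_offset_x_deg=rng.uniform(-_WRIST_OFFSET_MAX_DEG, _WRIST_OFFSET_MAX_DEG),
        wrist_offset_y_deg=rng.uniform(-_WRIST_OFFSET_MAX_DEG, _WRIST_OFFSET_MAX_DEG),
        sip_rate_factor=max(0.7, rng.normal(1.0, _SIP_DUR_PF_SD)),
        tilt_offset_deg=rng.normal(0.0, 3.0),
    )


def _smoothstep(n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    return 3 * u**2 - 2 * u**3


def _rotation_xy(ax_deg: float, ay_deg: float) -> np.ndarray:
    """Rotation matrix: first about X by ax, then about Y by ay (degrees)."""
    ax, ay = math.radians(ax_deg), math.radians(ay_deg)
    rx = np.array([[1, 0, 0],
                   [0, math.cos(ax), -math.sin(ax)],
                   [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)],
                   [0, 1, 0],
                   [-math.sin(ay), 0, math.cos(ay)]])
    return ry @ rx


def sip_duration_s(amount_g: float, rate_factor: float = 1.0) -> float:
    """Noise-free sip duration law: concave, strictly increasing in amount."""
    return (_SIP_DUR_BASE_S + _SIP_DUR_COEF * amount_g**_SIP_DUR_POW) * rate_factor


def peak_tilt_deg(fill_level_g: float, cup_capacity_g: float) -> float:
    """Noise-free peak sip tilt: decreases linearly with fill level."""
    return _TILT_BASE_DEG + _TILT_FILL_GAIN_DEG * (1.0 - fill_level_g / cup_capacity_g)


def synthesize_event(
    profile: ParticipantProfile,
    fill_level_g: float,
    sip_size: str,
    rng: np.random.Generator,
    *,
    sip_model: SipSizeModel | None = None,
    sample_rate_hz: float = 128.0,
    cup_capacity_g: float = 500.0,
    repetition: int = 0,
) -> DrinkingEvent:
    """Synthesize one labeled drinking event for both sensor placements."""
    if sip_model is None:
        sip_model = SipSizeModel()
    fs = sample_rate_hz

    amount = sip_model.draw_amount(sip_size, fill_level_g, rng)

    # Phase durations (seconds -> samples).
    durs = {p: rng.uniform(*_PHASE_DUR_BOUNDS_S[p]) for p in _PHASE_DUR_BOUNDS_S}
    sip_dur = sip_duration_s(amount, profile.sip_rate_factor) + rng.normal(
        0.0, _SIP_DUR_NOISE_SD_S
    )
    durs["sip"] = max(_SIP_DUR_MIN_S, sip_dur)
    n_phase = {p: max(2, int(round(durs[p] * fs))) for p in GESTURES}
    boundaries = np.cumsum([0] + [n_phase[p] for p in GESTURES])
    n = int(boundaries[-1])
    t = np.arange(n) / fs
    labels = np.repeat(np.arange(5, dtype=np.int8), [n_phase[p] for p in GESTURES])

    # --- container tilt profile (deg, rotation about sensor X axis) ---------
    theta = np.zeros(n)
    peak = (
        peak_tilt_deg(fill_level_g, cup_capacity_g)
        + profile.tilt_offset_deg
        + rng.normal(0.0, _TILT_NOISE_SD_DEG)
    )
    peak = float(np.clip(peak, _TILT_CARRY_DEG + 5.0, 115.0))
    s_pre, e_pre = boundaries[1], boundaries[2]
    s_sip, e_sip = boundaries[2], boundaries[3]
    s_post, e_post = boundaries[3], boundaries[4]
    theta[s_pre:e_pre] = _TILT_CARRY_DEG * _smoothstep(e_pre - s_pre)
    u_sip = np.linspace(0.0, 1.0, e_sip - s_sip, endpoint=False)
    theta[s_sip:e_sip] = _TILT_CARRY_DEG + (peak - _TILT_CARRY_DEG) * np.sin(np.pi * u_sip)
    theta[s_post:e_post] = _TILT_CARRY_DEG * (1.0 - _smoothstep(e_post - s_post))

    # --- container motion signals (noise-free) ------------------------------
    th = np.radians(theta)
    acc_motion = np.column_stack([np.zeros(n), np.sin(th), np.cos(th)])
    gyr_motion = np.zeros((n, 3))
    gyr_motion[:, 0] = np.gradient(theta) * fs  # deg/s about X

    # Lift (pre-sip) and lower (post-sip) vertical acceleration signatures,
    # opposite-signed so the two phases are separable from the accelerometer.
    u_pre = np.linspace(0.0, 1.0, e_pre - s_pre, endpoint=False)
    u_post = np.linspace(0.0, 1.0, e_post - s_post, endpoint=False)
    acc_motion[s_pre:e_pre, 2] += _LIFT_ACC_G * np.sin(2 * np.pi * u_pre)
    acc_motion[s_post:e_post, 2] -= _LIFT_ACC_G * np.sin(2 * np.pi * u_post)

    cont_acc = acc_motion + rng.normal(0.0, _ACC_NOISE_SD_G, (n, 3))
    cont_gyr = gyr_motion + rng.normal(0.0, _GYR_NOISE_SD_DPS, (n, 3))

    # --- wrist: rotated container motion + reach/retract + 3x noise ---------
    rot = _rotation_xy(profile.wrist_offset_x_deg, profile.wrist_offset_y_deg)
    wrist_acc = acc_motion @ rot.T
    wrist_gyr = gyr_motion @ rot.T

    s_gr, e_gr = boundaries[0], boundaries[1]
    s_re, e_re = boundaries[4], boundaries[5]
    u_gr = np.linspace(0.0, 1.0, e_gr - s_gr, endpoint=False)
    u_re = np.linspace(0.0, 1.0, e_re - s_re, endpoint=False)
    # Reach towards the cup (grasp) and retract (release): mirrored bursts.
    wrist_gyr[s_gr:e_gr, 1] += _REACH_GYR_DPS * np.sin(np.pi * u_gr)
    wrist_gyr[s_re:e_re, 1] -= _REACH_GYR_DPS * np.sin(np.pi * u_re)
    wrist_acc[s_gr:e_gr, 0] += _REACH_ACC_G * np.sin(2 * np.pi * u_gr)
    wrist_acc[s_re:e_re, 0] -= _REACH_ACC_G * np.sin(2 * np.pi * u_re)

    # Slow orientation wobble: unlike the rigid cup, the hand jitters around
    # its nominal pose; modeled as a smooth small-angle rotation about X/Y
    # interpolated from low-rate Gaussian nodes.  It perturbs both the wrist
    # gravity direction (inclination) and the gyroscope.
    n_nodes = max(2, int(round(n / fs * _WRIST_WOBBLE_HZ)) + 1)
    node_t = np.linspace(0.0, n / fs, n_nodes)
    wob = np.radians(
        np.column_stack(
            [
                np.interp(t, node_t, rng.normal(0, _WRIST_WOBBLE_SD_DEG, n_nodes)),
                np.interp(t, node_t, rng.normal(0, _WRIST_WOBBLE_SD_DEG, n_nodes)),
                np.zeros(n),
            ]
        )
    )
    wrist_acc = wrist_acc + np.cross(wob, wrist_acc)
    wrist_gyr = wrist_gyr + np.degrees(np.gradient(wob, axis=0)) * fs

    wrist_acc = wrist_acc + rng.normal(0.0, _WRIST_NOISE_FACTOR * _ACC_NOISE_SD_G, (n, 3))
    wrist_gyr = wrist_gyr + rng.normal(0.0, _WRIST_NOISE_FACTOR * _GYR_NOISE_SD_DPS, (n, 3))

    def _finish(a: np.ndarray, g: np.ndarray, placement: str) -> SensorSeries:
        a = np.round(np.clip(a, -ACC_RANGE_G, ACC_RANGE_G), _QUANT_DECIMALS)
        g = np.round(np.clip(g, -GYR_RANGE_DPS, GYR_RANGE_DPS), _QUANT_DECIMALS)
        return SensorSeries(placement, t, a, g, labels, fs)

    event_id = (
        f"p{profile.participant_id:02d}_f{int(round(fill_level_g)):03d}"
        f"_{sip_size}_r{repetition}"
    )
    return DrinkingEvent(
        event_id=event_id,
        participant_id=profile.participant_id,
        fill_level_g=float(fill_level_g),
        sip_size=sip_size,
        repetition=repetition,
        true_amount_g=float(round(amount, 4)),
        wrist=_finish(wrist_acc, wrist_gyr, "wrist"),
        container=_finish(cont_acc, cont_gyr, "container"),
        phase_boundaries=boundaries,
    )


def generate_dataset(
    cfg: ProtocolConfig | None = None, sip_model: SipSizeModel | None = None
) -> list[DrinkingEvent]:
    """Generate the full protocol grid of labeled drinking events.

    Returns ``n_participants x |fill_levels| x |sip_sizes| x repetitions``
    events; identical seeds give identical output.
    """
    if cfg is None:
        cfg = ProtocolConfig()
    if sip_model is None:
        sip_model = SipSizeModel()
    cfg.validate()
    sip_model.validate()

    root = np.random.default_rng(cfg.seed)
    events: list[DrinkingEvent] = []
    for pid in range(1, cfg.n_participants + 1):
        # One child stream per participant: the grid for one person is
        # reproducible independently of how many participants run before them.
        prng = np.random.default_rng(root.integers(0, 2**31 - 1))
        profile = make_profile(pid, prng)
        for fill in cfg.fill_levels_g:
            for size in cfg.sip_sizes:
                for rep in range(cfg.repetitions):
                    events.append(
                        synthesize_event(
                            profile, fill, size, prng,
                            sip_model=sip_model,
                            sample_rate_hz=cfg.sample_rate_hz,
                            cup_capacity_g=cfg.cup_capacity_g,
                            repetition=rep,
                        )
                    )
    return events


# --------------------------------------------------------------------------
# Session-bundle serialization (plain text: CSV per series + JSON metadata)
# --------------------------------------------------------------------------

_CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "label"]


def _series_frame(s: SensorSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": s.t,
            "ax": s.acc[:, 0], "ay": s.acc[:, 1], "az": s.acc[:, 2],
            "gx": s.gyr[:, 0], "gy": s.gyr[:, 1], "gz": s.gyr[:, 2],
            "label": [GESTURES[c] for c in s.labels],
        }
    )


def write_dataset(events: list[DrinkingEvent], outdir: str | Path) -> None:
    """Write one CSV per sensor series plus one JSON metadata file per event."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": FORMAT_VERSION, "n_events": len(events),
                "event_ids": [e.event_id for e in events]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    for e in events:
        for s in (e.wrist, e.container):
            _series_frame(s).to_csv(
                outdir / f"{e.event_id}_{s.placement}.csv",
                index=False, float_format=f"%.{_QUANT_DECIMALS}f",
            )
        meta = {
            "format_version": FORMAT_VERSION,
            "event_id": e.event_id,
            "participant_id": e.participant_id,
            "fill_level_g": e.fill_level_g,
            "sip_size": e.sip_size,
            "repetition": e.repetition,
            "true_amount_g": e.true_amount_g,
            "sample_rate_hz": e.wrist.sample_rate_hz,
            "phase_boundaries": [int(b) for b in e.phase_boundaries],
        }
        (outdir / f"{e.event_id}_meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def _read_series(path: Path, placement: str, fs: float) -> SensorSeries:
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_COLUMNS:
        raise ValueError(f"{path}: unexpected columns {list(df.columns)}")
    labels = np.array([GESTURE_CODES[l] for l in df["label"]], dtype=np.int8)
    return SensorSeries(
        placement=placement,
        t=df["t"].to_numpy(),
        acc=df[["ax", "ay", "az"]].to_numpy(),
        gyr=df[["gx", "gy", "gz"]].to_numpy(),
        labels=labels,
        sample_rate_hz=fs,
    )


def read_dataset(indir: str | Path) -> list[DrinkingEvent]:
    """Read a session bundle written by :func:`write_dataset`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported dataset format version {manifest.get('format_version')!r}"
        )
    events = []
    for eid in manifest["event_ids"]:
        meta = json.loads((indir / f"{eid}_meta.json").read_text())
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"{eid}: unsupported format version")
        fs = meta["sample_rate_hz"]
        events.append(
            DrinkingEvent(
                event_id=eid,
                participant_id=meta["participant_id"],
                fill_level_g=meta["fill_level_g"],
                sip_size=meta["sip_size"],
                repetition=meta["repetition"],
                true_amount_g=meta["true_amount_g"],
                wrist=_read_series(indir / f"{eid}_wrist.csv", "wrist", fs),
                container=_read_series(indir / f"{eid}_container.csv", "container", fs),
                phase_boundaries=np.array(meta["phase_boundaries"], dtype=np.int64),
            )
        )
    return events
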
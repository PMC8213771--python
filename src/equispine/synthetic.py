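"""Forward simulation of trotting-horse marker trajectories.

The generator emulates the study design the pipeline targets: 12 horses
measured on 2 days, 5 trials per day, each trial consisting of a straight-line
measurement and lungeing on left and right circles of ~5 m radius at 100 Hz,
with Gaussian marker noise at the 3.2 mm motion-capture residual scale.

Construction contract (noise-free exactness)
--------------------------------------------
Every configurable stride-mean variable is built so that the measurement
pipeline (stride segmentation -> lean-corrected body frame -> projected
angles) recovers it exactly in the noise-free limit:

1. the spine chain is solved per frame so that the whole-back three-point
   angles (FE in the sagittal body plane, LB in the horizontal body plane)
   equal their configured target series; segment angles follow a smooth bend
   distribution along the chain (six interior bend degrees of freedom cannot
   realise seven independent triplet angles, so segment angles are emergent);
2. the chain is gauged with withers and tubera sacrale on the body long axis,
   so the measured longitudinal axis (horizontal projection of tubera
   sacrale -> withers) coincides with the constructed heading;
3. the whole body is rolled about that axis by the body lean, defined as the
   configured stride-mean pelvis roll for the path (whose default is a static
   roll offset plus the physics prediction arctan(v^2 / g r), signed negative
   on the left circle);
4. the pelvic T-strip is placed by inverting the pipeline's roll / pitch /
   yaw definitions in the rolled frame, and the head by inverting the
   lab-horizontal swivel definition;
5. the body is placed on the path (circle traversed at constant speed, or a
   straight line), with the heading offset from the travel direction by the
   configured body-tracking angle, a double-harmonic vertical trot bounce
   (two croup maxima per stride) applied to the whole body, and a
   stride-harmonic pelvis-roll oscillation driving stance-side labelling;
6. i.i.d. Gaussian noise is added to every lab coordinate.

Random streams are hierarchical (study seed -> horse -> measurement), so
adding horses or measurements never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MarkerTrajectorySet, TrialMeta
from .kinematics import three_point_angle_2d

PATHS = ("straight", "left", "right")

#: variables whose stride mean / ROM the generator can be asked to realise.
CONTROLLED_VARIABLES = (
    "fe_whole_back",
    "lb_whole_back",
    "pelvis_roll",
    "pelvis_pitch",
    "pelvis_yaw",
    "head_swivel",
    "body_tracking",
)

#: variables that flip sign between left and right circles.
LATERAL_CONTROLLED = (
    "lb_whole_back",
    "pelvis_roll",
    "pelvis_yaw",
    "head_swivel",
    "body_tracking",
)


class ConfigError(ValueError):
    pass


def predicted_lean(v: float, r: float, g: float = 9.81) -> float:
    """Body lean [deg] predicted from circular-motion physics.

    A horse trotting a circle of radius ``r`` at speed ``v`` must generate a
    centripetal force m v^2 / r; balancing the ground-reaction resultant
    through the body axis requires leaning inward by arctan(v^2 / (g r)).
    The caller applies the sign (negative for the left circle).
    """
    if r <= 0 or g <= 0:
        raise ValueError("radius and g must be positive")
    if v < 0:
        raise ValueError("speed must be non-negative")
    return math.degrees(math.atan(v * v / (g * r)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# Path-wise stride-mean defaults [deg]; pelvis roll on the circles is derived
# from the lean physics at run time (see SyntheticStudyConfig.resolve_means).
DEFAULT_MEAN_OFFSETS: dict[str, dict[str, float]] = {
    "fe_whole_back": {"straight": -17.6, "left": -17.7, "right": -17.7},
    "lb_whole_back": {"straight": -0.1, "left": -3.9, "right": 3.5},
    "pelvis_roll": {"straight": -1.0},
    "pelvis_pitch": {"straight": 36.9, "left": 37.6, "right": 37.9},
    "pelvis_yaw": {"straight": 2.2, "left": -0.2, "right": 4.5},
    "head_swivel": {"straight": -1.5, "left": -6.7, "right": 3.3},
    "body_tracking": {"straight": 0.1, "left": 2.4, "right": -2.5},
}

# Path-wise half-ROM stride-oscillation amplitudes [deg] (half the reported
# whole-back / pelvic stride ranges per path; swivel/tracking ROM is not
# reported, small values chosen to exercise the pipeline).
DEFAULT_ROM_AMPLITUDES: dict[str, dict[str, float] | float] = {
    "fe_whole_back": {"straight": 2.71, "left": 2.80, "right": 2.725},
    "lb_whole_back": {"straight": 3.675, "left": 4.11, "right": 3.985},
    "pelvis_roll": {"straight": 4.745, "left": 4.675, "right": 4.67},
    "pelvis_pitch": {"straight": 3.885, "left": 4.04, "right": 4.15},
    "pelvis_yaw": {"straight": 2.32, "left": 2.585, "right": 2.665},
    "head_swivel": 1.0,
    "body_tracking": 0.75,
}

# (harmonic, phase [rad]): FE and pitch oscillate at twice the stride
# frequency in trot (one cycle per diagonal stance); lateral variables at the
# stride frequency.  Roll phase 0 puts its extrema at the croup maxima, which
# is what makes stance-side labelling work.
DEFAULT_PHASE_MAP: dict[str, tuple[int, float]] = {
    "fe_whole_back": (2, 1.5),
    "lb_whole_back": (1, 0.5),
    "pelvis_roll": (1, 0.0),
    "pelvis_pitch": (2, 1.0),
    "pelvis_yaw": (1, 2.0),
    "head_swivel": (1, 1.0),
    "body_tracking": (1, 2.5),
}


@dataclass(frozen=True)
class Skeleton:
    """Neutral-pose marker geometry in the body frame (metres)."""

    #: cranio-caudal distance of each spine marker from the withers
    stations: tuple[float, ...] = (0.0, 0.25, 0.40, 0.55, 0.70, 0.82, 0.97, 1.10)
    #: relative bend weight at the six interior chain markers (T12..tuber
    #: sacrale); the profile follows the larger cranial-segment mobility
    bend_weights: tuple[float, ...] = (1.4, 1.1, 1.1, 1.1, 0.35, 0.25)
    tc_halfwidth: float = 0.125  # half the inter-tuber-coxae width
    pelvis_arm: float = 0.20  # tuber-coxae midpoint to tubera sacrale
    neck_length: float = 0.55  # withers to head marker, horizontal
    neck_height: float = 0.25  # head marker height above withers
    base_height: float = 1.35  # nominal back height above the ground
    bounce_amplitude: float = 0.045  # vertical trot-bounce amplitude

    def __post_init__(self) -> None:
        if len(self.stations) != 8 or any(np.diff(self.stations) <= 0):
            raise ConfigError("stations must be 8 strictly increasing distances")
        if len(self.bend_weights) != 6 or any(w < 0 for w in self.bend_weights):
            raise ConfigError("bend_weights must be 6 non-negative values")
        for name in ("tc_halfwidth", "pelvis_arm", "neck_length", "base_height"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class SyntheticStudyConfig:
    """Study design and kinematic targets for the forward simulation."""

    n_horses: int = 12
    days: int = 2
    trials_per_day: int = 5
    paths: tuple[str, ...] = PATHS
    radius: float = 5.0  # circle radius [m]
    speeds: dict[str, float] = field(
        default_factory=lambda: {"straight": 3.73, "left": 3.31, "right": 3.34}
    )
    stride_frequency: float = 1.4  # [Hz]
    g: float = 9.81
    lean_offset: float = 0.0  # additive deviation from the physics lean [deg]
    mean_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    rom_amplitudes: dict[str, float] = field(default_factory=dict)
    phase_map: dict[str, tuple[int, float]] = field(default_factory=dict)
    noise_sd: float = 0.0032  # marker noise [m]
    skeleton: Skeleton = field(default_factory=Skeleton)
    trial_duration: dict[str, float] = field(
        default_factory=lambda: {"straight": 16.0, "left": 25.0, "right": 25.0}
    )
    rate: float = 100.0
    # between-horse / between-measurement variability of the stride means
    horse_sd: float = 1.5  # [deg], shared across paths within horse
    measurement_sd: float = 0.5  # [deg]
    # preferred-speed spread between horses; the reported per-path speed
    # standard errors (~0.04 m/s over 12 horses) imply roughly this scale
    speed_horse_sd: float = 0.14  # [m/s]
    speed_measurement_sd: float = 0.06  # [m/s]
    #: fractional amplitude of the slow within-trial speed fluctuation (two
    #: low-frequency components with random phases; handlers keep speed
    #: roughly, never perfectly, constant)
    speed_wobble: float = 0.025
    speed_wobble_freqs: tuple[float, float] = (0.13, 0.31)  # [Hz]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.paths:
            raise ConfigError("paths must be non-empty")
        for p in self.paths:
            if p not in PATHS:
                raise ConfigError(f"unknown path {p!r}; valid paths: {PATHS}")
        if self.radius <= 0 or self.stride_frequency <= 0 or self.rate <= 0:
            raise ConfigError("radius, stride_frequency and rate must be positive")
        if any(v <= 0 for v in self.speeds.values()):
            raise ConfigError("speeds must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for name in self.mean_offsets:
            if name not in CONTROLLED_VARIABLES:
                raise ConfigError(
                    f"unknown variable {name!r} in mean_offsets; "
                    f"valid names: {', '.join(CONTROLLED_VARIABLES)}"
                )
        for name, amp in self.rom_amplitudes.items():
            if name not in CONTROLLED_VARIABLES:
                raise ConfigError(
                    f"unknown variable {name!r} in rom_amplitudes; "
                    f"valid names: {', '.join(CONTROLLED_VARIABLES)}"
                )
            vals = amp.values() if isinstance(amp, Mapping) else (amp,)
            if any(a < 0 for a in vals):
                raise ConfigError(f"rom amplitude for {name!r} must be >= 0")
        for name in self.phase_map:
            if name not in CONTROLLED_VARIABLES:
                raise ConfigError(
                    f"unknown variable {name!r} in phase_map; "
                    f"valid names: {', '.join(CONTROLLED_VARIABLES)}"
                )

    # -- resolution helpers -------------------------------------------------

    def amplitude(self, var: str, path: str) -> float:
        amp = self.rom_amplitudes.get(var, DEFAULT_ROM_AMPLITUDES[var])
        if isinstance(amp, Mapping):
            return amp.get(path, next(iter(amp.values())))
        return float(amp)

    def phase(self, var: str) -> tuple[int, float]:
        return self.phase_map.get(var, DEFAULT_PHASE_MAP[var])

    def resolve_means(self, path: str, speed: float | None = None) -> dict[str, float]:
        """Stride-mean targets for one path.

        Explicit entries in ``mean_offsets`` win; otherwise defaults apply.
        The default circle pelvis roll is the straight-line (marker/posture)
        roll offset plus the signed physics lean at the actual speed.
        """
        v = speed if speed is not None else self.speeds[path]
        out: dict[str, float] = {}
        for var in CONTROLLED_VARIABLES:
            user = self.mean_offsets.get(var, {})
            if path in user:
                out[var] = user[path]
                continue
            default = DEFAULT_MEAN_OFFSETS[var]
            if var == "pelvis_roll" and path in ("left", "right"):
                rho0 = user.get("straight", default["straight"])
                lean = predicted_lean(v, self.radius, self.g) + self.lean_offset
                out[var] = rho0 + (lean if path == "right" else -lean)
            else:
                out[var] = default[path]
        return out


# ---------------------------------------------------------------------------
# spine-chain solve
# ---------------------------------------------------------------------------

def _chain_offsets(scale: np.ndarray, stations: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Transverse chain offsets (8, n) for bend scale(s) [rad] per frame.

    Bends ``scale * weights`` are applied at the six interior markers; the
    chain is gauged so the withers and tubera sacrale offsets are zero.
    """
    scale = np.atleast_1d(np.asarray(scale, dtype=float))
    n = scale.shape[0]
    betas = weights[:, None] * scale[None, :]  # (6, n)
    phis = np.vstack([np.zeros((1, n)), -np.cumsum(betas, axis=0)])  # (7, n)
    ds = np.diff(stations)  # (7,)
    u = np.zeros((8, n))
    for k in range(7):
        u[k + 1] = u[k] + ds[k] * np.tan(phis[k])
    # remove the linear trend so u[0] = u[6] = 0 (withers and tubera sacrale
    # stay on the body long axis; angles are affine-gauge invariant)
    span = stations[6] - stations[0]
    u -= u[6][None, :] * ((stations - stations[0]) / span)[:, None]
    return u


def _whole_back_angle(u: np.ndarray, stations: np.ndarray) -> np.ndarray:
    """Three-point whole-back angle [deg] (markers 0, 2, 6) from offsets."""
    s = np.broadcast_to(stations[:, None], u.shape)
    return three_point_angle_2d(s[0], u[0], s[2], u[2], s[6], u[6])


def solve_chain(target_deg: np.ndarray, skeleton: Skeleton) -> np.ndarray:
    """Chain offsets (8, n) whose whole-back three-point angle equals the
    target series, solved per frame by damped Newton iteration."""
    stations = np.asarray(skeleton.stations, dtype=float)
    weights = np.asarray(skeleton.bend_weights, dtype=float)
    weights = weights / weights.sum()
    target = np.atleast_1d(np.asarray(target_deg, dtype=float))
    # linearised gain dA/ds at zero bend
    eps = 1e-4
    gain = _whole_back_angle(_chain_offsets(np.array([eps]), stations, weights), stations)[0] / eps
    scale = target / gain
    for _ in range(25):
        u = _chain_offsets(scale, stations, weights)
        a = _whole_back_angle(u, stations)
        err = target - a
        if np.max(np.abs(err)) < 1e-11:
            break
        du = _chain_offsets(scale + 1e-6, stations, weights)
        da = (_whole_back_angle(du, stations) - a) / 1e-6
        da = np.where(np.abs(da) < 1e-9, gain, da)
        scale = scale + err / da
    return _chain_offsets(scale, stations, weights)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _rotz(h: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Rotate (n, 3) vectors about the lab vertical by per-frame angles."""
    c, s = np.cos(h), np.sin(h)
    out = np.empty_like(vec)
    out[:, 0] = c * vec[:, 0] - s * vec[:, 1]
    out[:, 1] = s * vec[:, 0] + c * vec[:, 1]
    out[:, 2] = vec[:, 2]
    return out


def _generate(
    config: SyntheticStudyConfig,
    meta: TrialMeta,
    means: Mapping[str, float],
    speed: float,
    rng: np.random.Generator,
) -> MarkerTrajectorySet:
    sk = config.skeleton
    path = meta.path
    f = config.stride_frequency
    duration = config.trial_duration[path]
    n = int(round(duration * config.rate))
    t = np.arange(n) / config.rate
    wt = 2.0 * math.pi * f * t

    def series(var: str) -> np.ndarray:
        harmonic, phase = config.phase(var)
        return means[var] + config.amplitude(var, path) * np.cos(harmonic * wt + phase)

    fe = series("fe_whole_back")
    lb = series("lb_whole_back")
    roll_t = series("pelvis_roll")
    pitch_t = np.radians(series("pelvis_pitch"))
    yaw_t = np.radians(series("pelvis_yaw"))
    swivel_t = np.radians(series("head_swivel"))
    track_t = np.radians(series("body_tracking"))

    stations = np.asarray(sk.stations, dtype=float)
    x_sp = 0.55 - stations  # cranial-positive body x of the spine markers
    z_off = solve_chain(fe, sk)  # (8, n) sagittal offsets
    y_off = solve_chain(lb, sk)  # (8, n) lateral offsets (left positive)

    # body lean = stride-mean pelvis roll for the path (the oscillation is a
    # pelvis-local rotation, so the windowed roll mean recovers exactly this)
    lam = math.radians(means["pelvis_roll"])
    cl, sl = math.cos(lam), math.sin(lam)
    h0 = sk.base_height

    # spine markers: roll the chain about the body long axis (y = z = 0 line
    # at height h0); the withers and tubera sacrale lie on that axis
    spine = np.empty((8, n, 3))
    spine[:, :, 0] = x_sp[:, None]
    spine[:, :, 1] = y_off * cl - z_off * sl
    spine[:, :, 2] = h0 + y_off * sl + z_off * cl

    # rolled body axes in the heading frame
    e_long = np.array([1.0, 0.0, 0.0])
    e_vert = np.array([0.0, -sl, cl])
    e_t = np.array([0.0, cl, sl])

    ts_pos = spine[6]  # tubera sacrale, on the roll axis: (x_ts, 0, h0)

    # pelvis T-strip: invert the pipeline's pitch / yaw / roll definitions
    mid_tc = ts_pos + sk.pelvis_arm * (
        np.cos(pitch_t)[:, None] * e_long - np.sin(pitch_t)[:, None] * e_vert
    )
    u_dir = np.sin(yaw_t)[:, None] * e_long - np.cos(yaw_t)[:, None] * e_t  # (n, 3)
    a_coef = u_dir[:, 2]
    b_coef = e_vert[2]
    target_z = np.sin(np.radians(-roll_t))
    r_amp = np.hypot(a_coef, b_coef)
    gamma = np.arcsin(np.clip(target_z / r_amp, -1.0, 1.0)) - np.arctan2(a_coef, b_coef)
    d_dir = np.cos(gamma)[:, None] * u_dir + np.sin(gamma)[:, None] * e_vert
    tc_left = mid_tc - sk.tc_halfwidth * d_dir
    tc_right = mid_tc + sk.tc_halfwidth * d_dir

    # head: lab-horizontal swivel relative to the body axis, so the neck
    # offset lives in the (unrolled) heading frame
    withers = spine[0]
    head = withers + np.column_stack(
        [
            sk.neck_length * np.cos(swivel_t),
            -sk.neck_length * np.sin(swivel_t),
            np.full(n, sk.neck_height),
        ]
    )

    # path placement at a slowly fluctuating speed (arc-length integration)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=2)
    f1, f2 = config.speed_wobble_freqs
    v_t = speed * (
        1.0
        + config.speed_wobble
        * (np.sin(2 * math.pi * f1 * t + phases[0]) + np.sin(2 * math.pi * f2 * t + phases[1]))
    )
    arc = np.concatenate(([0.0], np.cumsum(0.5 * (v_t[1:] + v_t[:-1])))) / config.rate
    if path == "straight":
        h_path = np.zeros(n)
        pos = np.column_stack([arc, np.zeros(n), np.full(n, h0)])
    else:
        sgn = 1.0 if path == "left" else -1.0
        ang = arc / config.radius
        h_path = sgn * ang
        pos = np.column_stack(
            [
                config.radius * np.sin(ang),
                sgn * (config.radius - config.radius * np.cos(ang)),
                np.full(n, h0),
            ]
        )
    h_body = h_path - track_t  # positive tracking = forehand right of travel

    bounce = sk.bounce_amplitude * np.cos(2.0 * wt)
    markers = {
        "head": head,
        "withers": spine[0],
        "T12": spine[1],
        "T15": spine[2],
        "T18": spine[3],
        "L3": spine[4],
        "L5": spine[5],
        "tuber_sacrale": spine[6],
        "tuber_coxae_left": tc_left,
        "tuber_coxae_right": tc_right,
        "S5": spine[7],
    }
    out: dict[str, np.ndarray] = {}
    for name, q in markers.items():
        lab = pos + _rotz(h_body, q - ts_pos)
        lab[:, 2] += bounce
        if config.noise_sd > 0:
            lab = lab + rng.normal(0.0, config.noise_sd, lab.shape)
        out[name] = lab
    return MarkerTrajectorySet(out, config.rate, meta)


def generate_trial(
    config: SyntheticStudyConfig,
    horse: str,
    day: int,
    trial: int,
    path: str,
    seed: int,
) -> MarkerTrajectorySet:
    """One measurement at the configured path means (no study-level random
    effects); deterministic for a fixed seed."""
    if path not in PATHS:
        raise ConfigError(f"unknown path {path!r}; valid paths: {PATHS}")
    rng = np.random.default_rng(seed)
    speed = config.speeds[path]
    meta = TrialMeta(
        horse=horse,
        day=day,
        trial=trial,
        path=path,
        radius=config.radius if path != "straight" else None,
    )
    return _generate(config, meta, config.resolve_means(path, speed), speed, rng)


def generate_study(config: SyntheticStudyConfig) -> Iterator[MarkerTrajectorySet]:
    """Yield one trajectory set per horse x day x trial x path.

    Per-horse offsets (shared across paths) and per-measurement offsets
    perturb the configured stride means, realising the mixed model's
    measurement-within-horse variance structure.  Streams are spawned
    hierarchically from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    horse_seqs = root.spawn(config.n_horses)
    n_meas = config.days * config.trials_per_day * len(config.paths)
    for i, hseq in enumerate(horse_seqs):
        kids = hseq.spawn(1 + n_meas)
        rng_h = np.random.default_rng(kids[0])
        horse_off = {
            var: rng_h.normal(0.0, config.horse_sd) for var in CONTROLLED_VARIABLES
        }
        horse_speed = rng_h.normal(0.0, config.speed_horse_sd)
        horse = f"horse{i + 1:02d}"
        k = 1
        for day in range(1, config.days + 1):
            for trial in range(1, config.trials_per_day + 1):
                for path in config.paths:
                    rng_m = np.random.default_rng(kids[k])
                    k += 1
                    speed = max(
                        0.5,
                        config.speeds[path]
                        + horse_speed
                        + rng_m.normal(0.0, config.speed_measurement_sd),
                    )
                    means = config.resolve_means(path, speed)
                    for var in CONTROLLED_VARIABLES:
                        means[var] += horse_off[var] + rng_m.normal(
                            0.0, config.measurement_sd
                        )
                    meta = TrialMeta(
                        horse=horse,
                        day=day,
                        trial=trial,
                        path=path,
                        radius=config.radius if path != "straight" else None,
                    )
                    yield _generate(config, meta, means, speed, rng_m)


# ---------------------------------------------------------------------------
# stride-table simulation (model-level calibration)
# ---------------------------------------------------------------------------

def simulate_stride_table(
    n_horses: int = 12,
    days: int = 2,
    trials_per_day: int = 5,
    paths: Sequence[str] = PATHS,
    strides_per_measurement: int = 12,
    path_effects: Mapping[str, float] | None = None,
    speed_means: Mapping[str, float] | None = None,
    speed_slope: float = 0.0,
    horse_sd: float = 1.0,
    measurement_sd: float = 0.5,
    stride_sd: float = 0.8,
    speed_sd: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a stride-level response table straight from the mixed model's
    generative structure (horse and measurement-within-horse random
    intercepts plus stride noise), for calibration studies of the statistics
    layer without the marker-level forward model."""
    path_effects = dict(path_effects or {})
    speed_means = dict(speed_means or {"straight": 3.73, "left": 3.31, "right": 3.34})
    rng = np.random.default_rng(seed)
    grand = float(np.mean([speed_means[p] for p in paths]))
    rows = []
    for i in range(n_horses):
        horse = f"horse{i + 1:02d}"
        u_h = rng.normal(0.0, horse_sd)
        for day in range(1, days + 1):
            for trial in range(1, trials_per_day + 1):
                for path in paths:
                    u_m = rng.normal(0.0, measurement_sd)
                    speed = speed_means[path] + rng.normal(0.0, speed_sd)
                    mid = f"{horse}-d{day}-t{trial}-{path}"
                    mu = (
                        path_effects.get(path, 0.0)
                        + speed_slope * (speed - grand)
                        + u_h
                        + u_m
                    )
                    vals = mu + rng.normal(0.0, stride_sd, strides_per_measurement)
                    for sidx, val in enumerate(vals):
                        rows.append(
                            (horse, day, trial, path, mid, sidx, speed, float(val))
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "horse",
            "day",
            "trial",
            "path",
            "measurement",
            "stride",
            "speed",
            "value",
        ],
    )
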
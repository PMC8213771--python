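"""Lean-corrected spinal and pelvic angle computation.

All angles are in degrees.  The body reference frame is right-handed with the
longitudinal axis pointing cranially (horizontal projection of the tubera
sacrale -> withers line), the transverse axis pointing to the horse's left and
the vertical axis obtained by rolling the lab vertical about the longitudinal
axis by the horse's body lean.  Lean is approximated per frame by the centred
moving average of raw pelvis roll over one stride (median stride duration x
sampling rate), so that flexion-extension and lateral bending are measured in
anatomical planes on the circle as well as on the straight.

Sign conventions
----------------
* flexion-extension (FE): 0 when the three markers are level, positive for
  flexion (mid marker dorsal to the cranial-caudal chord), negative for
  extension;
* lateral bending (LB): 0 when the markers lie in the sagittal plane, positive
  for bending of the back to the right (mid marker to the horse's left of the
  chord);
* pelvis roll: positive when the right tuber coxae is lower (lean right);
* pelvis pitch: positive for an upward slope from the tuber-coxae midpoint to
  the tubera sacrale;
* pelvis yaw: positive for "tail to the right";
* head swivel: positive with the head to the right of the body axis;
* body tracking: positive for "forehand to the right / hindquarters to the
  left" relative to the direction of travel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .io import MarkerTrajectorySet

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import StrideSegmentation

#: three-point angle triplets (cranial, mid, caudal); the first is the whole
#: thoracolumbar back, the rest are the overlapping segments.
ANGLE_TRIPLETS: dict[str, tuple[str, str, str]] = {
    "whole_back": ("withers", "T15", "tuber_sacrale"),
    "withers_T12_T15": ("withers", "T12", "T15"),
    "T12_T15_T18": ("T12", "T15", "T18"),
    "T15_T18_L3": ("T15", "T18", "L3"),
    "T18_L3_L5": ("T18", "L3", "L5"),
    "L3_L5_tuber_sacrale": ("L3", "L5", "tuber_sacrale"),
    "L5_tuber_sacrale_S5": ("L5", "tuber_sacrale", "S5"),
}

SPINE_ANGLE_NAMES: tuple[str, ...] = tuple(
    f"{plane}_{trip}" for plane in ("fe", "lb") for trip in ANGLE_TRIPLETS
)

OTHER_ANGLE_NAMES: tuple[str, ...] = (
    "pelvis_roll",
    "pelvis_pitch",
    "pelvis_yaw",
    "head_swivel",
    "body_tracking",
    "speed",
)

ALL_VARIABLES: tuple[str, ...] = SPINE_ANGLE_NAMES + OTHER_ANGLE_NAMES

#: variables that flip sign under a left-right mirror of the lab frame.
LATERAL_VARIABLES: tuple[str, ...] = tuple(
    n for n in ALL_VARIABLES if n.startswith("lb_")
) + ("pelvis_roll", "pelvis_yaw", "head_swivel", "body_tracking")

MIN_TRACKING_SPEED = 0.2  # m/s; below this the travel direction is undefined


@dataclass(frozen=True)
class AngleErrorModel:
    """Worst-case single-frame angle error from marker position residuals."""

    residual: float  # marker position error [m]
    segment_length: float  # inter-marker distance [m]


def angle_error_bound(m: AngleErrorModel) -> float:
    """Maximum angle error, in degrees, for one marker displaced by the
    position residual perpendicular to a segment of the given length."""
    if m.residual < 0 or m.segment_length <= 0:
        raise ValueError("residual must be >= 0 and segment_length > 0")
    return math.degrees(math.atan(m.residual / m.segment_length))


@dataclass
class BodyFrameSeries:
    """Per-frame lean-corrected body frame.

    Axes are unit vectors in lab coordinates; ``lean`` is the windowed mean
    pelvis roll in degrees; ``valid`` flags frames with a well-defined
    longitudinal axis.
    """

    origin: np.ndarray  # (n, 3) tubera sacrale position
    e_long: np.ndarray  # (n, 3) cranial
    e_trans: np.ndarray  # (n, 3) horse's left
    e_vert: np.ndarray  # (n, 3) lab vertical rolled by lean
    lean: np.ndarray  # (n,) degrees
    valid: np.ndarray  # (n,) bool

    @property
    def n_frames(self) -> int:
        return self.origin.shape[0]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetrically shrinking windows at edges.

    At frame i the half-width is ``min(window // 2, i, n - 1 - i)``, so the
    window is always centred on the frame in question.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n == 0:
        return x.copy()
    half = min(window // 2, n - 1)
    idx = np.arange(n)
    h = np.minimum(np.minimum(idx, n - 1 - idx), half)
    if x.ndim == 1:
        csum = np.concatenate(([0.0], np.cumsum(x)))
        return (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)
    csum = np.vstack([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    return (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)[:, None]


def pelvis_roll_lab(t: MarkerTrajectorySet) -> np.ndarray:
    """Raw pelvis roll [deg] relative to the lab horizontal.

    Elevation angle of the left -> right tuber-coxae line, positive when the
    right marker is lower (lean to the right).
    """
    d = t["tuber_coxae_right"] - t["tuber_coxae_left"]
    horiz = np.hypot(d[:, 0], d[:, 1])
    if np.any(horiz == 0):
        raise ValueError("coincident tuber coxae markers: pelvis roll undefined")
    return np.degrees(np.arctan2(-d[:, 2], horiz))


def lean_corrected_frame(t: MarkerTrajectorySet, seg: "StrideSegmentation") -> BodyFrameSeries:
    """Build the per-frame lean-corrected body frame.

    The lean is the centred moving average of raw pelvis roll over a window of
    one median stride duration; the longitudinal axis is the unit horizontal
    projection of tubera sacrale -> withers; the vertical axis is the lab
    vertical rotated about the longitudinal axis by the lean.
    """
    roll = pelvis_roll_lab(t)
    window = max(1, int(round(seg.median_stride_duration * t.rate)))
    lean = centered_moving_average(roll, window)

    ts = t["tuber_sacrale"]
    wi = t["withers"]
    axis = wi - ts
    axis_h = axis.copy()
    axis_h[:, 2] = 0.0
    norm = np.linalg.norm(axis_h, axis=1)
    valid = norm > 1e-9
    e_long = np.zeros_like(axis_h)
    e_long[valid] = axis_h[valid] / norm[valid, None]

    lam = np.radians(lean)
    zhat = np.array([0.0, 0.0, 1.0])
    # horizontal left direction before lean correction
    left0 = np.cross(np.broadcast_to(zhat, e_long.shape), e_long)
    e_vert = np.cos(lam)[:, None] * zhat - np.sin(lam)[:, None] * left0
    e_trans = np.cross(e_vert, e_long)
    return BodyFrameSeries(ts, e_long, e_trans, e_vert, lean, valid)


def _project(points: np.ndarray, frame: BodyFrameSeries, plane: str) -> tuple[np.ndarray, np.ndarray]:
    """Project lab points onto a named body plane.

    Returns per-frame 2-D coordinates (longitudinal, u) where u is the
    vertical axis for FE and the transverse (left) axis for LB.
    """
    rel = points - frame.origin
    ell = np.einsum("ij,ij->i", rel, frame.e_long)
    if plane == "FE":
        u = np.einsum("ij,ij->i", rel, frame.e_vert)
    elif plane == "LB":
        u = np.einsum("ij,ij->i", rel, frame.e_trans)
    else:
        raise ValueError(f"unknown plane {plane!r}; use 'FE' or 'LB'")
    return ell, u


def three_point_angle_2d(
    sc: np.ndarray, uc: np.ndarray,
    sm: np.ndarray, um: np.ndarray,
    sd: np.ndarray, ud: np.ndarray,
) -> np.ndarray:
    """Signed deviation from collinearity at the mid point, in degrees.

    Magnitude is 180 deg minus the included angle at the mid point; the sign is
    positive when the mid point lies on the +u side of the cranial -> caudal
    chord.  Works on scalars or equally-shaped arrays.
    """
    av = np.stack([sc - sm, uc - um], axis=-1)
    bv = np.stack([sd - sm, ud - um], axis=-1)
    na = np.linalg.norm(av, axis=-1)
    nb = np.linalg.norm(bv, axis=-1)
    bad = (na == 0) | (nb == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", av, bv) / (na * nb)
    mag = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    # side of the mid point relative to the chord line (parameterisation-free)
    chord_s = sd - sc
    chord_u = ud - uc
    side = (um - uc) * chord_s - (sm - sc) * chord_u
    sign = np.sign(side) * np.sign(chord_s)
    sign = np.where(sign == 0, 1.0, sign)
    out = np.where(bad, np.nan, mag * sign)
    return out


def projected_spine_angle(
    p_cranial: np.ndarray,
    p_mid: np.ndarray,
    p_caudal: np.ndarray,
    frame: BodyFrameSeries,
    plane: str,
) -> np.ndarray:
    """Signed projected three-point angle series for one marker triplet."""
    sc, uc = _project(np.atleast_2d(p_cranial), frame, plane)
    sm, um = _project(np.atleast_2d(p_mid), frame, plane)
    sd, ud = _project(np.atleast_2d(p_caudal), frame, plane)
    return three_point_angle_2d(sc, uc, sm, um, sd, ud)


def compute_spine_angles(
    t: MarkerTrajectorySet, frame: BodyFrameSeries
) -> dict[str, np.ndarray]:
    """All 14 FE/LB angle series (7 triplets x 2 planes), degrees."""
    out: dict[str, np.ndarray] = {}
    for trip_name, (c, m, d) in ANGLE_TRIPLETS.items():
        for plane in ("FE", "LB"):
            key = f"{plane.lower()}_{trip_name}"
            out[key] = projected_spine_angle(t[c], t[m], t[d], frame, plane)
    return out


def pelvis_rotations(
    t: MarkerTrajectorySet, frame: BodyFrameSeries
) -> dict[str, np.ndarray]:
    """Pelvis roll (lab-referenced), pitch and yaw (body-frame), degrees."""
    roll = pelvis_roll_lab(t)

    mid_tc = 0.5 * (t["tuber_coxae_left"] + t["tuber_coxae_right"])
    v = t["tuber_sacrale"] - mid_tc
    vl = np.einsum("ij,ij->i", v, frame.e_long)
    vv = np.einsum("ij,ij->i", v, frame.e_vert)
    # measured against the caudal direction: positive = upward slope to sacrum
    pitch = np.degrees(np.arctan2(vv, -vl))

    d = t["tuber_coxae_right"] - t["tuber_coxae_left"]
    dl = np.einsum("ij,ij->i", d, frame.e_long)
    dt = np.einsum("ij,ij->i", d, frame.e_trans)
    # cranial-pointing normal of the tuber-coxae line; positive = tail right
    yaw = np.degrees(np.arctan2(dl, -dt))
    return {"pelvis_roll": roll, "pelvis_pitch": pitch, "pelvis_yaw": yaw}


def _signed_horizontal_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed lab-horizontal angle from a to b, positive clockwise from above
    (i.e. positive when b points to the right of a), degrees."""
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    return -np.degrees(np.arctan2(cross, dot))


def head_swivel_and_tracking(
    t: MarkerTrajectorySet,
    frame: BodyFrameSeries,
    seg: "StrideSegmentation | None" = None,
) -> dict[str, np.ndarray]:
    """Head swivel, body tracking and speed series.

    Speed is the norm of the centrally-differenced horizontal tubera sacrale
    velocity, smoothed with the lean window; tracking is the signed horizontal
    angle from the travel direction to the body axis (undefined below
    ``MIN_TRACKING_SPEED``); swivel is the signed horizontal angle from the
    body axis to the withers -> head line, positive head-right.
    """
    if t.n_frames < 2:
        raise ValueError("need at least 2 frames for velocity estimation")
    ts = t["tuber_sacrale"]
    vel = np.gradient(ts[:, :2], axis=0) * t.rate
    window = max(1, int(round((seg.median_stride_duration if seg else 0.0) * t.rate)))
    if window > 1:
        vel = centered_moving_average(vel, window)
    speed = np.hypot(vel[:, 0], vel[:, 1])

    tracking = _signed_horizontal_angle(vel, frame.e_long)
    tracking = np.where(speed < MIN_TRACKING_SPEED, np.nan, tracking)

    neck = t["head"] - t["withers"]
    swivel = _signed_horizontal_angle(frame.e_long, neck)
    return {"head_swivel": swivel, "body_tracking": tracking, "speed": speed}


def compute_all_variables(
    t: MarkerTrajectorySet, seg: "StrideSegmentation"
) -> dict[str, np.ndarray]:
    """Every per-frame variable of the analysis, keyed by name."""
    frame = lean_corrected_frame(t, seg)
    out = compute_spine_angles(t, frame)
    out.update(pelvis_rotations(t, frame))
    out.update(head_swivel_and_tracking(t, frame, seg))
    return out
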
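# Methods

`equispine` implements a complete measurement-and-analysis chain for equine
thoracolumbar kinematics in trot, comparing straight-line locomotion with
lungeing on left and right circles. This note documents the model, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Measurement model

### Input data

Each measurement is a set of 3-D marker trajectories at 100 Hz: a head
marker, the highest point of the withers, single markers on the dorsal
spinous processes of T12, T15, T18, L3 and L5, the sacral S5 marker, and a
pelvic T-strip carrying the tubera sacrale marker and both tuber coxae
markers. Files store millimetres; the library works in metres, z up,
right-handed, with no assumption about the direction of travel (on a circle
it rotates continuously). Missing samples are explicit gaps; gaps of at most
10 frames (0.1 s) in required markers are linearly interpolated, longer gaps
mark the measurement as unusable ("poor marker tracking"). The 10-frame
threshold is this package's choice — published QC descriptions discard such
measurements without defining a threshold.

### Stride segmentation

In trot the croup oscillates vertically twice per stride, once per diagonal
stance. The tubera sacrale height is high-pass filtered with a zero-lag
(forward–backward) Butterworth filter of order 4 (effective order 8) at 70%
of the stride frequency, and stride events are the local maxima of the
filtered signal. The stride frequency itself is estimated as half the
periodogram peak of the mean-removed height over 1–5 Hz; peak detection
requires prominence of at least 25% of the filtered signal's RMS and event
spacing of at least 0.3/f. Each event is labelled left/right hind stance
from the sign of the pelvis-roll stride oscillation, obtained by band-passing
raw roll between the segmentation cut-off and 2f (the high-pass leg is
essential on the circle, where the body-lean mean of ±13° would otherwise fix
the sign). Strides are full cycles anchored on the event sequence — every
second event, starting from the first — which makes the intervals invariant
under a left–right mirror of the scene and robust when the roll oscillation
is weak. Stride durations outside 0.4–1.2 s are rejected. Measurements with
fewer than five complete strides are discarded.

### Body-lean-corrected reference frame

On a circle a horse leans inward; computing flexion–extension (FE) and
lateral bending (LB) in lab-fixed planes would then mix the two (projection
crosstalk). Body lean is approximated by the stride-averaged pelvis roll: per
frame, the centred moving average of raw roll over one median stride duration
(edge frames shrink the window symmetrically). The body frame is

* longitudinal axis: unit horizontal projection of tubera sacrale → withers;
* vertical axis: lab vertical rotated about the longitudinal axis by the
  lean;
* transverse axis: their cross product (pointing to the horse's left).

The lean correction applies to the 14 thoracolumbar angles and to pelvis
pitch and yaw. Pelvis roll stays lab-referenced by definition, and speed is
lab-horizontal.

### Angles

All angles are in degrees. For each of seven marker triplets (the whole back
withers–T15–tubera sacrale, plus six overlapping segments from withers to
S5), the three points are projected onto the sagittal (FE) or horizontal (LB)
plane of the body frame and the angle is the signed deviation from
collinearity at the middle marker: 180° minus the included angle, positive
when the middle marker is dorsal to the cranial–caudal chord (FE, flexion)
or to the horse's left of it (LB, bending right — the spine is then convex
left). Sign conventions follow the published worked descriptions: FE negative
is extension (mid marker ventral), roll negative is lean left, yaw positive
is tail right, head swivel positive is head right, tracking positive is
forehand right of the travel direction. (One published results sentence
describes the straight-line tracking sign the opposite way from the methods
definition; this package follows the methods definition.)

Pelvis rotations: roll is the elevation of the left→right tuber-coxae line
above the lab horizontal, positive right-lower; pitch is the angle, in the
sagittal body plane, of the mid-coxae → tubera sacrale vector against the
caudal direction of the body line, positive for an upward slope (~37° in a
neutral pose); yaw is the angle of the tuber-coxae line's cranial normal
against the body axis in the horizontal body plane. The normal-based yaw
definition is chosen so a neutral pelvis reads 0°.

Speed is the norm of the centrally differenced horizontal tubera sacrale
velocity, smoothed with the lean window; on a 5 m circle this chord-based
estimate reads ~1% below the true path speed. Body tracking (angle from the
velocity direction to the body axis) is undefined below 0.2 m/s. Head swivel
is the horizontal angle from the body axis to the withers→head line.

Because projected angles are planar, a rigid 5° yaw of the pelvis shifts the
projected pitch by sin(p)·cos(p)·(1−cos 5°) ≈ 0.1° at p ≈ 37–45°. This
second-order projection shortening is inherent to planar angle definitions
and is distinct from the first-order roll crosstalk the lean correction
removes.

### Summaries and models

Stride mean and ROM (max − min) are computed per stride on the raw,
unfiltered series (the filter exists only for event detection); strides with
more than 20% missing frames for a variable yield no record. Two mixed-model
families are fitted on stride-by-stride data by REML (statsmodels MixedLM),
both with a random intercept per horse plus a variance component for
measurement within horse (the nested reading of "measurement within horse";
a measurement-only structure is available behind a switch):

1. **Path comparison** — fixed effects path, speed and path×speed;
   least-squares means per path evaluated at the speed grand mean; the three
   pairwise differences tested with Benjamini–Hochberg FDR adjustment within
   each model; α = 0.05.
2. **Association models** — whole-back FE/LB mean or ROM regressed, per
   path, on the pelvic rotations (matching statistic), speed, and stride-mean
   head swivel and body tracking; for FE responses, swivel and tracking enter
   as absolute values; all fixed effects are retained.

p-values use the large-sample normal approximation; the published analysis
used an external package's default degrees-of-freedom method, so p-values are
comparable but not bit-identical. Responses are untransformed.

### Error model

A marker position residual ε perpendicular to a segment of length L bounds
the single-frame angle error by arctan(ε/L): 1.2° for ε = 3.2 mm and
L = 0.15 m (back segments), 0.4° for L = 0.5 m. Per-stride averaging reduces
the effective error by roughly the square root of the frames per stride.

## Synthetic-data generator

The generator forward-simulates the full study design — by default 12 horses
× 2 days × 5 trials/day × 3 paths (straight ~16 s, circles 25 s at ~5 m
radius), 360 measurements — with Gaussian marker noise at the 3.2 mm
motion-capture residual scale. Its central property is **noise-free
exactness**: every configurable stride-mean variable is constructed by
inverting the measurement definitions, so the pipeline recovers configured
values to well under 0.05° on noise-free data. Concretely:

* the spine chain (8 markers over a 0.97 m whole-back span) is solved per
  frame by damped Newton iteration so that the whole-back three-point FE and
  LB angles equal their target series; bends are distributed over the six
  interior markers with a fixed profile weighted toward the more mobile
  cranial segments. Segment angles are emergent, not configurable: six
  interior bend degrees of freedom cannot satisfy seven independent triplet
  angles;
* the chain is gauged with withers and tubera sacrale on the body axis, so
  the measured longitudinal axis coincides with the constructed heading;
* the whole body is rolled about that axis by the body lean, defined as the
  per-path stride-mean pelvis roll. Default roll means follow the
  circular-motion physics: a static roll offset (−1° straight-line
  marker/posture asymmetry) plus arctan(v²/gr) signed by circle direction,
  which reproduces the reported circle roll levels to ~0.1°;
* the pelvic T-strip inverts the pipeline's roll/pitch/yaw definitions in
  the rolled frame, and the head placement inverts the lab-horizontal swivel
  definition;
* the trot bounce (two croup maxima per stride, 4.5 cm amplitude) is a rigid
  vertical translation of the whole body, so it exercises segmentation
  without touching any angle; the stride-harmonic roll oscillation phase is
  locked to the bounce so stance sides alternate;
* speed fluctuates slowly within each trial (two components below the stride
  frequency, ~2.5% amplitude, random phases). Handlers keep speed roughly
  but never perfectly constant, and without within-measurement speed
  variation the path×speed interaction of the prescribed model would be
  nearly unidentifiable — a degeneracy real data do not have;
* per-horse offsets (shared across paths, SD 1.5°; preferred speed SD
  0.14 m/s, the scale implied by the reported per-path speed standard
  errors) and per-measurement offsets (SD 0.5°, speed SD 0.06 m/s) realise
  the measurement-within-horse variance structure. Random streams are
  hierarchical (study → horse → measurement), so adding horses never
  perturbs existing data.

Default stride frequency is 1.4 Hz (typical trot; not a reported value);
default stride-mean targets are the published straight/left/right LS means,
and default oscillation half-amplitudes are half the published per-path
ranges. Within-stride waveform shapes (harmonics and phases) are plausible
trot mechanics — FE and pitch at twice the stride frequency, lateral
variables at the stride frequency — but are placeholders for the real
waveforms, which are not published as parameters.

### What the generator does not emulate

Skin-marker displacement artefacts, hoof-timing events, ground-reaction
forces, stride-to-stride cadence variability, axial rotation of individual
vertebrae, and any nonlinear speed–angle coupling. Passing tests therefore
demonstrate that the measurement chain is geometrically and statistically
correct — that the pipeline inverts its own definitions exactly and that the
models recover known effects under the study's noise and variance structure —
not that it is robust to every artefact of real capture data.

Mirroring note: generating a right-circle trial with sign-flipped lateral
targets (and stride-phase shifts of π for the lateral oscillations)
reproduces the left-circle trial reflected through the x–z plane exactly in
the noise-free limit, with the anatomically paired tuber-coxae markers
swapping labels, as a physical reflection demands. With noise the identity
cannot hold bitwise, because reflection negates the lateral component of an
i.i.d. noise stream.

Range statistics under noise carry a small positive bias (the extrema of
signal-plus-noise exceed the signal extrema), which is slightly larger for
smaller amplitudes; recovered ROM path differences are therefore attenuated
by ~0.1° at the 3.2 mm noise level.

## Numerical choices

* Butterworth order 4, applied forward–backward (`sosfiltfilt`); cut-offs:
  high-pass 0.7f for events, low-pass 2f for stance labelling.
* Newton solves for the chain use a linearised initial gain, numerical
  derivatives, and iterate to 1e-11°; angle/oracle agreement is asserted to
  1e-9°.
* Frames are 0-based internally with half-open stride intervals; reports are
  1-based where human-facing.
* Degenerate inputs: constant vertical signal, too-short trials (< 3 s),
  cut-offs at or above Nyquist, coincident markers and zero-length chords
  raise informative errors or NaN-flag the affected frames; near-zero speed
  flags tracking as undefined rather than producing wild angles.
* LS means and contrasts are computed from the fitted fixed-effect
  covariance with design rows built by patsy at speed grand mean; the
  contrast identity (s−l) − (s−r) = −(r−l) is asserted on every fit.

## Problem sizes used in the shipped checks

The bundled tests run a full-design forward-model recovery (12 × 2 × 5 × 3,
~10,700 strides) once, a reduced study (4 horses × 1 day × 2 trials) for
pipeline tests, and a 100-replicate null calibration at the stride-table
level — the calibration concerns the statistics layer, whose generative
structure (horse and measurement intercepts plus stride noise) the table
simulator reproduces directly without the marker-level forward model. These
sizes were chosen to exercise the full design where the claim depends on it
and smaller designs elsewhere.

## Known limitations

* The association models inherit the instability the published analysis
  reports: predictors other than pelvis yaw have small, collinear effects.
* p-values are normal-approximation; with 12 horses, horse-level effects
  have few degrees of freedom (though they cancel in path contrasts).
* The C3D dialect requires the optional `ezc3d` dependency; the TSV dialect
  is the tested interchange format.
* Speed on circles is underestimated by ~1% by the smoothed chord estimator;
  it is used as a covariate, where this bias is immaterial.
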
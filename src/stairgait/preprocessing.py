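"""Sensor-to-body-frame alignment and shared filtering utilities.

The body frame is defined by aligning the mean accelerometer reading of
static periods with the gravity direction, so that during quiet standing the
si axis measures ~1 g and ml/pa ~0 g.  Left-foot data are mirrored onto the
shared convention by negating the ml axis of both sensors, which makes the
terminal-contact dip of gyr_ml negative on both feet.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .types import (
    ML,
    DegenerateInputError,
    EmptyInputError,
    GravityAlignment,
    ImuSequence,
    StaticWindowSet,
)

GRAVITY_TARGET = np.array([0.0, 0.0, 1.0])


def detect_static_windows(
    seq: ImuSequence,
    min_duration_s: float = 1.0,
    gyr_threshold_dps: float = 2.5,
) -> StaticWindowSet:
    """Find maximal windows where the gyroscope norm stays below threshold.

    Windows shorter than ``min_duration_s`` are discarded.  Returned intervals
    are half-open, disjoint and ordered.
    """
    if len(seq) == 0:
        raise EmptyInputError("cannot detect static windows in an empty sequence")
    quiet = np.linalg.norm(seq.gyr, axis=1) < gyr_threshold_dps
    min_len = int(np.ceil(min_duration_s * seq.sampling_rate))
    windows = [(s, e) for s, e in _bool_runs(quiet) if e - s >= min_len]
    return StaticWindowSet(windows, min_duration_s, gyr_threshold_dps)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def estimate_gravity_rotation(static_acc_samples: np.ndarray) -> GravityAlignment:
    """Rotation vector aligning the mean static acceleration with (0, 0, 1).

    The rotation axis is the cross product of the normalized mean vector and
    the gravity target, the angle their arccos.  Degenerate cases: an already
    aligned vector yields the identity; an anti-parallel vector rotates by pi
    around (1, 0, 0).
    """
    samples = np.atleast_2d(np.asarray(static_acc_samples, dtype=float))
    if samples.size == 0:
        raise EmptyInputError("need at least one static acceleration sample")
    mean_acc = samples.mean(axis=0)
    norm = np.linalg.norm(mean_acc)
    if norm < 1e-12:
        raise DegenerateInputError("mean static acceleration has zero norm")
    unit = mean_acc / norm
    cosang = float(np.clip(unit @ GRAVITY_TARGET, -1.0, 1.0))
    angle = float(np.arccos(cosang))
    axis = np.cross(unit, GRAVITY_TARGET)
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-12:
        # parallel or anti-parallel: any axis perpendicular to gravity works
        axis = np.array([1.0, 0.0, 0.0])
        angle = 0.0 if cosang > 0 else float(np.pi)
    else:
        axis = axis / axis_norm
    return GravityAlignment(mean_static_acc=mean_acc, axis=axis, angle=angle)


def alignment_from_sequence(
    seq: ImuSequence,
    min_duration_s: float = 1.0,
    gyr_threshold_dps: float = 2.5,
    guard_s: float = 0.025,
) -> GravityAlignment:
    """Estimate the gravity alignment by pooling all static windows of a recording.

    A small guard margin is trimmed from both ends of each window: at motion
    onset the accelerometer reacts one sample before the gyroscope threshold
    releases, so the outermost samples of a quiet window may not be static.
    """
    windows = detect_static_windows(seq, min_duration_s, gyr_threshold_dps)
    if not windows.windows:
        raise DegenerateInputError("no static window found for gravity alignment")
    guard = int(round(guard_s * seq.sampling_rate))
    chunks = []
    for s, e in windows.windows:
        lo, hi = s + guard, e - guard
        if hi - lo < 2:
            lo, hi = s, e
        chunks.append(seq.acc[lo:hi])
    return estimate_gravity_rotation(np.vstack(chunks))


def align_to_body_frame(
    seq: ImuSequence, alignment: GravityAlignment, foot: str | None = None
) -> ImuSequence:
    """Rotate a sensor-frame sequence into the shared (ml, pa, si) body frame.

    Left-foot data are additionally mirrored (ml axis of acc and gyr negated)
    so both feet share the same sign convention.
    """
    if seq.frame == "body":
        raise ValueError("sequence is already in the body frame (idempotency violation)")
    foot = foot if foot is not None else seq.foot
    rot = Rotation.from_rotvec(alignment.rotation_vector)
    acc = rot.apply(seq.acc)
    gyr = rot.apply(seq.gyr)
    if foot == "left":
        acc[:, ML] = -acc[:, ML]
        gyr[:, ML] = -gyr[:, ML]
    return ImuSequence(acc=acc, gyr=gyr, sampling_rate=seq.sampling_rate, frame="body", foot=foot)


def lowpass(
    x: np.ndarray,
    cutoff_hz: float,
    fs: float,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth low-pass filter of a 1-D series.

    ``zero_phase=True`` applies forward-backward filtering (no group delay),
    which keeps filtered extrema aligned with the raw signal.
    """
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {nyq} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)
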
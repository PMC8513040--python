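"""ZUPT detection, error-state Kalman trajectory reconstruction, spatial features.

The foot trajectory is reconstructed by open-loop strapdown integration of
the body-frame IMU data, while a 9-dimensional error state (position,
velocity and small-angle attitude errors) is tracked by a Kalman filter.
Zero-velocity measurements are applied whenever the ZUPT mask is set; the
error state is never fed back during the forward pass.  A Rauch-Tung-Striebel
backward pass smooths the error-state sequence, which is then applied once
to correct the nominal trajectory without discontinuities.

A walking sequence is split into subsequences at accelerometer-quiet
orientation-update windows; each subsequence restarts the attitude from the
gravity direction (yaw unobservable and set to zero; only relative spatial
parameters are derived) and zero velocity, with position carried over so the
stitched trajectory is continuous.  No level-ground (zero-height) assumption
is made anywhere, which is what permits stair ambulation.

Spatial stride parameters are position differences between consecutive
mid-stance events: height (up positive), horizontal length, and the
inclination angle arctan(height / length).

Units: g and dps at the interface, SI internally; gravity = 9.81 m/s^2.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .types import (
    GaitEventSet,
    ImuSequence,
    OrientationUpdateWindow,
    SpatialStrideParams,
    TrajectoryEstimate,
    ZuptMask,
)

G0 = 9.81

ZUPT_WINDOW_S = 0.150
ZUPT_ACC_THRESHOLD_G = 0.1
ZUPT_GYR_THRESHOLD_DPS = 10.0
ZUPT_MS_WINDOW_S = 0.050

ORIENT_WINDOW_S = 0.300
ORIENT_VAR_THRESHOLD_G2 = 0.015

#: process/measurement noise defaults (the source work does not state values;
#: these are conventional foot-mounted MEMS figures, all configurable)
GYRO_NOISE_DENSITY_DPS = 0.02  # dps / sqrt(Hz)
ACC_NOISE_DENSITY_G = 0.002  # g / sqrt(Hz)
ZUPT_MEAS_SD_MS = 0.01  # m/s


def _cover_windows(passing_starts: np.ndarray, w: int, n: int) -> np.ndarray:
    """Union of windows [s, s+w) for every passing start, as a boolean mask."""
    mask = np.zeros(n + 1, dtype=int)
    np.add.at(mask, passing_starts, 1)
    np.add.at(mask, passing_starts + w, -1)
    return np.cumsum(mask)[:n] > 0


def detect_zupt(
    seq: ImuSequence,
    events: GaitEventSet | None = None,
    window_s: float = ZUPT_WINDOW_S,
    acc_threshold_g: float = ZUPT_ACC_THRESHOLD_G,
    gyr_threshold_dps: float = ZUPT_GYR_THRESHOLD_DPS,
    ms_window_s: float = ZUPT_MS_WINDOW_S,
) -> ZuptMask:
    """Combined zero-velocity mask: acceleration-magnitude OR gyroscope-energy
    OR enforced mid-stance windows.

    The acc detector marks every sample of each sliding window in which the
    deviation of the acceleration norm from 1 g stays below threshold; the
    gyr detector does the same for the windowed RMS angular rate; the MS
    component is a 50 ms window centred on each detected mid-stance event.
    """
    n = len(seq)
    w = max(int(round(window_s * seq.sampling_rate)), 1)
    acc_mask = np.zeros(n, dtype=bool)
    gyr_mask = np.zeros(n, dtype=bool)
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        dev = np.abs(np.linalg.norm(seq.acc, axis=1) - 1.0)
        win_max = sliding_window_view(dev, w).max(axis=1)
        acc_mask = _cover_windows(np.flatnonzero(win_max < acc_threshold_g), w, n)
        gyr_sq = (seq.gyr**2).sum(axis=1)
        csum = np.concatenate(([0.0], np.cumsum(gyr_sq)))
        rms = np.sqrt((csum[w:] - csum[:-w]) / w)
        gyr_mask = _cover_windows(np.flatnonzero(rms < gyr_threshold_dps), w, n)
    ms_mask = np.zeros(n, dtype=bool)
    half = int(round(ms_window_s / 2 * seq.sampling_rate))
    if events is not None:
        for ms in events.ms_indices():
            ms_mask[max(ms - half, 0) : min(ms + half + 1, n)] = True
    return ZuptMask(acc=acc_mask, gyr=gyr_mask, ms_event=ms_mask)


def find_orientation_windows(
    seq: ImuSequence,
    min_duration_s: float = ORIENT_WINDOW_S,
    var_threshold_g2: float = ORIENT_VAR_THRESHOLD_G2,
) -> list[OrientationUpdateWindow]:
    """Maximal accelerometer-quiet windows suitable for attitude updates.

    All windows of ``min_duration_s`` whose per-axis accelerometer variance
    stays below threshold are merged into maximal windows.  Updates are
    always forced at the start and end of the sequence; if those regions are
    not quiet the update uses best-effort local statistics and a warning is
    emitted.
    """
    n = len(seq)
    w = min(max(int(round(min_duration_s * seq.sampling_rate)), 2), n)
    acc = seq.acc
    csum = np.concatenate((np.zeros((1, 3)), np.cumsum(acc, axis=0)))
    csum2 = np.concatenate((np.zeros((1, 3)), np.cumsum(acc**2, axis=0)))
    mean = (csum[w:] - csum[:-w]) / w
    var = (csum2[w:] - csum2[:-w]) / w - mean**2
    ok = np.flatnonzero((var < var_threshold_g2).all(axis=1))
    windows: list[OrientationUpdateWindow] = []
    if ok.size:
        breaks = np.flatnonzero(np.diff(ok) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [ok.size - 1]))
        for a, b in zip(run_starts, run_ends):
            windows.append(OrientationUpdateWindow(start=int(ok[a]), end=int(ok[b]) + w))
    # an update is always enforced at the beginning and end of the sequence
    for start, end, where in ((0, w, "start"), (n - w, n, "end")):
        quiet = bool((var[min(max(start, 0), var.shape[0] - 1)] < var_threshold_g2).all())
        if not quiet:
            warnings.warn(
                f"sequence {where} is not static; forced orientation update uses "
                "best-effort local statistics"
            )
        windows.append(OrientationUpdateWindow(start=start, end=end, forced=True))
    windows.sort(key=lambda wd: (wd.start, wd.end))
    return windows


def _gravity_attitude(acc_dir: np.ndarray) -> np.ndarray:
    """Rotation matrix (body->world) mapping the measured gravity direction
    onto +z with zero yaw (minimal rotation)."""
    a = acc_dir / np.linalg.norm(acc_dir)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(a, z)
    s = np.linalg.norm(axis)
    c = float(a @ z)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return Rotation.from_rotvec([np.pi, 0.0, 0.0]).as_matrix()
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis / s * angle).as_matrix()


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def _exp_so3(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    if theta < 1e-12:
        return np.eye(3) + _skew(w)
    k = _skew(w / theta)
    return np.eye(3) + np.sin(theta) * k + (1.0 - np.cos(theta)) * (k @ k)


def reconstruct_trajectory(
    seq: ImuSequence,
    zupt: ZuptMask,
    updates: list[OrientationUpdateWindow],
    gyro_noise_density_dps: float = GYRO_NOISE_DENSITY_DPS,
    acc_noise_density_g: float = ACC_NOISE_DENSITY_G,
    zupt_meas_sd_ms: float = ZUPT_MEAS_SD_MS,
    lowpass_hz: float = 10.0,
) -> TrajectoryEstimate:
    """Open-loop strapdown integration + error-state Kalman filter + RTS smoothing.

    The sequence is processed per subsequence between orientation-update
    centres; attitude restarts from gravity (yaw 0) and velocity from zero at
    each boundary, position accumulates across boundaries.
    """
    if not updates:
        raise ValueError("at least one orientation update window is required")
    n = len(seq)
    fs = seq.sampling_rate
    dt = 1.0 / fs
    acc_ms2 = seq.acc * G0
    gyr_rad = np.deg2rad(seq.gyr)
    acc_low = sps.sosfiltfilt(
        sps.butter(4, lowpass_hz, btype="low", fs=fs, output="sos"), seq.acc, axis=0
    )
    zm = zupt.combined

    sigma_g = np.deg2rad(gyro_noise_density_dps) * np.sqrt(fs / 2.0)  # rad/s
    sigma_a = acc_noise_density_g * G0 * np.sqrt(fs / 2.0)  # m/s^2
    q_vel = (sigma_a * dt) ** 2
    q_att = (sigma_g * dt) ** 2
    Q = np.diag([1e-12] * 3 + [q_vel] * 3 + [q_att] * 3)
    R_meas = np.eye(3) * zupt_meas_sd_ms**2
    H = np.zeros((3, 9))
    H[:, 3:6] = np.eye(3)
    P0 = np.diag([1e-8] * 3 + [1e-6] * 3 + [np.deg2rad(0.5) ** 2] * 3)
    g_vec = np.array([0.0, 0.0, G0])

    boundaries = sorted({min(max(wd.centre, 0), n - 1) for wd in updates})
    if boundaries[0] != 0:
        boundaries.insert(0, 0)
    if boundaries[-1] != n - 1:
        boundaries.append(n - 1)

    position = np.zeros((n, 3))
    velocity = np.zeros((n, 3))
    rotmats = np.tile(np.eye(3), (n, 1, 1))
    subsequences: list[tuple[int, int]] = []
    p_carry = np.zeros(3)

    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b <= a:
            continue
        subsequences.append((a, b))
        ln = b - a + 1
        # nominal strapdown
        R = _gravity_attitude(acc_low[a])
        Rs = np.empty((ln, 3, 3))
        p_nom = np.empty((ln, 3))
        v_nom = np.empty((ln, 3))
        Rs[0] = R
        p_nom[0] = p_carry
        v_nom[0] = 0.0
        aw_prev = R @ acc_ms2[a] - g_vec
        for j in range(1, ln):
            k = a + j
            w_mid = 0.5 * (gyr_rad[k - 1] + gyr_rad[k])
            R = R @ _exp_so3(w_mid * dt)
            Rs[j] = R
            aw = R @ acc_ms2[k] - g_vec
            v_nom[j] = v_nom[j - 1] + 0.5 * (aw_prev + aw) * dt
            p_nom[j] = p_nom[j - 1] + 0.5 * (v_nom[j - 1] + v_nom[j]) * dt
            aw_prev = aw

        if not zm[a:b + 1].any():
            warnings.warn(
                f"no ZUPT sample in subsequence [{a}, {b}]; velocity drift is unbounded"
            )

        # error-state filter, open loop
        xs_f = np.zeros((ln, 9))
        Ps_f = np.empty((ln, 9, 9))
        xs_p = np.zeros((ln, 9))
        Ps_p = np.empty((ln, 9, 9))
        Fs = np.empty((ln - 1, 9, 9)) if ln > 1 else np.empty((0, 9, 9))
        Ps_f[0] = P0
        Ps_p[0] = P0
        x = np.zeros(9)
        P = P0.copy()
        for j in range(1, ln):
            k = a + j
            F = np.eye(9)
            F[0:3, 3:6] = np.eye(3) * dt
            F[3:6, 6:9] = -_skew(Rs[j - 1] @ acc_ms2[k - 1]) * dt
            Fs[j - 1] = F
            x = F @ x
            P = F @ P @ F.T + Q
            xs_p[j] = x
            Ps_p[j] = P
            if zm[k]:
                y = -v_nom[j] - H @ x
                S = H @ P @ H.T + R_meas
                K = P @ H.T @ np.linalg.inv(S)
                x = x + K @ y
                P = (np.eye(9) - K @ H) @ P
            xs_f[j] = x
            Ps_f[j] = P

        # RTS backward pass
        xs_s = xs_f.copy()
        for j in range(ln - 2, -1, -1):
            C = Ps_f[j] @ Fs[j].T @ np.linalg.inv(Ps_p[j + 1])
            xs_s[j] = xs_f[j] + C @ (xs_s[j + 1] - xs_p[j + 1])

        # apply the smoothed error state once (true = nominal + error)
        p_corr = p_nom + xs_s[:, 0:3]
        v_corr = v_nom + xs_s[:, 3:6]
        # keep the stitch point continuous
        p_corr = p_corr + (p_carry - p_corr[0])
        for j in range(ln):
            Rs[j] = _exp_so3(xs_s[j, 6:9]) @ Rs[j]
        position[a : b + 1] = p_corr
        velocity[a : b + 1] = v_corr
        rotmats[a : b + 1] = Rs
        p_carry = p_corr[-1]

    quat = Rotation.from_matrix(rotmats).as_quat()
    quat = quat / np.linalg.norm(quat, axis=1, keepdims=True)
    return TrajectoryEstimate(
        position=position,
        velocity=velocity,
        orientation=quat,
        zupt=zm,
        sampling_rate=fs,
        subsequence_bounds=subsequences,
    )


def compute_spatial_params(
    traj: TrajectoryEstimate, events: GaitEventSet
) -> SpatialStrideParams:
    """Spatial stride features between consecutive mid-stance events.

    Row j describes the stride ending at the (j+1)-th detected MS event:
    S_d = p_d(MS_j+1) - p_d(MS_j); height = S_z; length = sqrt(Sx^2 + Sy^2);
    inclination = arctan(height / length) in degrees (+-90 when the length is
    zero with nonzero height, flagged).
    """
    pairs = [
        (i, ev.ms)
        for i, ev in enumerate(events.events)
        if ev.valid and ev.ms is not None
    ]
    if len(pairs) < 2:
        empty = np.zeros((0,))
        return SpatialStrideParams(
            delta=np.zeros((0, 3)), height=empty, length=empty,
            inclination=empty, flagged=np.zeros(0, dtype=bool),
            stride_indices=np.zeros(0, dtype=int),
        )
    idx = np.array([i for i, _ in pairs])
    ms = np.array([m for _, m in pairs])
    delta = traj.position[ms[1:]] - traj.position[ms[:-1]]
    height = delta[:, 2]
    length = np.hypot(delta[:, 0], delta[:, 1])
    inclination = np.degrees(np.arctan2(height, length))
    flagged = (length == 0) & (height != 0)
    return SpatialStrideParams(
        delta=delta,
        height=height,
        length=length,
        inclination=inclination,
        flagged=flagged,
        stride_indices=idx[1:],
    )


def stride_inclination_deg(height_m: float, length_m: float) -> float:
    """Stride inclination arctan(height / length) in degrees."""
    return float(np.degrees(np.arctan2(height_m, length_m)))
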
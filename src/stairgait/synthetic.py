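"""Kinematically consistent synthetic foot-IMU + insole signals with ground truth.

The generator builds a continuous foot trajectory per foot (static stance
dwell, smooth swing with clearance, per-stride forward/vertical displacement
from the stair geometry) and a sagittal foot-pitch profile whose mediolateral
angular velocity reproduces the stride morphology used for annotation: a
negative terminal-contact (TC) dip, a prominent positive swing peak and a
deep initial-contact (IC) dip, with exactly zero net rotation per stride.
The emitted accelerometer/gyroscope samples are the exact specific force and
body rate of that motion at a sensor mounted with a lever arm above the foot
pivot and a tilted mounting rotation.

Two deliberately sample-resolution ingredients make the signals usable by
threshold/argmax detectors the way real signals are:

* a short braking transient is embedded in the forward position track at
  each IC, designed so that trapezoidal re-integration of its second
  difference telescopes exactly back to the position profile;
* a small antisymmetric "weight transfer" wobble in early stance keeps the
  minimum-gyroscope-energy window (the mid-stance event) in late stance.

Ground truth stored per foot: stride borders (= TC dip minima), the events
TC, swing max, forward-acceleration max, IC, MS, stride-type labels, the
continuous sensor trajectory, and the insole ground-contact intervals.

Default noise is conservative (acc 0.01 g, gyr 0.5 dps) so that downstream
tolerances measure the pipeline, not the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .fsr import FsrRecord
from .types import ASCENDING, DESCENDING, LEVEL, ImuSequence

G0 = 9.81  # m/s^2, shared with the trajectory module

#: step (rise, run) in metres of the three stair geometries
STAIRCASES = {"A": (0.175, 0.265), "B": (0.145, 0.35), "C": (0.13, 0.97)}

SPEED_STRIDE_DURATION_S = {"slow": 1.5, "preferred": 1.1, "fast": 0.8}
LEVEL_STRIDE_LENGTH_M = {"slow": 1.0, "preferred": 1.3, "fast": 1.5}

#: sagittal angular-velocity morphology defaults (deg/s)
SWING_PEAK_DPS = 130.0
IC_DIP_DPS = 350.0
MIN_TC_DIP_DPS = 30.0
STANCE_WOBBLE_DPS = 6.0

SWING_RATIO = 0.42
CLEARANCE_M = 0.05
TERMINATION_DIP_DPS = 40.0
#: sensor lever arm from the foot pivot in body coordinates (ml, pa, si), m
SENSOR_OFFSET_M = (0.0, 0.02, 0.10)

DEFAULT_MOUNTING_DEG = {"left": (-6.0, 4.0, 0.0), "right": (8.0, -3.0, 0.0)}

#: mid-stance detector window (s) mirrored here to anchor the MS ground truth
MS_WINDOW_S = 0.2


@dataclass
class NoiseParams:
    """Additive white sensor noise; zero for noise-free signals."""

    acc_sd_g: float = 0.01
    gyr_sd_dps: float = 0.5

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(0.0, 0.0)


@dataclass
class StrideSpec:
    """One stride (one swing) of one foot.

    ``length_m`` and ``rise_m`` are the net forward and vertical displacement
    of the foot over the stride; a steady-state double stair step stride has
    rise = 2 x step rise and length = 2 x step run.
    """

    stride_type: str = LEVEL
    duration_s: float = 1.1
    length_m: float = 1.3
    rise_m: float = 0.0
    speed_tag: str = "preferred"
    foot: str | None = None


def level_spec(speed: str = "preferred", duration_scale: float = 1.0) -> StrideSpec:
    return StrideSpec(
        stride_type=LEVEL,
        duration_s=SPEED_STRIDE_DURATION_S[speed] * duration_scale,
        length_m=LEVEL_STRIDE_LENGTH_M[speed],
        rise_m=0.0,
        speed_tag=speed,
    )


def stair_spec(
    staircase: str,
    direction: str = "up",
    steps_per_stride: int = 2,
    speed: str = "preferred",
    duration_scale: float = 1.0,
) -> StrideSpec:
    """Steady-state (double step) or transition (single step) stair stride."""
    rise, run = STAIRCASES[staircase]
    sign = 1.0 if direction == "up" else -1.0
    return StrideSpec(
        stride_type=ASCENDING if direction == "up" else DESCENDING,
        duration_s=SPEED_STRIDE_DURATION_S[speed] * duration_scale,
        length_m=steps_per_stride * run,
        rise_m=sign * steps_per_stride * rise,
        speed_tag=speed,
    )


@dataclass
class FootTruth:
    """Ground truth of one foot; all indices are original-rate samples."""

    borders: np.ndarray  # (K,) TC dip sample of each swing; K-1 complete strides
    labels: list[str]  # stride-type label per complete stride
    tc: np.ndarray  # per complete stride (== borders[:-1])
    swing_max: np.ndarray
    facc_max: np.ndarray
    ic: np.ndarray
    ms: np.ndarray
    position: np.ndarray  # (n, 3) sensor position, world frame (ml, pa, up), m
    velocity: np.ndarray  # (n, 3) m/s
    pitch_deg: np.ndarray  # (n,) sagittal foot pitch
    contacts: list[tuple[int, int]]  # inclusive ground-contact intervals [IC, TC]

    @property
    def stride_borders(self) -> list[tuple[int, int]]:
        return [
            (int(self.borders[i]), int(self.borders[i + 1]))
            for i in range(len(self.borders) - 1)
        ]

    @property
    def n_strides(self) -> int:
        return max(len(self.borders) - 1, 0)


@dataclass
class FootChannel:
    imu: ImuSequence
    fsr: FsrRecord
    truth: FootTruth


@dataclass
class SyntheticWalk:
    left: FootChannel
    right: FootChannel
    sampling_rate: float
    body_weight_kg: float
    seed: int | None = None
    manifest: dict = field(default_factory=dict)

    def foot(self, side: str) -> FootChannel:
        return self.left if side == "left" else self.right

    @property
    def feet(self) -> dict[str, FootChannel]:
        return {"left": self.left, "right": self.right}


# --- compactly supported bump primitives -----------------------------------

def _bump(v) -> np.ndarray:
    """(1 - v^2)^2 on [-1, 1], zero value and slope at the edges."""
    v = np.clip(np.asarray(v, dtype=float), -1.0, 1.0)
    return (1.0 - v * v) ** 2


def _bump_der(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    out = -4.0 * v * (1.0 - v * v)
    return np.where(np.abs(v) <= 1.0, out, 0.0)


def _bump_der2(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    out = 12.0 * v * v - 4.0
    return np.where(np.abs(v) <= 1.0, out, 0.0)


def _bump_int(v) -> np.ndarray:
    """Antiderivative of _bump from v = -1; reaches 16/15 for v >= 1."""
    v = np.clip(np.asarray(v, dtype=float), -1.0, 1.0)
    return (v - (2.0 / 3.0) * v**3 + 0.2 * v**5) + 8.0 / 15.0


_BUMP_AREA = 16.0 / 15.0
_BUMP_DER_MAX = 16.0 / (5.0 * np.sqrt(5.0))  # max |d/dv (1-v^2)^2|

#: displacement spans 10%..100% of the swing: it starts once the TC dip has
#: made the gyroscope loud (so zero-velocity detectors have released), the
#: forward velocity peaks after the gyroscope swing maximum (so the filtered
#: forward acceleration has its maximum just after it), and braking runs into
#: the initial contact as in real gait
_VEL_CENTRE, _VEL_HALFWIDTH = 0.55, 0.45
#: max |d2s/du2| of the displacement profile
_VEL_ACC_PEAK = (1.0 / (_VEL_HALFWIDTH * _BUMP_AREA)) * (16.0 / (5.0 * np.sqrt(5.0))) / _VEL_HALFWIDTH
_VEL_GAIN = 1.0 / (_VEL_HALFWIDTH * _BUMP_AREA)

_CL_CENTRE, _CL_HALFWIDTH = 0.41, 0.33

#: antisymmetric stance wobble shape, normalized to peak 1
_WOB_NORM = 16.0 / (5.0 * np.sqrt(5.0))


def _smooth_step(u):
    """Normalized swing displacement s(u): s(0)=0, s(u>=0.8)=1.

    Returns (s, ds/du, d2s/du2)."""
    v = (np.asarray(u, dtype=float) - _VEL_CENTRE) / _VEL_HALFWIDTH
    s = _VEL_GAIN * _VEL_HALFWIDTH * _bump_int(v)
    s1 = _VEL_GAIN * _bump(v)
    s2 = _VEL_GAIN * _bump_der(v) / _VEL_HALFWIDTH
    return s, s1, s2


#: IC impact acceleration kernel: a sharp central spike with shallow symmetric
#: negative flanks (zero sum and zero first moment, so velocity and position
#: both return to zero after the transient)
_IMPACT_KERNEL = np.array([-0.125] * 4 + [1.0] + [-0.125] * 4)
_IMPACT_HALFWIDTH = (len(_IMPACT_KERNEL) - 1) // 2


def _impact_position_bump(a_peak: float, dt: float) -> np.ndarray:
    """Discrete position transient whose second difference is the impact kernel.

    Built as the double cumulative sum of the kernel so that trapezoidal
    re-integration of the emitted acceleration telescopes exactly back to it.
    """
    return a_peak * dt * dt * np.cumsum(np.cumsum(_IMPACT_KERNEL))


# --- swing planning ---------------------------------------------------------

@dataclass
class _Swing:
    n0: int  # first sample of the swing
    m: int  # swing length in samples; IC falls on n0 + m
    spec: StrideSpec
    c1: int = 0  # TC dip centre (samples into swing)
    h1: int = 0
    c2: int = 0  # swing peak centre
    h2: int = 0
    c3: int = 0  # IC dip centre
    h3: int = 0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0

    @property
    def ic(self) -> int:
        return self.n0 + self.m

    @property
    def tc(self) -> int:
        return self.n0 + self.c1


def _plan_swing(n0: int, m: int, spec: StrideSpec, swing_peak_dps: float) -> _Swing:
    """Lay out the three pitch-rate lobes of one swing on the sample grid.

    The swing lobe overlaps both dips so the gyroscope is active throughout
    the swing (zero-velocity detectors must not fire mid-swing); the dip
    amplitudes are scaled so the net rotation per stride is exactly zero.
    """
    h1 = max(int(round(0.07 * m)), 3)
    h2 = max(int(round(0.40 * m)), 8)
    h3 = max(int(round(0.08 * m)), 3)
    c1 = h1  # TC dip support starts exactly at the swing onset
    c2 = int(round(0.47 * m))
    c3 = m - h3  # IC dip support ends exactly at IC
    a2 = swing_peak_dps
    # zero net rotation: a1*h1 + a3*h3 = a2*h2, keeping the IC dip twice as
    # deep as the TC dip as in real mediolateral foot angular velocity
    scale = a2 * h2 / (200.0 * h1 + 400.0 * h3)
    a1 = 200.0 * scale
    a3 = 400.0 * scale
    return _Swing(n0, m, spec, c1, h1, c2, h2, c3, h3, a1, a2, a3)


def _foot_kinematics(
    swings: list[_Swing],
    n_total: int,
    fs: float,
    clearance_m: float,
    wobble_dps: float,
):
    """Analytic world-frame kinematics of the foot pivot plus pitch profile.

    World axes are (x=ml, y=pa forward, z=up).  Returns the pivot position
    (m), pitch angle (deg), pitch rate (dps) and the per-swing stance-wobble
    end sample.
    """
    dt = 1.0 / fs
    pos = np.zeros((n_total, 3))
    omega = np.zeros(n_total)

    base = np.zeros(3)
    cursor = 0
    wobble_ends: list[int] = []
    for k, sw in enumerate(swings):
        n0, m, spec = sw.n0, sw.m, sw.spec
        pos[cursor:n0] = base  # stance dwell before this swing
        idx = np.arange(n0, min(n0 + m + 1, n_total))
        u = (idx - n0) / m
        s, _, _ = _smooth_step(u)
        dy, dz = spec.length_m, spec.rise_m
        pos[idx, 1] = base[1] + dy * s
        pos[idx, 2] = base[2] + dz * s
        vcl = (u - _CL_CENTRE) / _CL_HALFWIDTH
        pos[idx, 2] += clearance_m * _bump(vcl)
        base = base + np.array([0.0, dy, dz])
        cursor = n0 + m

        # sagittal pitch rate: -TC dip, +swing peak, -IC dip (deg/s); the IC
        # dip amplitude is balanced against the sampled lobe sums so the
        # discretely integrated pitch returns to exactly zero after the swing
        b1 = _bump((idx - n0 - sw.c1) / sw.h1)
        b2 = _bump((idx - n0 - sw.c2) / sw.h2)
        b3 = _bump((idx - n0 - sw.c3) / sw.h3)
        a3 = (sw.a2 * b2.sum() - sw.a1 * b1.sum()) / b3.sum()
        omega[idx] += -sw.a1 * b1 + sw.a2 * b2 - a3 * b3

        # early-stance weight-transfer wobble (zero net rotation)
        ic = sw.ic
        next_n0 = swings[k + 1].n0 if k + 1 < len(swings) else None
        stance = (
            (next_n0 - ic)
            if next_n0 is not None
            else int(round(spec.duration_s * fs)) - m
        )
        hw = max(int(round(0.24 * stance)), 5)
        w0 = ic + 3
        widx = np.arange(w0, min(w0 + 2 * hw + 1, n_total))
        vw = (widx - w0 - hw) / hw
        omega[widx] += wobble_dps * (-4.0 * vw * (1.0 - vw * vw) ** 2) / _WOB_NORM
        wobble_ends.append(w0 + 2 * hw)

    pos[cursor:] = base

    # gait termination: a small negative-first foot adjustment one stride
    # duration after the last TC closes the final stride with a snappable
    # gyr_ml minimum (net rotation zero)
    termination = None
    if swings:
        sw = swings[-1]
        n_term = sw.n0 + int(round(sw.spec.duration_s * fs)) + sw.c1
        h_t = max(int(round(0.10 * sw.m)), 4)
        tidx = np.arange(max(n_term - h_t, 0), min(n_term + h_t + 1, n_total))
        vt = (tidx - n_term) / h_t
        omega[tidx] += TERMINATION_DIP_DPS * (4.0 * vt * (1.0 - vt * vt) ** 2) / _WOB_NORM
        termination = (n_term, h_t)

    # ground-truth pitch = midpoint-rule integral of the emitted rate, so the
    # discrete orientation is exactly consistent with the gyroscope samples
    theta = np.concatenate(([0.0], np.cumsum(0.5 * (omega[:-1] + omega[1:]) * dt)))
    return pos, theta, omega, wobble_ends, termination


def _generate_foot(
    swings: list[_Swing],
    n_total: int,
    fs: float,
    foot: str,
    clearance_m: float,
    wobble_dps: float,
    sensor_offset: tuple[float, float, float],
    mounting_deg: tuple[float, float, float],
    noise: NoiseParams,
    body_weight_kg: float,
    rng: np.random.Generator,
) -> FootChannel:
    dt = 1.0 / fs
    pos, theta, omega, wobble_ends, termination = _foot_kinematics(
        swings, n_total, fs, clearance_m, wobble_dps
    )

    # IC braking transient on the forward axis, at sample resolution
    h = _IMPACT_HALFWIDTH
    for sw in swings:
        ic = sw.ic
        if ic + h + 2 >= n_total:
            continue
        alpha3_peak = np.deg2rad(sw.a3 * _BUMP_DER_MAX / (sw.h3 * dt))  # rad/s^2
        t_sw = sw.m * dt
        braking_peak = _VEL_ACC_PEAK * sw.spec.length_m / (t_sw * t_sw)
        a_imp = max(5.0 * G0, 1.5 * braking_peak, 2.2 * sensor_offset[2] * alpha3_peak)
        # the kernel's spike sits 3 samples into the 9-sample support
        pos[ic - h + 1 : ic + h + 2, 1] += _impact_position_bump(a_imp, dt)

    # sensor lever arm: p_sensor = p_foot + R(theta) r
    r_pa, r_si = sensor_offset[1], sensor_offset[2]
    th = np.deg2rad(theta)
    sin, cos = np.sin(th), np.cos(th)
    pos_s = pos.copy()
    pos_s[:, 1] += r_pa * cos - r_si * sin
    pos_s[:, 2] += r_pa * sin + r_si * cos

    # world acceleration as the exact discrete second difference of the
    # ground-truth sensor position, so that trapezoidal re-integration of the
    # emitted signals telescopes back to the trajectory; velocity truth is the
    # matching central difference (the sequence starts and ends static)
    acc_s = np.zeros_like(pos_s)
    acc_s[1:-1] = (pos_s[2:] - 2.0 * pos_s[1:-1] + pos_s[:-2]) / (dt * dt)
    vel_s = np.zeros_like(pos_s)
    vel_s[1:-1] = (pos_s[2:] - pos_s[:-2]) / (2.0 * dt)

    # body-frame specific force (g) and rates (dps)
    f_world = acc_s + np.array([0.0, 0.0, G0])
    rot_wb = Rotation.from_euler("x", theta[:, None], degrees=True)
    acc_body = rot_wb.inv().apply(f_world) / G0
    gyr_body = np.column_stack([omega, np.zeros(n_total), np.zeros(n_total)])

    truth = _build_truth(swings, wobble_ends, termination, acc_body, omega, pos_s, vel_s, theta, fs)

    # left feet are emitted in the mirrored ml-axis convention
    emit_acc, emit_gyr = acc_body.copy(), gyr_body.copy()
    if foot == "left":
        emit_acc[:, 0] = -emit_acc[:, 0]
        emit_gyr[:, 0] = -emit_gyr[:, 0]
    rot_m = Rotation.from_rotvec(np.deg2rad(np.asarray(mounting_deg, dtype=float)))
    emit_acc = rot_m.inv().apply(emit_acc)
    emit_gyr = rot_m.inv().apply(emit_gyr)
    if noise.acc_sd_g > 0:
        emit_acc = emit_acc + rng.normal(0.0, noise.acc_sd_g, emit_acc.shape)
    if noise.gyr_sd_dps > 0:
        emit_gyr = emit_gyr + rng.normal(0.0, noise.gyr_sd_dps, emit_gyr.shape)

    imu = ImuSequence(acc=emit_acc, gyr=emit_gyr, sampling_rate=fs, frame="sensor", foot=foot)
    fsr = _fsr_from_contacts(truth.contacts, n_total, fs, body_weight_kg)
    return FootChannel(imu=imu, fsr=fsr, truth=truth)


def _build_truth(
    swings: list[_Swing],
    wobble_ends: list[int],
    termination: tuple[int, int] | None,
    acc_body: np.ndarray,
    omega: np.ndarray,
    pos_s: np.ndarray,
    vel_s: np.ndarray,
    theta: np.ndarray,
    fs: float,
) -> FootTruth:
    n_total = pos_s.shape[0]
    # the pitch-rate lobes overlap, so anchor TC (minimum of the first half of
    # the swing) and the swing maximum on the sampled profile itself
    border_list = [
        sw.n0 + int(np.argmin(omega[sw.n0 : sw.n0 + max(sw.m // 2, 2)])) for sw in swings
    ]
    if termination is not None:
        n_term, h_t = termination
        lo = max(n_term - h_t, 0)
        border_list.append(lo + int(np.argmin(omega[lo : n_term + 1])))
    borders = np.array(border_list, dtype=int)
    n_strides = max(len(borders) - 1, 0)
    w_ms = int(round(MS_WINDOW_S * fs))
    tc = borders[:n_strides]
    swing_max = np.array(
        [swings[i].n0 + int(np.argmax(omega[swings[i].n0 : swings[i].ic])) for i in range(n_strides)],
        dtype=int,
    )
    ic = np.array([swings[i].ic for i in range(n_strides)], dtype=int)
    ms = np.array([min(wobble_ends[i] + w_ms // 2, n_total - 1) for i in range(n_strides)], dtype=int)
    # forward-acceleration maximum is detector-relative by definition: locate
    # it on the 5 Hz low-passed noise-free forward acceleration
    facc = np.zeros(n_strides, dtype=int)
    if n_strides:
        sos = sps.butter(5, 5.0, btype="low", fs=fs, output="sos")
        pa_low = sps.sosfiltfilt(sos, acc_body[:, 1])
        for i in range(n_strides):
            lo, hi = swing_max[i] + 1, ms[i]
            facc[i] = lo + int(np.argmax(pa_low[lo:hi]))
    labels = [swings[i].spec.stride_type for i in range(n_strides)]
    contacts: list[tuple[int, int]] = []
    if swings:
        contacts.append((0, int(borders[0])))
        for i in range(len(swings) - 1):
            contacts.append((int(swings[i].ic), int(borders[i + 1])))
        contacts.append((int(swings[-1].ic), n_total - 1))
    else:
        contacts.append((0, n_total - 1))
    return FootTruth(
        borders=borders,
        labels=labels,
        tc=tc,
        swing_max=swing_max,
        facc_max=facc,
        ic=ic,
        ms=ms,
        position=pos_s,
        velocity=vel_s,
        pitch_deg=theta,
        contacts=contacts,
    )


_FSR_RAMP_SAMPLES = 6
_FSR_CHANNEL_WEIGHTS = np.array([0.21, 0.32, 0.42])  # toe, MTH, heel; sum 0.95
_FSR_BASELINE_KG = 0.3  # lacing offset per channel


def _fsr_from_contacts(
    contacts: list[tuple[int, int]], n_total: int, fs: float, body_weight_kg: float
) -> FsrRecord:
    env = np.zeros(n_total)
    r = _FSR_RAMP_SAMPLES
    for a, b in contacts:
        n = np.arange(a, b + 1)
        env[a : b + 1] = np.minimum(1.0, np.minimum((n - a + 1) / r, (b - n + 1) / r))
    loads = env[:, None] * _FSR_CHANNEL_WEIGHTS[None, :] * body_weight_kg + _FSR_BASELINE_KG
    return FsrRecord(loads=loads, sampling_rate=fs, body_weight_kg=body_weight_kg)


# --- public entry points ----------------------------------------------------

def generate_walk(
    specs: list[StrideSpec],
    noise: NoiseParams | None = None,
    fs: float = 204.8,
    seed: int | None = None,
    lead_in_s: float = 2.5,
    lead_out_s: float = 2.5,
    swing_ratio: float = SWING_RATIO,
    clearance_m: float = CLEARANCE_M,
    swing_peak_dps: float = SWING_PEAK_DPS,
    wobble_dps: float = STANCE_WOBBLE_DPS,
    sensor_offset: tuple[float, float, float] = SENSOR_OFFSET_M,
    mounting_deg: dict[str, tuple[float, float, float]] | None = None,
    body_weight_kg: float = 70.0,
) -> SyntheticWalk:
    """Synthesize one continuous two-foot walk from a list of stride specs.

    Specs alternate feet starting with the left foot; a spec with an explicit
    ``foot`` must respect the alternation.  Each spec describes one swing; a
    foot with K swings yields K-1 complete (border-to-border) strides.
    """
    noise = noise if noise is not None else NoiseParams()
    mounting = mounting_deg if mounting_deg is not None else DEFAULT_MOUNTING_DEG
    rng = np.random.default_rng(seed)

    feet_order = ["left", "right"]
    starts: list[int] = []
    n = int(round(lead_in_s * fs))
    for i, spec in enumerate(specs):
        expected = feet_order[i % 2]
        if spec.foot is not None and spec.foot != expected:
            raise ValueError(
                f"stride specs must alternate feet starting left; spec {i} says "
                f"{spec.foot!r}, expected {expected!r}"
            )
        starts.append(n)
        n += int(round(spec.duration_s / 2.0 * fs))
    swing_lengths = [int(round(spec.duration_s * swing_ratio * fs)) for spec in specs]
    # leave room for the termination adjustment one stride after the last TC
    end_of_motion = max(
        (
            starts[i]
            + int(round(specs[i].duration_s * fs))
            + max(int(round(0.10 * swing_lengths[i])), 4)
            + 1
            for i in range(len(specs))
        ),
        default=int(round(lead_in_s * fs)),
    )
    n_total = end_of_motion + int(round(lead_out_s * fs))

    channels: dict[str, FootChannel] = {}
    for fi, foot in enumerate(feet_order):
        swings = [
            _plan_swing(starts[i], swing_lengths[i], specs[i], swing_peak_dps)
            for i in range(len(specs))
            if i % 2 == fi
        ]
        channels[foot] = _generate_foot(
            swings,
            n_total,
            fs,
            foot,
            clearance_m,
            wobble_dps,
            sensor_offset,
            mounting[foot],
            noise,
            body_weight_kg,
            rng,
        )
    return SyntheticWalk(
        left=channels["left"],
        right=channels["right"],
        sampling_rate=fs,
        body_weight_kg=body_weight_kg,
        seed=seed,
    )


def _task_specs(task: dict, n_stair: int, n_level: int) -> list[StrideSpec]:
    if task["kind"] == "stair":
        return (
            [level_spec(task["speed"])] * n_level
            + [stair_spec(task["staircase"], task["direction"], 2, task["speed"])] * n_stair
            + [level_spec(task["speed"])] * n_level
        )
    # combined: continuous walk passing the staircase up and down at preferred speed
    return (
        [level_spec("preferred")] * 6
        + [stair_spec(task["staircase"], "up", 2, "preferred")] * n_stair
        + [level_spec("preferred")] * 4
        + [stair_spec(task["staircase"], "down", 2, "preferred")] * n_stair
        + [level_spec("preferred")] * 6
    )


def generate_evaluation_set(
    n_participants: int = 1,
    staircases: tuple[str, ...] = ("A", "B", "C"),
    speeds: tuple[str, ...] = ("slow", "preferred", "fast"),
    seed: int | None = None,
    noise: NoiseParams | None = None,
    n_stair_strides: int = 8,
    n_level_strides: int = 4,
    fs: float = 204.8,
) -> list[tuple[dict, SyntheticWalk]]:
    """Per synthetic participant, the full task grid with kinematic variation.

    Tasks: each staircase x {up, down} x speed, plus one combined walk per
    staircase at preferred speed (21 tasks with the default grids).
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    sseq = np.random.SeedSequence(seed)
    out: list[tuple[dict, SyntheticWalk]] = []
    for p in range(n_participants):
        pseq = sseq.spawn(1)[0]
        prng = np.random.default_rng(pseq)
        duration_scale = float(np.clip(prng.normal(1.0, 0.04), 0.9, 1.1))
        clearance = float(np.clip(prng.normal(CLEARANCE_M, 0.006), 0.03, 0.08))
        swing_peak = float(np.clip(prng.normal(SWING_PEAK_DPS, 8.0), 100.0, 170.0))
        tasks = [
            {"kind": "stair", "staircase": sc, "direction": d, "speed": sp}
            for sc in staircases
            for d in ("up", "down")
            for sp in speeds
        ] + [{"kind": "combined", "staircase": sc, "speed": "preferred"} for sc in staircases]
        for t, task in enumerate(tasks):
            specs = _task_specs(task, n_stair_strides, n_level_strides)
            specs = [
                StrideSpec(
                    stride_type=s.stride_type,
                    duration_s=s.duration_s * duration_scale,
                    length_m=s.length_m,
                    rise_m=s.rise_m,
                    speed_tag=s.speed_tag,
                )
                for s in specs
            ]
            walk_seed = int(pseq.spawn(1)[0].generate_state(1)[0] % (2**31))
            walk = generate_walk(
                specs,
                noise=noise,
                fs=fs,
                seed=walk_seed,
                clearance_m=clearance,
                swing_peak_dps=swing_peak,
            )
            manifest = dict(task, participant=p, task_index=t, n_specs=len(specs), seed=walk_seed)
            walk.manifest = manifest
            out.append((manifest, walk))
    return out
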
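"""Gait-event detection within segmented strides and temporal parameters.

A strict event sequence is assumed per stride: the terminal contact (TC, the
gyr_ml minimum at the stride border), the swing maximum (first prominent
peak of the low-passed gyr_ml), the forward-acceleration maximum, the
initial contact (IC, impact peak of the squared forward acceleration with a
derivative-based fallback), and the mid-stance (MS, centre of the minimum
3D gyroscope-energy window).  Events are detected in the fixed order
TC -> swing max -> MS -> forward-acc max -> IC because the forward
acceleration is searched before the MS event.

Temporal parameters follow directly from the events:
stride(i) = t(IC_i) - t(IC_{i-1}); swing(i) = t(IC_i) - t(TC_i);
stance(i) = t(TC_i) - t(IC_{i-1}); hence swing + stance = stride exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import (
    GaitEventSet,
    ImuSequence,
    StrideBorderSet,
    StrideEvents,
    TemporalParams,
)

TC_FILTER_HZ, TC_FILTER_ORDER = 10.0, 5
SWING_FILTER_HZ, SWING_FILTER_ORDER = 5.0, 5
TC_HALF_WINDOW_S = 0.150
MS_WINDOW_S = 0.200
IC_SEARCH_FRACTION = 0.6
IC_MIN_PEAK_G2 = 4.0
SWING_PROMINENCE_DPS = 20.0

SWING_BOUNDS_S = (0.2, 1.0)
STANCE_BOUNDS_S = (0.2, 1.5)
SWING_RATIO_BOUNDS = (0.25, 0.60)


def _zero_phase(x: np.ndarray, cutoff: float, order: int, fs: float) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def refine_tc(seq: ImuSequence, border: int, half_window_s: float = TC_HALF_WINDOW_S) -> int:
    """Minimum of the 10 Hz zero-phase filtered gyr_ml within +-150 ms of a border."""
    filt = _zero_phase(seq.gyr_ml, TC_FILTER_HZ, TC_FILTER_ORDER, seq.sampling_rate)
    return _argmin_window(filt, border, half_window_s, seq.sampling_rate)


def _argmin_window(x: np.ndarray, centre: int, half_window_s: float, fs: float) -> int:
    half = int(round(half_window_s * fs))
    lo = max(centre - half, 0)
    hi = min(centre + half + 1, len(x))
    return lo + int(np.argmin(x[lo:hi]))


def detect_swing_max(gyr_ml_low: np.ndarray, tc: int, tc_next: int) -> int | None:
    """First peak with prominence >= 20 dps in the filtered gyr_ml, inside (tc, tc_next)."""
    seg = gyr_ml_low[tc + 1 : tc_next]
    peaks, _ = sps.find_peaks(seg, prominence=SWING_PROMINENCE_DPS)
    if peaks.size == 0:
        return None
    return tc + 1 + int(peaks[0])


def detect_ms(
    gyr: np.ndarray,
    search_start: int,
    tc_next: int,
    fs: float,
    window_s: float = MS_WINDOW_S,
) -> tuple[int, bool]:
    """Centre of the minimum total 3D gyroscope-energy window.

    Windows of length ``window_s`` slide sample-by-sample over
    [search_start, tc_next); ties resolve to the earliest window.  If the
    interval is shorter than one window the interval centre is returned with
    a flag.
    """
    w = int(round(window_s * fs))
    lo, hi = search_start, tc_next
    if hi - lo < w:
        return (lo + hi) // 2, True
    energy = (np.asarray(gyr[lo:hi]) ** 2).sum(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(energy)))
    window_sums = csum[w:] - csum[:-w]  # sum over [s, s+w) for s = 0..len-w
    s = int(np.argmin(window_sums))
    return lo + s + w // 2, False


def detect_facc_max(acc_pa_low: np.ndarray, swing_max: int, ms: int) -> int | None:
    """Maximum of the 5 Hz filtered forward acceleration in (swing_max, ms)."""
    if ms - swing_max < 2:
        return None
    seg = acc_pa_low[swing_max + 1 : ms]
    return swing_max + 1 + int(np.argmax(seg))


def detect_ic(
    acc_pa: np.ndarray,
    acc_pa_low: np.ndarray,
    facc_max: int,
    ms: int,
    fs: float,
    fraction: float = IC_SEARCH_FRACTION,
    min_peak_g2: float = IC_MIN_PEAK_G2,
) -> int | None:
    """Impact peak of the squared forward acceleration in the IC search region.

    The region is the first 60% of (facc_max, ms).  If the squared-signal
    maximum stays below 4 g^2 (no clear impact), the maximum of the central
    first difference of the filtered signal is used instead.
    """
    if ms <= facc_max + 1:
        return None
    span = ms - facc_max
    hi = facc_max + max(int(np.floor(fraction * span)), 2)
    lo = facc_max + 1
    if hi <= lo:
        return None
    seg_sq = np.asarray(acc_pa[lo:hi]) ** 2
    peak = int(np.argmax(seg_sq))
    if seg_sq[peak] >= min_peak_g2:
        return lo + peak
    deriv = np.gradient(acc_pa_low)[lo:hi]
    return lo + int(np.argmax(deriv))


def detect_events(seq: ImuSequence, borders: StrideBorderSet) -> GaitEventSet:
    """Detect all gait events for each segmented stride.

    Stride borders are assumed refined (TC minima); the TC of stride i is its
    start border, re-refined on the 10 Hz filtered signal.  A stride whose
    event sequence cannot be completed in order is flagged invalid.
    """
    fs = seq.sampling_rate
    gyr_ml = seq.gyr_ml
    gyr_ml_low = _zero_phase(gyr_ml, SWING_FILTER_HZ, SWING_FILTER_ORDER, fs)
    acc_pa = seq.acc_pa
    acc_pa_low = _zero_phase(acc_pa, SWING_FILTER_HZ, SWING_FILTER_ORDER, fs)

    events: list[StrideEvents] = []
    for stride in borders.strides:
        tc = refine_tc(seq, stride.start)
        tc_next = stride.end
        ev = StrideEvents(tc=tc)
        swing = detect_swing_max(gyr_ml_low, tc, tc_next)
        if swing is None:
            ev.valid, ev.reason = False, "no prominent swing peak"
            events.append(ev)
            continue
        ev.swing_max = swing
        raw_max = tc + 1 + int(np.argmax(gyr_ml[tc + 1 : tc_next]))
        ms, ms_flagged = detect_ms(seq.gyr, raw_max, tc_next, fs)
        ev.ms = ms
        facc = detect_facc_max(acc_pa_low, swing, ms)
        if facc is None:
            ev.valid, ev.reason = False, "empty forward-acceleration window"
            events.append(ev)
            continue
        ev.facc_max = facc
        ic = detect_ic(acc_pa, acc_pa_low, facc, ms, fs)
        if ic is None:
            ev.valid, ev.reason = False, "empty IC search region"
            events.append(ev)
            continue
        ev.ic = ic
        if ms_flagged:
            ev.reason = "ms interval shorter than window"
        if not (tc < swing < facc < ic < ms < tc_next):
            ev.valid, ev.reason = False, "event ordering violated"
        events.append(ev)
    return GaitEventSet(events=events, sampling_rate=fs)


def compute_temporal_params(events: GaitEventSet) -> TemporalParams:
    """Stride/swing/stance times from consecutive IC and TC events.

    The first stride lacks IC_{i-1}: its stride and stance times are NaN.
    Rational arithmetic on sample indices guarantees swing + stance = stride
    exactly wherever all three are defined.
    """
    fs = events.sampling_rate
    n = len(events)
    stride_t = np.full(n, np.nan)
    swing_t = np.full(n, np.nan)
    stance_t = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, ev in enumerate(events.events):
        if not ev.valid or ev.ic is None:
            continue
        valid[i] = True
        swing_t[i] = (ev.ic - ev.tc) / fs
        prev = events.events[i - 1] if i > 0 else None
        if prev is not None and prev.valid and prev.ic is not None:
            if prev.ic >= ev.ic:
                valid[i] = False
                continue
            stride_t[i] = (ev.ic - prev.ic) / fs
            stance_t[i] = (ev.tc - prev.ic) / fs
    return TemporalParams(stride_time=stride_t, swing_time=swing_t, stance_time=stance_t, valid=valid)


def flag_outliers(params: TemporalParams) -> TemporalParams:
    """Mark biomechanically unrealistic strides invalid.

    Valid strides satisfy swing in [0.2, 1.0] s, stance in [0.2, 1.5] s and a
    swing proportion of 25-60% of the stride time.
    """
    valid = params.valid.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = params.swing_time / params.stride_time
    for i in range(len(params)):
        if not valid[i]:
            continue
        sw, st = params.swing_time[i], params.stance_time[i]
        if not (SWING_BOUNDS_S[0] <= sw <= SWING_BOUNDS_S[1]):
            valid[i] = False
        elif np.isfinite(st) and not (STANCE_BOUNDS_S[0] <= st <= STANCE_BOUNDS_S[1]):
            valid[i] = False
        elif np.isfinite(ratio[i]) and not (
            SWING_RATIO_BOUNDS[0] <= ratio[i] <= SWING_RATIO_BOUNDS[1]
        ):
            valid[i] = False
    return TemporalParams(
        stride_time=params.stride_time,
        swing_time=params.swing_time,
        stance_time=params.stance_time,
        valid=valid,
    )
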
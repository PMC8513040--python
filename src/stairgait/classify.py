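"""Threshold-based stride-type classification, bout assembly and DMOs.

A stride is ascending when both its height and inclination exceed +10 cm and
+6 degrees, descending when both fall below the mirrored thresholds, and
level otherwise; strides with implausible spatial or temporal parameters are
rejected outright.  Classified strides of both feet are then assembled into
walking bouts: a level bout needs at least two consecutive strides per foot
(alternating feet), a stair bout at least five consecutive same-type strides
no farther apart than one maximum stride time.  Stair runs that are too
short are re-labelled as level walking, which keeps the precision of the
stair classes high.  Digital mobility outcomes are per-activity means and
standard deviations (population convention) of the temporal parameters.
"""

from __future__ import annotations

import numpy as np

from .types import (
    ASCENDING,
    DESCENDING,
    LEVEL,
    REJECTED,
    ClassifiedStride,
    DmoSummary,
    WalkingBout,
)

MIN_STRIDE_HEIGHT_M = 0.10
MIN_STRIDE_INCLINATION_DEG = 6.0
MIN_STRIDE_LENGTH_M = 0.25
MAX_STRIDE_LENGTH_M = 2.0
MIN_STAIR_COUNT = 5
MAX_GAP_S = 2.5
MIN_LEVEL_BOUT_STRIDES = 4  # two consecutive strides of each foot


def reject_implausible(
    length_m: float,
    temporal_valid: bool = True,
    min_length_m: float = MIN_STRIDE_LENGTH_M,
    max_length_m: float = MAX_STRIDE_LENGTH_M,
) -> bool:
    """True when the stride should be rejected (implausible length or temporals)."""
    if not temporal_valid:
        return True
    if not np.isfinite(length_m):
        return True
    return length_m < min_length_m or length_m > max_length_m


def classify_stride(
    height_m: float,
    inclination_deg: float,
    min_height_m: float = MIN_STRIDE_HEIGHT_M,
    min_inclination_deg: float = MIN_STRIDE_INCLINATION_DEG,
) -> str:
    """Stride type from spatial features; thresholds are inclusive.

    Ascending/descending require BOTH the height and the inclination to pass
    their signed thresholds; everything else is level walking (ramps have no
    class of their own and count as level).
    """
    if height_m >= min_height_m and inclination_deg >= min_inclination_deg:
        return ASCENDING
    if height_m <= -min_height_m and inclination_deg <= -min_inclination_deg:
        return DESCENDING
    return LEVEL


def assemble_bouts(
    strides: list[ClassifiedStride],
    min_stair_count: int = MIN_STAIR_COUNT,
    max_gap_s: float = MAX_GAP_S,
    merge_interruptions: bool = True,
) -> list[WalkingBout]:
    """Group time-sorted strides of both feet into walking bouts.

    Strides are first chained wherever the gap to the next stride does not
    exceed ``max_gap_s``.  Within a chain, runs of same-type stair strides
    form a stair bout when at least ``min_stair_count`` strides long; with
    ``merge_interruptions`` brief level-walking strides inside the gap bound
    do not split a stair run (they stay level strides and are not bout
    members).  Too-short stair runs are re-labelled level.  Remaining level
    strides form level bouts when at least two consecutive strides of each
    foot alternate.
    """
    active = [s for s in strides if s.stride_type != REJECTED]
    active.sort(key=lambda s: s.start_time)
    _check_no_overlap(active)

    chains: list[list[ClassifiedStride]] = []
    for s in active:
        if chains and s.start_time - chains[-1][-1].end_time <= max_gap_s:
            chains[-1].append(s)
        else:
            chains.append([s])

    bouts: list[WalkingBout] = []
    for chain in chains:
        stair_members: set[int] = set()
        for stair_type in (ASCENDING, DESCENDING):
            runs = _stair_runs(chain, stair_type, merge_interruptions)
            for run in runs:
                if len(run) >= min_stair_count:
                    bouts.append(WalkingBout(strides=[chain[i] for i in run], activity=stair_type))
                    stair_members.update(run)
                else:
                    for i in run:  # too short: treated as level-walking strides
                        chain[i].stride_type = LEVEL
        level = [i for i, s in enumerate(chain) if i not in stair_members and s.stride_type == LEVEL]
        for group in _alternating_groups(chain, level):
            feet = [chain[i].foot for i in group]
            if len(group) >= MIN_LEVEL_BOUT_STRIDES and min(feet.count("left"), feet.count("right")) >= 2:
                bouts.append(WalkingBout(strides=[chain[i] for i in group], activity=LEVEL))
    bouts.sort(key=lambda b: b.start_time)
    return bouts


def _check_no_overlap(strides: list[ClassifiedStride]) -> None:
    last_end: dict[str, float] = {}
    for s in strides:
        if s.foot in last_end and s.start_time < last_end[s.foot] - 1e-9:
            raise ValueError(f"overlapping strides on the {s.foot} foot at t={s.start_time:.3f}s")
        last_end[s.foot] = s.end_time


def _stair_runs(
    chain: list[ClassifiedStride], stair_type: str, merge_interruptions: bool
) -> list[list[int]]:
    """Indices of same-type stair runs; level interruptions bridge runs when merging."""
    runs: list[list[int]] = []
    current: list[int] = []
    for i, s in enumerate(chain):
        if s.stride_type == stair_type:
            current.append(i)
        elif current:
            bridge = merge_interruptions and s.stride_type == LEVEL
            if not bridge:
                runs.append(current)
                current = []
    if current:
        runs.append(current)
    return runs


def _alternating_groups(chain: list[ClassifiedStride], indices: list[int]) -> list[list[int]]:
    """Group contiguous level strides, splitting wherever feet stop alternating."""
    groups: list[list[int]] = []
    for i in indices:
        if groups and i == groups[-1][-1] + 1 and chain[i].foot != chain[groups[-1][-1]].foot:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def compute_dmos(bouts: list[WalkingBout]) -> dict[str, DmoSummary]:
    """Pooled per-activity mean and SD of stride, swing and stance times.

    SD uses the population convention (divide by n); activities without any
    stride with finite parameters are omitted.
    """
    out: dict[str, DmoSummary] = {}
    for activity in (LEVEL, ASCENDING, DESCENDING):
        members = [s for b in bouts if b.activity == activity for s in b.strides]
        if not members:
            continue

        def _stat(values: list[float]) -> tuple[float, float]:
            arr = np.array([v for v in values if np.isfinite(v)])
            if arr.size == 0:
                return float("nan"), float("nan")
            return float(arr.mean()), float(arr.std())

        stride_m, stride_s = _stat([s.stride_time for s in members])
        swing_m, swing_s = _stat([s.swing_time for s in members])
        stance_m, stance_s = _stat([s.stance_time for s in members])
        out[activity] = DmoSummary(
            activity=activity,
            n_strides=len(members),
            stride_time_mean=stride_m,
            stride_time_sd=stride_s,
            swing_time_mean=swing_m,
            swing_time_sd=swing_s,
            stance_time_mean=stance_m,
            stance_time_sd=stance_s,
        )
    return out
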
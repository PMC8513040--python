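"""Shared domain containers for the gait-analysis pipeline.

All sample indices are 0-based and intervals are half-open ``[start, end)``
unless stated otherwise.  Accelerations are kept in g and angular rates in
deg/s (dps) at module interfaces; SI conversion happens only inside the
trajectory module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: body-frame column order
ML, PA, SI = 0, 1, 2
AXES = ("ml", "pa", "si")

LEVEL = "level"
ASCENDING = "ascending"
DESCENDING = "descending"
TRANSITION = "transition"
REJECTED = "rejected"
STRIDE_CLASSES = (LEVEL, ASCENDING, DESCENDING)


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty sequence."""


class DegenerateInputError(ValueError):
    """Raised for inputs outside an operation's domain (zero-norm vector, ...)."""


@dataclass
class ImuSequence:
    """Time-indexed 3D accelerometer (g) + gyroscope (dps) stream of one foot.

    ``frame`` is ``"sensor"`` for raw data or ``"body"`` once gravity-aligned;
    in the body frame columns are ordered (ml, pa, si).
    """

    acc: np.ndarray
    gyr: np.ndarray
    sampling_rate: float = 204.8
    frame: str = "sensor"
    foot: str = "unknown"

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.shape != self.gyr.shape or self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc and gyr must both have shape (n_samples, 3)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.frame not in ("sensor", "body"):
            raise ValueError(f"unknown frame tag {self.frame!r}")

    def __len__(self) -> int:
        return self.acc.shape[0]

    @property
    def gyr_ml(self) -> np.ndarray:
        return self.gyr[:, ML]

    @property
    def acc_pa(self) -> np.ndarray:
        return self.acc[:, PA]

    @property
    def acc_si(self) -> np.ndarray:
        return self.acc[:, SI]

    def seconds(self, sample: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(sample) / self.sampling_rate


@dataclass
class GravityAlignment:
    """Minimal rotation mapping the mean static acceleration onto (0, 0, 1)."""

    mean_static_acc: np.ndarray
    axis: np.ndarray
    angle: float

    @property
    def rotation_vector(self) -> np.ndarray:
        return self.axis * self.angle


@dataclass
class StaticWindowSet:
    """Maximal quiet windows (half-open sample intervals)."""

    windows: list[tuple[int, int]]
    min_duration_s: float
    gyr_threshold_dps: float

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class Stride:
    """One segmented stride: half-open ``[start, end)`` in original-rate samples."""

    start: int
    end: int
    predicted_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("stride start must precede end")

    @property
    def duration_samples(self) -> int:
        return self.end - self.start


@dataclass
class StrideBorderSet:
    strides: list[Stride]
    stage: str = "raw_hmm"  # raw_hmm | refined | filtered
    sampling_rate: float = 204.8

    def __len__(self) -> int:
        return len(self.strides)

    def borders(self) -> np.ndarray:
        return np.array([(s.start, s.end) for s in self.strides], dtype=int).reshape(-1, 2)


@dataclass
class StrideEvents:
    """Gait events of a single stride, as original-rate sample indices.

    The strict within-stride ordering is tc < swing_max < facc_max < ic < ms.
    ``valid`` is False when any detector failed or ordering was violated.
    """

    tc: int
    swing_max: Optional[int] = None
    facc_max: Optional[int] = None
    ic: Optional[int] = None
    ms: Optional[int] = None
    valid: bool = True
    reason: str = ""


@dataclass
class GaitEventSet:
    events: list[StrideEvents]
    sampling_rate: float = 204.8

    def __len__(self) -> int:
        return len(self.events)

    def ms_indices(self) -> list[int]:
        return [e.ms for e in self.events if e.valid and e.ms is not None]


@dataclass
class TemporalParams:
    """Per-stride temporal parameters in seconds.

    ``stride_time`` and ``stance_time`` need the previous stride's IC and are
    NaN for the first stride of a sequence.
    """

    stride_time: np.ndarray
    swing_time: np.ndarray
    stance_time: np.ndarray
    valid: np.ndarray

    @property
    def swing_ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.swing_time / self.stride_time

    def __len__(self) -> int:
        return len(self.swing_time)


@dataclass
class ZuptMask:
    """Zero-velocity mask and its component detectors (Boolean per sample)."""

    acc: np.ndarray
    gyr: np.ndarray
    ms_event: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.acc | self.gyr | self.ms_event


@dataclass
class OrientationUpdateWindow:
    start: int
    end: int  # half-open
    forced: bool = False

    @property
    def centre(self) -> int:
        return (self.start + self.end - 1) // 2


@dataclass
class TrajectoryEstimate:
    """World-frame trajectory (z up, antiparallel to gravity)."""

    position: np.ndarray  # (n, 3) metres
    velocity: np.ndarray  # (n, 3) m/s
    orientation: np.ndarray  # (n, 4) unit quaternions, scalar-last (x, y, z, w)
    zupt: np.ndarray  # (n,) bool
    sampling_rate: float = 204.8
    subsequence_bounds: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SpatialStrideParams:
    """Per-stride spatial features between consecutive mid-stance events."""

    delta: np.ndarray  # (n, 3) S_x, S_y, S_z in metres
    height: np.ndarray  # m, positive for ascent
    length: np.ndarray  # m, horizontal
    inclination: np.ndarray  # degrees
    flagged: np.ndarray  # bool, degenerate geometry
    stride_indices: Optional[np.ndarray] = None  # stride index each row belongs to

    def __len__(self) -> int:
        return len(self.height)


@dataclass
class ClassifiedStride:
    start: int
    end: int
    foot: str
    stride_type: str
    start_time: float
    end_time: float
    stride_time: float = np.nan
    swing_time: float = np.nan
    stance_time: float = np.nan
    height: float = np.nan
    length: float = np.nan
    inclination: float = np.nan


@dataclass
class WalkingBout:
    strides: list[ClassifiedStride]
    activity: str

    @property
    def start_time(self) -> float:
        return min(s.start_time for s in self.strides)

    @property
    def end_time(self) -> float:
        return max(s.end_time for s in self.strides)

    def __len__(self) -> int:
        return len(self.strides)


@dataclass
class DmoSummary:
    """Per-activity digital mobility outcomes (population SD convention)."""

    activity: str
    n_strides: int
    stride_time_mean: float
    stride_time_sd: float
    swing_time_mean: float
    swing_time_sd: float
    stance_time_mean: float
    stance_time_sd: float

    def to_dict(self) -> dict:
        return {
            "activity": self.activity,
            "n_strides": self.n_strides,
            "stride_time_mean": self.stride_time_mean,
            "stride_time_sd": self.stride_time_sd,
            "swing_time_mean": self.swing_time_mean,
            "swing_time_sd": self.swing_time_sd,
            "stance_time_mean": self.stance_time_mean,
            "stance_time_sd": self.stance_time_sd,
        }
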
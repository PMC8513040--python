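"""Pressure-insole (FSR) reference processing.

Three force-sensitive resistors per insole (toe, first metatarsal head,
heel) provide a ground-contact reference.  The conditioned sensor voltage
follows a non-inverting amplifier model; calibrated loads are summed into a
total-weight signal from which reference initial/terminal contacts are read
with a body-weight-relative threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import DegenerateInputError

#: reference voltage of the conditioning circuit, volts
V_REF = 0.1
#: threshold for reference events, fraction of body weight
DEFAULT_THRESHOLD_FRACTION = 0.075
#: calibrated load range of each sensor, kg
CALIBRATED_RANGE_KG = (0.5, 20.0)


@dataclass
class FsrCalibration:
    """Per-channel conditioning + polynomial load calibration.

    ``poly_coeffs`` map conditioned voltage to load in kg (numpy polyval
    order, highest degree first); loads saturate at the calibrated maximum.
    """

    r_ref_ohm: float
    poly_coeffs: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    v_ref: float = V_REF

    def load_from_resistance(self, r_fsr_ohm: float) -> float:
        v = conditioned_voltage(r_fsr_ohm, self)
        load = float(np.polyval(self.poly_coeffs, v))
        return min(max(load, 0.0), CALIBRATED_RANGE_KG[1])


@dataclass
class FsrRecord:
    """Per-sample loads in kg for the toe, MTH and heel channels."""

    loads: np.ndarray  # (n, 3) columns toe, mth, heel
    sampling_rate: float = 204.8
    body_weight_kg: float = 70.0

    def __post_init__(self) -> None:
        self.loads = np.asarray(self.loads, dtype=float)
        if self.loads.ndim != 2 or self.loads.shape[1] != 3:
            raise ValueError("loads must have shape (n_samples, 3)")

    def __len__(self) -> int:
        return self.loads.shape[0]


def conditioned_voltage(r_fsr_ohm: float | np.ndarray, cal: FsrCalibration) -> float | np.ndarray:
    """Output voltage of the non-inverting amplifier: V_ref * (1 + R_ref / R_fsr)."""
    r = np.asarray(r_fsr_ohm, dtype=float)
    if np.any(r <= 0):
        raise DegenerateInputError("FSR resistance must be positive")
    out = cal.v_ref * (1.0 + cal.r_ref_ohm / r)
    return float(out) if out.ndim == 0 else out


def total_weight(record: FsrRecord, stride_borders: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Channel sum with per-stride minimum-baseline subtraction.

    Baseline offsets (e.g. from shoe lacing) are removed by subtracting the
    minimum total weight between stride borders; without borders a single
    global minimum per recording is used.
    """
    tw = record.loads.sum(axis=1)
    out = tw.copy()
    if stride_borders:
        for s, e in stride_borders:
            seg = tw[s:e]
            if seg.size:
                out[s:e] = seg - seg.min()
    elif tw.size:
        out = tw - tw.min()
    return np.maximum(out, 0.0)


def detect_reference_events(
    total_weight_kg: np.ndarray,
    body_weight_kg: float,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> list[tuple[str, int]]:
    """Threshold crossings of the total-weight signal as reference IC/TC events.

    An IC is recorded at the first sample at/above the threshold, a TC at the
    first sample below it again (no sub-sample interpolation); IC and TC
    strictly alternate.
    """
    if body_weight_kg <= 0:
        raise DegenerateInputError("body weight must be positive")
    thr = threshold_fraction * body_weight_kg
    above = np.asarray(total_weight_kg) >= thr
    events: list[tuple[str, int]] = []
    loaded = bool(above[0]) if above.size else False
    if loaded:
        events.append(("ic", 0))
    for i in range(1, above.size):
        if above[i] and not loaded:
            events.append(("ic", i))
            loaded = True
        elif not above[i] and loaded:
            events.append(("tc", i))
            loaded = False
    return events
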
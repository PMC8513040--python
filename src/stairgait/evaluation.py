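"""Segmentation scoring and event-timing error statistics.

A predicted stride is a true positive when both of its borders lie within
the matching tolerance (+-100 ms) of an unmatched reference stride's
borders; unmatched predictions are false positives and unmatched references
false negatives.  Precision, recall and F1 follow the usual definitions,
with 0 substituted on empty denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import StrideBorderSet

MATCH_TOLERANCE_MS = 100.0


@dataclass
class SegmentationScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    tolerance_ms: float = MATCH_TOLERANCE_MS


@dataclass
class TimingErrorStats:
    mean_ms: float
    sd_ms: float
    mae_ms: float
    n: int


def match_strides(
    predicted: StrideBorderSet | list[tuple[int, int]],
    reference: StrideBorderSet | list[tuple[int, int]],
    sampling_rate: float | None = None,
    tol_ms: float = MATCH_TOLERANCE_MS,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy time-ordered one-to-one matching with a +-tol window per border.

    Returns (TP, FP, FN, pairing) where pairing holds (predicted_index,
    reference_index) tuples.  Each reference stride is matched at most once;
    among admissible references the nearest (summed border distance) wins.
    """
    pred = _as_borders(predicted)
    ref = _as_borders(reference)
    fs = sampling_rate or getattr(predicted, "sampling_rate", None) or 204.8
    tol = tol_ms / 1000.0 * fs
    used: set[int] = set()
    pairing: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(pred):
        best, best_d = None, None
        for j, (a, b) in enumerate(ref):
            if j in used:
                continue
            if abs(s - a) <= tol and abs(e - b) <= tol:
                d = abs(s - a) + abs(e - b)
                if best_d is None or d < best_d:
                    best, best_d = j, d
        if best is not None:
            used.add(best)
            pairing.append((i, best))
    tp = len(pairing)
    return tp, len(pred) - tp, len(ref) - tp, pairing


def _as_borders(x) -> list[tuple[int, int]]:
    if isinstance(x, StrideBorderSet):
        return [(s.start, s.end) for s in x.strides]
    return [(int(a), int(b)) for a, b in x]


def scores(tp: int, fp: int, fn: int) -> SegmentationScore:
    """Precision, recall and F1 from match counts (0 on empty denominators)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return SegmentationScore(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


def timing_errors(
    predicted_events: np.ndarray | list[int],
    reference_events: np.ndarray | list[int],
    sampling_rate: float = 204.8,
) -> TimingErrorStats:
    """Signed timing errors (predicted - reference) in ms with mean, SD, MAE.

    Inputs are paired per stride (same length, same order); SD uses the
    population convention.
    """
    pred = np.asarray(predicted_events, dtype=float)
    ref = np.asarray(reference_events, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference events must be paired 1:1")
    if pred.size == 0:
        return TimingErrorStats(mean_ms=float("nan"), sd_ms=float("nan"), mae_ms=float("nan"), n=0)
    err = (pred - ref) / sampling_rate * 1000.0
    return TimingErrorStats(
        mean_ms=float(err.mean()),
        sd_ms=float(err.std()),
        mae_ms=float(np.abs(err).mean()),
        n=int(err.size),
    )
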
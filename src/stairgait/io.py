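"""CSV/JSON readers and writers for pipeline artifacts.

IMU files are columnar CSV with header ``t,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z``
(units g and dps, one file per foot); insole files use
``t,toe_kg,mth_kg,heel_kg``.  All writers are deterministic (fixed float
format) so repeated runs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fsr import FsrRecord
from .synthetic import SyntheticWalk
from .types import GaitEventSet, ImuSequence, StrideBorderSet, TemporalParams

FLOAT_FORMAT = "%.9g"


def read_imu_csv(path: str | Path, sampling_rate: float | None = None, foot: str = "unknown") -> ImuSequence:
    df = pd.read_csv(path)
    expected = ["t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"IMU file {path} lacks columns {missing}")
    if sampling_rate is None:
        dt = np.diff(df["t"].to_numpy())
        if len(dt) == 0 or dt.mean() <= 0:
            raise ValueError("cannot infer sampling rate from a single-row file")
        sampling_rate = float(1.0 / dt.mean())
    return ImuSequence(
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        gyr=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(),
        sampling_rate=sampling_rate,
        frame="sensor",
        foot=foot,
    )


def write_imu_csv(seq: ImuSequence, path: str | Path) -> None:
    n = len(seq)
    t = np.arange(n) / seq.sampling_rate
    df = pd.DataFrame(
        {
            "t": t,
            "acc_x": seq.acc[:, 0],
            "acc_y": seq.acc[:, 1],
            "acc_z": seq.acc[:, 2],
            "gyr_x": seq.gyr[:, 0],
            "gyr_y": seq.gyr[:, 1],
            "gyr_z": seq.gyr[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fsr_csv(path: str | Path, sampling_rate: float | None = None, body_weight_kg: float = 70.0) -> FsrRecord:
    df = pd.read_csv(path)
    if sampling_rate is None:
        dt = np.diff(df["t"].to_numpy())
        sampling_rate = float(1.0 / dt.mean())
    return FsrRecord(
        loads=df[["toe_kg", "mth_kg", "heel_kg"]].to_numpy(),
        sampling_rate=sampling_rate,
        body_weight_kg=body_weight_kg,
    )


def write_fsr_csv(record: FsrRecord, path: str | Path) -> None:
    t = np.arange(len(record)) / record.sampling_rate
    df = pd.DataFrame(
        {
            "t": t,
            "toe_kg": record.loads[:, 0],
            "mth_kg": record.loads[:, 1],
            "heel_kg": record.loads[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_strides_csv(borders: StrideBorderSet, path: str | Path) -> None:
    fs = borders.sampling_rate
    df = pd.DataFrame(
        {
            "stride": np.arange(len(borders)),
            "start_sample": [s.start for s in borders.strides],
            "end_sample": [s.end for s in borders.strides],
            "start_s": [s.start / fs for s in borders.strides],
            "end_s": [s.end / fs for s in borders.strides],
            "stage": borders.stage,
            "predicted_class": [s.predicted_class for s in borders.strides],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_strides_csv(path: str | Path, sampling_rate: float = 204.8) -> StrideBorderSet:
    from .types import Stride

    df = pd.read_csv(path)
    strides = [
        Stride(int(r.start_sample), int(r.end_sample), str(getattr(r, "predicted_class", "unknown")))
        for r in df.itertuples()
    ]
    stage = str(df["stage"].iloc[0]) if len(df) and "stage" in df else "refined"
    return StrideBorderSet(strides=strides, stage=stage, sampling_rate=sampling_rate)


def write_events_csv(events: GaitEventSet, params: TemporalParams | None, path: str | Path) -> None:
    rows = []
    fs = events.sampling_rate
    for i, ev in enumerate(events.events):
        row = {
            "stride": i,
            "tc": ev.tc,
            "swing_max": ev.swing_max,
            "facc_max": ev.facc_max,
            "ic": ev.ic,
            "ms": ev.ms,
            "valid": ev.valid,
            "reason": ev.reason,
        }
        if params is not None:
            row.update(
                stride_time_s=params.stride_time[i],
                swing_time_s=params.swing_time[i],
                stance_time_s=params.stance_time[i],
                temporal_valid=bool(params.valid[i]),
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_walk(walk: SyntheticWalk, out_dir: str | Path) -> dict[str, Path]:
    """Persist a synthetic walk as the CSV dialects the pipeline reads, plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth: dict = {"sampling_rate": walk.sampling_rate, "body_weight_kg": walk.body_weight_kg}
    for foot in ("left", "right"):
        ch = walk.foot(foot)
        paths[f"imu_{foot}"] = out / f"imu_{foot}.csv"
        write_imu_csv(ch.imu, paths[f"imu_{foot}"])
        paths[f"fsr_{foot}"] = out / f"fsr_{foot}.csv"
        write_fsr_csv(ch.fsr, paths[f"fsr_{foot}"])
        truth[foot] = {
            "borders": ch.truth.borders.tolist(),
            "labels": ch.truth.labels,
            "tc": ch.truth.tc.tolist(),
            "swing_max": ch.truth.swing_max.tolist(),
            "facc_max": ch.truth.facc_max.tolist(),
            "ic": ch.truth.ic.tolist(),
            "ms": ch.truth.ms.tolist(),
            "contacts": [list(c) for c in ch.truth.contacts],
        }
    if walk.manifest:
        truth["manifest"] = walk.manifest
    paths["truth"] = out / "truth.json"
    write_json(truth, paths["truth"])
    return paths
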
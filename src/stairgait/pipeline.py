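"""End-to-end orchestration: raw per-foot IMU files in, DMO report out.

Stages: gravity alignment -> HMM stride segmentation -> gait-event detection
and temporal parameters -> ZUPT-aided trajectory reconstruction -> spatial
stride features -> stride-type classification -> walking-bout assembly ->
digital mobility outcomes.  Every intermediate is persisted as CSV with a
JSON report at the end; all stages are pure functions of their inputs and
the configuration, so identical config + seed reproduce byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as cls
from . import events as ev
from . import hmm
from . import io as sio
from . import preprocessing as pp
from . import trajectory as tj
from .types import REJECTED, STRIDE_CLASSES, TRANSITION, ClassifiedStride, ImuSequence

log = logging.getLogger("stairgait")


@dataclass
class PipelineConfig:
    """All tunable parameters with their published defaults."""

    left_imu: str = ""
    right_imu: str = ""
    model_path: str = ""
    out_dir: str = "stairgait_out"
    sampling_rate: float | None = None  # inferred from the time column if None
    seed: int = 0
    # preprocessing
    static_min_duration_s: float = 1.0
    static_gyr_threshold_dps: float = 2.5
    # classification / bouts
    min_stair_count: int = cls.MIN_STAIR_COUNT
    max_gap_s: float = cls.MAX_GAP_S
    merge_interruptions: bool = True

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls_(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class FootResult:
    foot: str
    body: ImuSequence
    borders: "hmm.StrideBorderSet"
    events: "ev.GaitEventSet"
    temporal: "ev.TemporalParams"
    spatial: "tj.SpatialStrideParams"
    classified: list[ClassifiedStride] = field(default_factory=list)


def process_foot(
    seq: ImuSequence,
    model: hmm.SegmentationModel,
    foot: str,
    config: PipelineConfig | None = None,
) -> FootResult:
    """Run all per-foot stages on one raw sensor-frame sequence."""
    config = config or PipelineConfig()
    alignment = pp.alignment_from_sequence(
        seq, config.static_min_duration_s, config.static_gyr_threshold_dps
    )
    body = pp.align_to_body_frame(seq, alignment, foot=foot)
    feats = hmm.extract_features(body)
    borders = hmm.postprocess_strides(hmm.predict_stride_borders(model, feats, body), body)
    events = ev.detect_events(body, borders)
    temporal = ev.flag_outliers(ev.compute_temporal_params(events))
    zupt = tj.detect_zupt(body, events)
    windows = tj.find_orientation_windows(body)
    traj = tj.reconstruct_trajectory(body, zupt, windows)
    spatial = tj.compute_spatial_params(traj, events)
    classified = classify_foot_strides(borders, events, temporal, spatial, foot, body.sampling_rate)
    return FootResult(
        foot=foot,
        body=body,
        borders=borders,
        events=events,
        temporal=temporal,
        spatial=spatial,
        classified=classified,
    )


def classify_foot_strides(
    borders, events, temporal, spatial, foot: str, fs: float
) -> list[ClassifiedStride]:
    """Attach spatial/temporal parameters to strides and classify each one.

    Strides without a spatial estimate (the first stride of a sequence, or
    strides whose mid-stance was not detected) cannot be measured and are
    rejected, as are strides failing the plausibility bounds.
    """
    spatial_by_stride = {}
    if spatial.stride_indices is not None:
        for row, idx in enumerate(spatial.stride_indices):
            spatial_by_stride[int(idx)] = row
    out: list[ClassifiedStride] = []
    for i, stride in enumerate(borders.strides):
        height = length = incl = float("nan")
        if i in spatial_by_stride:
            r = spatial_by_stride[i]
            height, length, incl = spatial.height[r], spatial.length[r], spatial.inclination[r]
        tvalid = bool(temporal.valid[i]) if i < len(temporal) else False
        if cls.reject_implausible(length, tvalid):
            stride_type = REJECTED
        else:
            stride_type = cls.classify_stride(height, incl)
        out.append(
            ClassifiedStride(
                start=stride.start,
                end=stride.end,
                foot=foot,
                stride_type=stride_type,
                start_time=stride.start / fs,
                end_time=stride.end / fs,
                stride_time=float(temporal.stride_time[i]) if i < len(temporal) else float("nan"),
                swing_time=float(temporal.swing_time[i]) if i < len(temporal) else float("nan"),
                stance_time=float(temporal.stance_time[i]) if i < len(temporal) else float("nan"),
                height=float(height),
                length=float(length),
                inclination=float(incl),
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline per the configuration and persist artifacts.

    Returns the DMO report dictionary (also written to ``dmos.json``).
    Empty inputs produce an empty report with a warning, not an error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = hmm.SegmentationModel.load(config.model_path)
    all_strides: list[ClassifiedStride] = []
    counts: dict[str, dict] = {}
    for foot, path in (("left", config.left_imu), ("right", config.right_imu)):
        if not path:
            continue
        seq = sio.read_imu_csv(path, config.sampling_rate, foot=foot)
        result = process_foot(seq, model, foot, config)
        sio.write_strides_csv(result.borders, out / f"strides_{foot}.csv")
        sio.write_events_csv(result.events, result.temporal, out / f"events_{foot}.csv")
        _write_trajectory_csv(result, out / f"spatial_{foot}.csv")
        all_strides.extend(result.classified)
        counts[foot] = {
            "n_samples": len(seq),
            "n_strides": len(result.borders),
            "n_valid_events": int(sum(e.valid for e in result.events.events)),
            "n_rejected": sum(1 for s in result.classified if s.stride_type == REJECTED),
        }
        log.info("%s foot: %s", foot, counts[foot])
    if not all_strides:
        log.warning("no strides segmented; writing an empty report")
    bouts = cls.assemble_bouts(
        all_strides,
        min_stair_count=config.min_stair_count,
        max_gap_s=config.max_gap_s,
        merge_interruptions=config.merge_interruptions,
    )
    dmos = cls.compute_dmos(bouts)
    report = {
        "schema_version": 1,
        "config": {"seed": config.seed, "min_stair_count": config.min_stair_count},
        "per_foot": counts,
        "n_bouts": len(bouts),
        "bouts": [
            {
                "activity": b.activity,
                "n_strides": len(b),
                "start_s": round(b.start_time, 6),
                "end_s": round(b.end_time, 6),
            }
            for b in bouts
        ],
        "dmos": {k: v.to_dict() for k, v in dmos.items()},
    }
    sio.write_json(report, out / "dmos.json")
    return report


def _write_trajectory_csv(result: FootResult, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "stride": i,
            "start_sample": s.start,
            "end_sample": s.end,
            "stride_type": c.stride_type,
            "height_m": c.height,
            "length_m": c.length,
            "inclination_deg": c.inclination,
            "stride_time_s": c.stride_time,
            "swing_time_s": c.swing_time,
            "stance_time_s": c.stance_time,
        }
        for i, (s, c) in enumerate(zip(result.borders.strides, result.classified))
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=sio.FLOAT_FORMAT)


def train_model_from_walks(walks, seed: int = 0) -> hmm.SegmentationModel:
    """Train the four sub-models on annotated synthetic walks and assemble them.

    ``walks`` is an iterable of SyntheticWalk (or (manifest, walk) tuples);
    ground-truth borders and labels provide the per-class training sequences.
    """
    pools: dict[str, list[np.ndarray]] = {c: [] for c in (TRANSITION, *STRIDE_CLASSES)}
    for item in walks:
        walk = item[1] if isinstance(item, tuple) else item
        for foot in ("left", "right"):
            ch = walk.foot(foot)
            body = pp.align_to_body_frame(ch.imu, pp.alignment_from_sequence(ch.imu), foot=foot)
            feats = hmm.extract_features(body, bout_id=str(getattr(walk, "seed", 0)) + foot)
            for c, seqs in hmm.split_training_sequences(
                feats, ch.truth.stride_borders, ch.truth.labels
            ).items():
                pools[c].extend(seqs)
    subs = {}
    for c in pools:
        spec = (
            hmm.transition_submodel_spec() if c == TRANSITION else hmm.stride_submodel_spec(c)
        )
        usable = [s for s in pools[c] if len(s) >= spec.n_states]
        if not usable:
            raise ValueError(f"no usable training sequences for class {c!r}")
        subs[c] = hmm.train_submodel(usable, spec, seed=seed)
    return hmm.build_segmentation_model(
        subs[TRANSITION], subs["level"], subs["ascending"], subs["descending"]
    )
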
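"""Shared fixtures: synthetic walks and a session-scoped trained segmentation model."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pytest

from stairgait import hmm, pipeline as pl, preprocessing as pp
from stairgait import synthetic as syn
from stairgait.types import Stride, StrideBorderSet

logging.getLogger("hmmlearn").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="Degenerate mixture covariance")


def align_foot(walk: syn.SyntheticWalk, foot: str):
    """Gravity-align one foot of a synthetic walk into the body frame."""
    ch = walk.foot(foot)
    alignment = pp.alignment_from_sequence(ch.imu)
    return pp.align_to_body_frame(ch.imu, alignment, foot=foot), ch.truth


def truth_border_set(truth, fs: float = 204.8) -> StrideBorderSet:
    return StrideBorderSet(
        [Stride(int(a), int(b)) for a, b in truth.stride_borders],
        stage="refined",
        sampling_rate=fs,
    )


@pytest.fixture(scope="session")
def level_walk_nf() -> syn.SyntheticWalk:
    return syn.generate_walk(
        [syn.level_spec() for _ in range(12)], noise=syn.NoiseParams.none(), seed=101
    )


@pytest.fixture(scope="session")
def ascending_walk_nf() -> syn.SyntheticWalk:
    return syn.generate_walk(
        [syn.stair_spec("A", "up") for _ in range(18)], noise=syn.NoiseParams.none(), seed=102
    )


@pytest.fixture(scope="session")
def trained_model() -> hmm.SegmentationModel:
    """Multiclass segmentation model trained once on a synthetic training set."""
    walks = syn.generate_evaluation_set(
        n_participants=2, seed=42, n_stair_strides=6, n_level_strides=3
    )
    return pl.train_model_from_walks(walks, seed=1)
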
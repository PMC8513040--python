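"""Multiclass hidden-Markov-model stride segmentation.

Four sub-models are trained independently — a transition model for
non-gait data and one left-right stride model per stride class (level
walking, stair ascending, stair descending) — and then assembled into a
single segmentation model by joining their transition matrices
block-diagonally and inserting the missing border edges between sub-models.
Crossing any of those edges in the decoded Viterbi state path marks a stride
border.

Feature space (51.2 Hz): the mediolateral angular velocity and the
superior-inferior acceleration, each with a centred sliding-window linear
gradient, z-score standardized per walking bout.

The HMM machinery (Baum-Welch, Viterbi, Gaussian-mixture emissions) is
delegated to hmmlearn; topologies, the assembly and all border logic live
here.  Predicted per-stride class labels are retained for diagnostics but
are not used downstream; only the borders feed the rest of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from hmmlearn.hmm import GMMHMM
from scipy import signal as sps
from sklearn.cluster import KMeans

from .types import (
    ASCENDING,
    DESCENDING,
    LEVEL,
    TRANSITION,
    DegenerateInputError,
    ImuSequence,
    Stride,
    StrideBorderSet,
)

DOWNSAMPLE_FACTOR = 4
FEATURE_RATE_HZ = 51.2
FEATURE_LOWPASS_HZ = 10.0
FEATURE_LOWPASS_ORDER = 4
GRADIENT_WINDOW_S = 0.2

N_STATES_TRANSITION = 5
N_STATES_STRIDE = 20
N_MIXTURE_COMPONENTS = 8
N_TRAINING_ITERATIONS = 10

BORDER_SNAP_HALF_WINDOW_S = 0.150

MIN_STRIDE_DURATION_S = 0.4
MAX_STRIDE_DURATION_S = 2.5
MIN_TC_DIP_DPS = -20.0
MIN_SWING_PEAK_DPS = 50.0

FEATURE_COLUMNS = ("gyr_ml", "acc_si", "grad_gyr_ml", "grad_acc_si")


@dataclass
class HmmFeatureMatrix:
    """Standardized 4-column feature matrix of one walking bout."""

    data: np.ndarray  # (n, 4)
    rate: float = FEATURE_RATE_HZ
    bout_id: int | str = 0
    mean: np.ndarray | None = None  # per-column standardization parameters
    std: np.ndarray | None = None

    def __len__(self) -> int:
        return self.data.shape[0]


def _sliding_gradient(x: np.ndarray, window: int) -> np.ndarray:
    """Slope of a least-squares line in a centred window (units per sample).

    For a symmetric window the LS slope is a correlation with the centred
    time axis; the first/last ``window // 2`` samples use shrunken symmetric
    windows (a two-point slope at the very edges).
    """
    n = len(x)
    half = window // 2
    j = np.arange(-half, half + 1, dtype=float)
    grad = np.convolve(x, -j / float((j * j).sum()), mode="same")  # kernel reversed
    for i in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
        h = min(i, n - 1 - i, half)
        if h < 1:
            seg = x[max(i - 1, 0) : i + 2]
            grad[i] = float(seg[-1] - seg[0]) / max(len(seg) - 1, 1)
            continue
        jj = np.arange(-h, h + 1, dtype=float)
        grad[i] = float((jj * x[i - h : i + h + 1]).sum() / (jj * jj).sum())
    return grad


def extract_features(seq: ImuSequence, bout_id: int | str = 0) -> HmmFeatureMatrix:
    """Downsample x4, low-pass at 10 Hz, add centred linear gradients, z-score.

    The returned matrix has ceil(n / 4) rows and columns
    (gyr_ml, acc_si, grad_gyr_ml, grad_acc_si), standardized per bout with
    the parameters stored on the matrix.
    """
    if seq.frame != "body":
        raise ValueError("feature extraction expects a body-frame sequence")
    rate = seq.sampling_rate / DOWNSAMPLE_FACTOR
    sos = sps.butter(FEATURE_LOWPASS_ORDER, FEATURE_LOWPASS_HZ, btype="low", fs=rate, output="sos")
    gyr = sps.sosfiltfilt(sos, seq.gyr_ml[::DOWNSAMPLE_FACTOR])
    acc = sps.sosfiltfilt(sos, seq.acc_si[::DOWNSAMPLE_FACTOR])
    window = int(round(GRADIENT_WINDOW_S * rate))
    if window % 2 == 0:
        window += 1
    cols = [gyr, acc, _sliding_gradient(gyr, window) * rate, _sliding_gradient(acc, window) * rate]
    data = np.column_stack(cols)
    mean = data.mean(axis=0)
    std = data.std(axis=0)
    for name, s in zip(FEATURE_COLUMNS, std):
        if s < 1e-12:
            raise DegenerateInputError(f"feature column {name!r} has zero variance in bout {bout_id!r}")
    return HmmFeatureMatrix(data=(data - mean) / std, rate=rate, bout_id=bout_id, mean=mean, std=std)


# --- sub-model topologies ----------------------------------------------------

@dataclass
class SubModelSpec:
    stride_class: str
    n_states: int
    topology: str  # "left_right" | "transition"
    n_mixture_components: int = N_MIXTURE_COMPONENTS
    n_training_iterations: int = N_TRAINING_ITERATIONS


def stride_submodel_spec(stride_class: str, n_states: int = N_STATES_STRIDE, **kw) -> SubModelSpec:
    return SubModelSpec(stride_class=stride_class, n_states=n_states, topology="left_right", **kw)


def transition_submodel_spec(n_states: int = N_STATES_TRANSITION, **kw) -> SubModelSpec:
    return SubModelSpec(stride_class=TRANSITION, n_states=n_states, topology="transition", **kw)


def initial_transmat(spec: SubModelSpec) -> np.ndarray:
    """Structural transition matrix of a sub-model.

    Left-right chains allow only self transitions and the next state; the
    transition topology additionally keeps a dense first row and first column
    (any state can restart the loop) and a last-state self-loop.
    """
    n = spec.n_states
    t = np.zeros((n, n))
    if spec.topology == "left_right":
        for i in range(n - 1):
            t[i, i] = 0.8
            t[i, i + 1] = 0.2
        t[n - 1, n - 1] = 1.0
    elif spec.topology == "transition":
        t[0, :] = 1.0
        t[:, 0] = 1.0
        for i in range(n - 1):
            t[i, i] = 1.0
            t[i, i + 1] = 1.0
        t[n - 1, n - 1] = 1.0
        t /= t.sum(axis=1, keepdims=True)
        return t
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")
    return t


def initial_startprob(spec: SubModelSpec) -> np.ndarray:
    p = np.zeros(spec.n_states)
    if spec.topology == "left_right":
        p[0] = 1.0
    else:
        p[:] = 1.0 / spec.n_states
    return p


@dataclass
class TrainedSubModel:
    spec: SubModelSpec
    startprob: np.ndarray
    transmat: np.ndarray
    weights: np.ndarray  # (n_states, n_mix)
    means: np.ndarray  # (n_states, n_mix, n_features)
    covars: np.ndarray  # (n_states, n_mix, n_features) diagonal
    log_likelihood_history: list[float] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.spec.n_states


_COVAR_FLOOR = 1e-2  # features are z-scored; keep mixtures from collapsing


def _init_emissions(
    sequences: list[np.ndarray], n_states: int, n_mix: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-means emission initialization from an equal-length partition.

    Each training sequence is split into ``n_states`` equal chunks; the data
    pooled per state is clustered into the mixture components.
    """
    d = sequences[0].shape[1]
    weights = np.full((n_states, n_mix), 1.0 / n_mix)
    means = np.zeros((n_states, n_mix, d))
    covars = np.ones((n_states, n_mix, d))
    for s in range(n_states):
        pool = np.vstack(
            [seq[int(s * len(seq) / n_states) : int((s + 1) * len(seq) / n_states)] for seq in sequences]
        )
        k = min(n_mix, len(np.unique(pool, axis=0)))
        km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(pool)
        for c in range(n_mix):
            cc = min(c, k - 1)
            members = pool[km.labels_ == cc]
            means[s, c] = km.cluster_centers_[cc] + (0.0 if c < k else 1e-3 * (c - k + 1))
            if len(members) > 1:
                covars[s, c] = np.maximum(members.var(axis=0), _COVAR_FLOOR)
            else:
                covars[s, c] = 1.0
            weights[s, c] = max(len(members), 1)
        weights[s] /= weights[s].sum()
    return weights, means, covars


class _StableGMMHMM(GMMHMM):
    """GMMHMM that repairs degenerate mixture components after each M-step.

    With many states and mixture components on repetitive data, individual
    components can receive (numerically) zero responsibility, which turns
    their parameters into NaN and poisons the next E-step.  Such components
    are reset to a weakly weighted broad component; rows of the transition
    matrix belonging to unoccupied states are reset to their structural
    topology.  Structural zeros are preserved throughout.
    """

    _structure: np.ndarray | None = None

    def _do_mstep(self, stats) -> None:
        super()._do_mstep(stats)
        bad = ~np.isfinite(self.means_).all(axis=2) | ~np.isfinite(self.covars_).all(axis=2)
        bad |= ~np.isfinite(self.weights_)
        if bad.any():
            self.means_[bad] = 0.0
            self.covars_[bad] = 1.0
            self.weights_[bad] = 1e-6
        self.weights_ = np.maximum(self.weights_, 1e-10)
        self.weights_ /= self.weights_.sum(axis=1, keepdims=True)
        self.covars_ = np.maximum(self.covars_, self.min_covar)
        rows_bad = ~np.isfinite(self.transmat_).all(axis=1)
        if rows_bad.any() and self._structure is not None:
            repaired = self._structure / self._structure.sum(axis=1, keepdims=True)
            self.transmat_[rows_bad] = repaired[rows_bad]


def _as_gmmhmm(
    startprob: np.ndarray,
    transmat: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    covars: np.ndarray,
    seed: int | None = None,
    n_iter: int = N_TRAINING_ITERATIONS,
) -> GMMHMM:
    n_states, n_mix, d = means.shape
    model = _StableGMMHMM(
        n_components=n_states,
        n_mix=n_mix,
        covariance_type="diag",
        min_covar=1e-3,
        n_iter=n_iter,
        tol=-np.inf,
        init_params="",
        params="tmcw",
        random_state=seed,
    )
    model.n_features = d
    model.startprob_ = startprob.copy()
    model.transmat_ = transmat.copy()
    model._structure = (transmat > 0).astype(float)
    model.weights_ = weights.copy()
    model.means_ = means.copy()
    model.covars_ = covars.copy()
    return model


def train_submodel(
    bouts: list[HmmFeatureMatrix | np.ndarray], spec: SubModelSpec, seed: int | None = 0
) -> TrainedSubModel:
    """Baum-Welch training of one sub-model on data of its own class only.

    Structural zeros of the topology are preserved by EM; the start
    distribution stays fixed.  Raises if any training sequence is shorter
    than the number of states.
    """
    sequences = [b.data if isinstance(b, HmmFeatureMatrix) else np.asarray(b, float) for b in bouts]
    if not sequences:
        raise ValueError("need at least one training bout")
    for i, s in enumerate(sequences):
        if len(s) < spec.n_states:
            raise ValueError(
                f"training sequence {i} has {len(s)} samples < n_states = {spec.n_states}"
            )
    weights, means, covars = _init_emissions(
        sequences, spec.n_states, spec.n_mixture_components, seed
    )
    model = _as_gmmhmm(
        initial_startprob(spec),
        initial_transmat(spec),
        weights,
        means,
        covars,
        seed=seed,
        n_iter=spec.n_training_iterations,
    )
    x = np.vstack(sequences)
    lengths = [len(s) for s in sequences]
    model.fit(x, lengths)
    return TrainedSubModel(
        spec=spec,
        startprob=model.startprob_,
        transmat=model.transmat_,
        weights=model.weights_,
        means=model.means_,
        covars=model.covars_,
        log_likelihood_history=list(model.monitor_.history),
    )


# --- combined segmentation model ---------------------------------------------

@dataclass
class SegmentationModel:
    """Assembled multiclass model: block-diagonal sub-models + border edges."""

    transmat: np.ndarray
    startprob: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    covars: np.ndarray
    state_class_map: list[str]  # per-state stride class / "transition"
    block_slices: dict[str, tuple[int, int]]
    border_edges: dict[tuple[int, int], str]  # edge -> class whose stride starts

    @property
    def n_states(self) -> int:
        return self.transmat.shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
            "state_class_map": self.state_class_map,
            "block_slices": {k: list(v) for k, v in self.block_slices.items()},
            "border_edges": [[a, b, c] for (a, b), c in self.border_edges.items()],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        p = json.loads(Path(path).read_text())
        if p.get("schema_version") != 1:
            raise ValueError("unsupported model schema version")
        return cls(
            transmat=np.array(p["transmat"]),
            startprob=np.array(p["startprob"]),
            weights=np.array(p["weights"]),
            means=np.array(p["means"]),
            covars=np.array(p["covars"]),
            state_class_map=list(p["state_class_map"]),
            block_slices={k: tuple(v) for k, v in p["block_slices"].items()},
            border_edges={(a, b): c for a, b, c in p["border_edges"]},
        )


def build_segmentation_model(
    transition_m: TrainedSubModel,
    level_m: TrainedSubModel,
    ascending_m: TrainedSubModel,
    descending_m: TrainedSubModel,
) -> SegmentationModel:
    """Join the four sub-models and insert the inter-sub-model border edges.

    Inserted edges: from every transition state into each stride model's
    first state; from each stride model's last state into every transition
    state; stride self-restarts (last -> first of the same model); and the
    stride-to-stride edges level<->ascending, level<->descending (no direct
    ascending<->descending edge exists).  Each inserted edge receives the
    mean outgoing probability of its source row before row renormalization.
    """
    subs = {TRANSITION: transition_m, LEVEL: level_m, ASCENDING: ascending_m, DESCENDING: descending_m}
    for name, m in subs.items():
        if m is None:
            raise ValueError(f"missing sub-model {name!r}")
    order = [TRANSITION, LEVEL, ASCENDING, DESCENDING]
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for name in order:
        offsets[name] = (pos, pos + subs[name].n_states)
        pos += subs[name].n_states
    n = pos
    s_mat = np.zeros((n, n))
    for name in order:
        a, b = offsets[name]
        s_mat[a:b, a:b] = subs[name].transmat

    t_states = list(range(*offsets[TRANSITION]))
    first = {c: offsets[c][0] for c in (LEVEL, ASCENDING, DESCENDING)}
    last = {c: offsets[c][1] - 1 for c in (LEVEL, ASCENDING, DESCENDING)}

    border_edges: dict[tuple[int, int], str] = {}
    for c in (LEVEL, ASCENDING, DESCENDING):
        for t in t_states:
            border_edges[(t, first[c])] = c  # gait initiation
            border_edges[(last[c], t)] = TRANSITION  # gait termination
        border_edges[(last[c], first[c])] = c  # stride self-restart
    for src, dst in (
        (ASCENDING, LEVEL),
        (DESCENDING, LEVEL),
        (LEVEL, ASCENDING),
        (LEVEL, DESCENDING),
    ):
        border_edges[(last[src], first[dst])] = dst

    for (i, j), _cls in border_edges.items():
        row = s_mat[i]
        positive = row[row > 0]
        s_mat[i, j] = max(positive.mean() if positive.size else 1.0, s_mat[i, j])
    s_mat /= s_mat.sum(axis=1, keepdims=True)

    startprob = np.zeros(n)
    startprob[list(range(*offsets[TRANSITION]))] = 1.0
    for c in (LEVEL, ASCENDING, DESCENDING):
        startprob[first[c]] = 1.0
    startprob /= startprob.sum()

    state_class_map = []
    for name in order:
        state_class_map += [name] * subs[name].n_states

    weights = np.vstack([subs[name].weights for name in order])
    means = np.vstack([subs[name].means for name in order])
    covars = np.vstack([subs[name].covars for name in order])
    return SegmentationModel(
        transmat=s_mat,
        startprob=startprob,
        weights=weights,
        means=means,
        covars=covars,
        state_class_map=state_class_map,
        block_slices=offsets,
        border_edges=border_edges,
    )


def split_training_sequences(
    features: HmmFeatureMatrix,
    stride_borders: list[tuple[int, int]],
    labels: list[str],
    min_length: int = 2,
) -> dict[str, list[np.ndarray]]:
    """Slice a bout's features into per-class training sequences.

    Each annotated stride (borders in original-rate samples) becomes one
    training sequence for its class's sub-model — a left-right chain models
    exactly one stride; repeats arise only through the assembly edges.
    Everything outside stride regions goes to the transition model.
    """
    out: dict[str, list[np.ndarray]] = {TRANSITION: [], LEVEL: [], ASCENDING: [], DESCENDING: []}
    n = len(features)
    cursor = 0
    for (a, b), lab in zip(stride_borders, labels):
        fa, fb = a // DOWNSAMPLE_FACTOR, b // DOWNSAMPLE_FACTOR
        if fa - cursor >= min_length:
            out[TRANSITION].append(features.data[cursor:fa])
        if fb - fa >= min_length:
            out[lab].append(features.data[fa:fb])
        cursor = max(cursor, fb)
    if n - cursor >= min_length:
        out[TRANSITION].append(features.data[cursor:n])
    return out


def viterbi_path(model: SegmentationModel, features: HmmFeatureMatrix) -> np.ndarray:
    """Most likely hidden-state sequence for a bout (log-space Viterbi)."""
    hmm = _as_gmmhmm(model.startprob, model.transmat, model.weights, model.means, model.covars)
    _, path = hmm.decode(features.data, algorithm="viterbi")
    return path


def predict_stride_borders(
    model: SegmentationModel,
    features: HmmFeatureMatrix,
    seq: ImuSequence,
) -> StrideBorderSet:
    """Stride borders from border-edge crossings in the Viterbi path.

    Border positions are mapped back to the original rate (x downsampling
    factor) and snapped to the minimum of the raw gyr_ml within +-150 ms
    (clipped at the sequence edges); the per-stride class label of the
    sub-model traversed is retained for diagnostics.
    """
    path = viterbi_path(model, features)
    crossings = [
        t + 1 for t in range(len(path) - 1) if (int(path[t]), int(path[t + 1])) in model.border_edges
    ]
    half = int(round(BORDER_SNAP_HALF_WINDOW_S * seq.sampling_rate))
    gyr = seq.gyr_ml

    def snap(feature_idx: int) -> int:
        raw = min(feature_idx * DOWNSAMPLE_FACTOR, len(seq) - 1)
        lo = max(raw - half, 0)
        hi = min(raw + half + 1, len(seq))
        return lo + int(np.argmin(gyr[lo:hi]))

    strides: list[Stride] = []
    for b0, b1 in zip(crossings[:-1], crossings[1:]):
        classes = {model.state_class_map[int(s)] for s in path[b0:b1]}
        if classes == {TRANSITION} or len(classes) != 1:
            continue
        start, end = snap(b0), snap(b1)
        if start < end:
            strides.append(Stride(start=start, end=end, predicted_class=classes.pop()))
    return StrideBorderSet(strides=strides, stage="refined", sampling_rate=seq.sampling_rate)


def postprocess_strides(borders: StrideBorderSet, seq: ImuSequence) -> StrideBorderSet:
    """Eliminate implausible stride candidates.

    A valid stride has duration 0.4-2.5 s, a terminal-contact dip of at most
    -20 dps at its start border (within the snap window) and an in-stride
    swing maximum of at least +50 dps.
    """
    fs = seq.sampling_rate
    half = int(round(BORDER_SNAP_HALF_WINDOW_S * fs))
    gyr = seq.gyr_ml
    kept = []
    for s in borders.strides:
        duration = (s.end - s.start) / fs
        if not (MIN_STRIDE_DURATION_S <= duration <= MAX_STRIDE_DURATION_S):
            continue
        dip = gyr[max(s.start - half, 0) : min(s.start + half + 1, len(seq))].min()
        if dip > MIN_TC_DIP_DPS:
            continue
        if gyr[s.start : s.end].max() < MIN_SWING_PEAK_DPS:
            continue
        kept.append(s)
    return StrideBorderSet(strides=kept, stage="filtered", sampling_rate=fs)
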
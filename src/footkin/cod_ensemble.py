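"""CNN ensemble for change-of-direction detection, with post-processing.

The classifier is a small 1-D CNN over 0.7 s windows of the six selected
channels.  Its layer stack and parameter budget are fixed:

    BN -> Conv1D(32, k=3) -> BN -> Conv1D(64, k=3) -> Flatten -> BN
       -> Dense(24) -> BN -> Dropout -> Dense(12) -> BN -> Dense(2)

with the convolution running along the 6-channel axis and the 35 time
samples acting as input features, giving the shape chain
(6,35) -> (4,32) -> (2,64) -> 128 -> 24 -> 12 -> 2 and 13,946 parameters
(13,484 trainable, 462 batch-norm running statistics).

Eight networks form a leave-one-player-out ensemble: each member trains
with a different (non-test) player withheld.  At prediction time the
member event probabilities X_ij are averaged into AP, smoothed with a
centered moving average into WAP, compared per round against the dynamic
threshold 1.75 * mean(WAP), and finally detections spanning less than
0.1 s are discarded — this last repair is what removes the isolated
single-window false positives that raw rounded predictions exhibit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cod_data import (
    SplitSpec,
    WindowDataset,
    augment_minority,
    make_splits,
    normalize_dataset,
)
from .kick_detection import moving_average, score_detections

MIN_DETECTION_SPAN_S = 0.1
DYNAMIC_THRESHOLD_FACTOR = 1.75
WAP_SIZE_DEFAULT = 5
N_ENSEMBLE = 8


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one ensemble member."""

    input_shape: tuple[int, int] = (6, 35)
    conv_filters: tuple[int, int] = (32, 64)
    kernel: int = 3
    dense_widths: tuple[int, int, int] = (24, 12, 2)
    dropout: float = 0.5


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.2
    augment_target: float = 0.5
    seed: int = 0


@dataclass
class EnsembleModel:
    members: list[nn.Network]
    held_out: list[str]
    spec: NetworkSpec = field(default_factory=NetworkSpec)
    histories: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) != len(self.held_out):
            raise ValueError("one held-out player per member required")
        if len(set(self.held_out)) != len(self.held_out):
            raise ValueError("held-out players must be distinct")


@dataclass
class PredictionTrace:
    """Per-window ensemble outputs and final decisions for one series."""

    X: np.ndarray            # (members, J) per-member event probabilities
    AP: np.ndarray           # (J,) averaged prediction
    WAP: np.ndarray          # (J,) smoothed prediction
    threshold: np.ndarray    # (J,) per-window threshold (constant per round)
    decisions: np.ndarray    # (J,) binary after duration filtering
    detections: list[tuple[int, int]]  # half-open window-index intervals


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(spec: NetworkSpec = NetworkSpec(), seed: int = 0) -> nn.Network:
    """Construct the fixed-architecture window classifier.

    The input is a (channels, time) = (6, 35) window presented to the
    convolution as a length-6 sequence of 35-dimensional features; this
    orientation is what yields the (6,35)->(4,32)->(2,64) shape chain and
    the exact parameter budget above.
    """
    rng = np.random.default_rng(seed)
    L, C = spec.input_shape
    f1, f2 = spec.conv_filters
    d1, d2, d_out = spec.dense_widths
    layers: list[nn.Layer] = [nn.BatchNorm(C)]
    layers += [nn.Conv1D(C, f1, spec.kernel, rng), nn.ReLU(), nn.BatchNorm(f1)]
    layers += [nn.Conv1D(f1, f2, spec.kernel, rng), nn.ReLU(), nn.Flatten()]
    flat = (L - 2 * (spec.kernel - 1)) * f2
    if flat < 1:
        raise ValueError(
            f"inconsistent network spec: two kernel-{spec.kernel} convolutions "
            f"do not fit input length {L}")
    layers += [nn.BatchNorm(flat)]
    layers += [nn.Dense(flat, d1, rng), nn.ReLU(), nn.BatchNorm(d1)]
    layers += [nn.Dropout(spec.dropout, rng)]
    layers += [nn.Dense(d1, d2, rng), nn.ReLU(), nn.BatchNorm(d2)]
    layers += [nn.Dense(d2, d_out, rng)]
    try:
        return nn.Network(layers, (L, C))
    except ValueError as exc:
        raise ValueError(f"inconsistent network spec: {exc}") from exc


def count_parameters(network: nn.Network) -> dict:
    """Exact per-layer and total parameter counts.

    Batch-norm running statistics are the non-trainable parameters; a
    batch-norm layer therefore reports 4 parameters per feature.
    """
    per_layer = []
    trainable = non_trainable = 0
    for layer in network.layers:
        n_t, n_s = layer.n_trainable, layer.n_non_trainable
        if n_t or n_s:
            per_layer.append({"layer": layer.name, "params": n_t + n_s})
        trainable += n_t
        non_trainable += n_s
    return {
        "total": trainable + non_trainable,
        "trainable": trainable,
        "non_trainable": non_trainable,
        "per_layer": per_layer,
    }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_member(
    train: WindowDataset, val: WindowDataset,
    spec: NetworkSpec = NetworkSpec(),
    config: TrainConfig = TrainConfig(),
) -> tuple[nn.Network, dict]:
    """Train one ensemble member on already normalized subsets."""
    if len(train) == 0:
        raise ValueError("empty training set")
    network = build_network(spec, seed=config.seed)
    # windows are stored (channels, time); the network consumes (length=channels,
    # features=time) so the stored layout is already the conv layout
    history = nn.fit(
        network,
        train.data, train.label.astype(np.int64),
        val.data, val.label.astype(np.int64),
        lr=config.lr, batch_size=config.batch_size, epochs=config.epochs,
        patience=config.patience, seed=config.seed,
    )
    return network, history


def train_ensemble(
    dataset: WindowDataset,
    test_player: str,
    sigma: np.ndarray | float,
    spec: NetworkSpec = NetworkSpec(),
    config: TrainConfig = TrainConfig(),
) -> EnsembleModel:
    """Leave-one-player-out ensemble of 8 members.

    Member i trains on all windows except the test player's and except one
    further held-out player; its training subset is augmented to
    ``config.augment_target`` event fraction with noise sd ``sigma`` and
    z-scored independently of its validation subset.
    """
    players = sorted(set(dataset.player_id.tolist()))
    if test_player not in players:
        raise ValueError(f"unknown test player {test_player!r}")
    non_test = [p for p in players if p != test_player]
    if len(non_test) < N_ENSEMBLE:
        raise ValueError(
            f"need at least {N_ENSEMBLE + 1} players so {N_ENSEMBLE} remain "
            f"after holding out the test player (have {len(players)})")
    members, histories, held = [], [], []
    for i, holdout in enumerate(non_test[:N_ENSEMBLE]):
        member_seed = (config.seed * 1009 + 7 * i + 1) % (2 ** 31)
        sub = dataset.subset(dataset.player_id != test_player)
        # the inner split's "test" part is this member's held-out player;
        # it is simply not used for this member's training
        splits = make_splits(
            sub, SplitSpec(test_player=holdout, val_fraction=config.val_fraction,
                           seed=member_seed))
        train = augment_minority(splits["train"], sigma,
                                 config.augment_target, seed=member_seed)
        train, _ = normalize_dataset(train)
        val, _ = normalize_dataset(splits["val"])
        member_config = TrainConfig(
            lr=config.lr, batch_size=config.batch_size, epochs=config.epochs,
            patience=config.patience, val_fraction=config.val_fraction,
            augment_target=config.augment_target, seed=member_seed)
        net, hist = train_member(train, val, spec, member_config)
        members.append(net)
        histories.append(hist)
        held.append(holdout)
    return EnsembleModel(members, held, spec, histories)


# ---------------------------------------------------------------------------
# prediction post-processing
# ---------------------------------------------------------------------------

def predict_members(ensemble: EnsembleModel, data: np.ndarray) -> np.ndarray:
    """Per-member event probabilities X_ij, shape (members, J)."""
    return np.stack([m.predict_proba(data)[:, 1] for m in ensemble.members])


def predict_AP(ensemble: EnsembleModel, data: np.ndarray) -> np.ndarray:
    """Averaged prediction: the true mean of the 8 member probabilities."""
    return predict_members(ensemble, data).mean(axis=0)


def smooth_WAP(ap: np.ndarray, size: int = WAP_SIZE_DEFAULT) -> np.ndarray:
    """Centered moving average of AP (truncated at the boundaries)."""
    return moving_average(ap, size)


def dynamic_threshold(wap: np.ndarray,
                      factor: float = DYNAMIC_THRESHOLD_FACTOR) -> float:
    """threshold = 1.75 * mean(WAP) over the analyzed series."""
    wap = np.asarray(wap, dtype=float)
    if wap.size == 0:
        raise ValueError("empty WAP series")
    return float(factor * wap.mean())


def filter_short_detections(
    intervals: list[tuple[int, int]], fs_pred: float,
    min_span_s: float = MIN_DETECTION_SPAN_S,
) -> list[tuple[int, int]]:
    """Drop detections spanning less than ``min_span_s`` seconds.

    The span is measured between the first and last positive window
    centers, i.e. (run_length - 1) / fs_pred, so an isolated positive
    window always has span 0 and is removed.
    """
    if fs_pred <= 0:
        raise ValueError("fs_pred must be positive")
    return [(s, e) for s, e in intervals if (e - s - 1) / fs_pred >= min_span_s]


def decide_cod(
    wap: np.ndarray, threshold: float, fs_pred: float,
    min_span_s: float = MIN_DETECTION_SPAN_S,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Threshold WAP and duration-filter the resulting runs.

    Returns the post-filter binary decision series and the surviving
    detections as half-open window-index intervals.  Ties at exactly the
    threshold are non-events.
    """
    wap = np.asarray(wap, dtype=float)
    raw = wap > threshold
    padded = np.concatenate([[False], raw, [False]])
    edges = np.diff(padded.astype(np.int8))
    runs = list(zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)))
    detections = filter_short_detections(
        [(int(s), int(e)) for s, e in runs], fs_pred, min_span_s)
    decisions = np.zeros(len(wap), dtype=np.int8)
    for s, e in detections:
        decisions[s:e] = 1
    return decisions, detections


def predict_trace(
    ensemble: EnsembleModel,
    data: np.ndarray,
    fs_pred: float,
    wap_size: int = WAP_SIZE_DEFAULT,
    round_ids: np.ndarray | None = None,
) -> PredictionTrace:
    """Full post-processing chain over one window series.

    When ``round_ids`` is given, smoothing, thresholding and the duration
    filter run separately within each round; otherwise the whole series is
    treated as one round.
    """
    X = predict_members(ensemble, data)
    ap = X.mean(axis=0)
    J = len(ap)
    wap = np.empty(J)
    thr = np.empty(J)
    decisions = np.zeros(J, dtype=np.int8)
    detections: list[tuple[int, int]] = []
    if round_ids is None:
        round_ids = np.zeros(J, dtype=np.int64)
    round_ids = np.asarray(round_ids)
    for rid in np.unique(round_ids):
        idx = np.flatnonzero(round_ids == rid)
        w = smooth_WAP(ap[idx], wap_size)
        t = dynamic_threshold(w)
        d, det = decide_cod(w, t, fs_pred)
        wap[idx] = w
        thr[idx] = t
        decisions[idx] = d
        detections.extend((int(idx[s]), int(idx[e - 1]) + 1) for s, e in det)
    return PredictionTrace(X, ap, wap, thr, decisions, detections)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_windows(decisions: np.ndarray, labels: np.ndarray) -> dict:
    """Window-level event/no-event confusion matrix, rows normalized."""
    decisions = np.asarray(decisions).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if decisions.shape != labels.shape:
        raise ValueError("shape mismatch")
    tp = int(np.sum(decisions & labels))
    tn = int(np.sum(~decisions & ~labels))
    fp = int(np.sum(decisions & ~labels))
    fn = int(np.sum(~decisions & labels))
    counts = np.array([[tn, fp], [fn, tp]], dtype=float)  # rows: true class
    row_sums = counts.sum(axis=1, keepdims=True)
    matrix = np.divide(counts, row_sums, out=np.full_like(counts, np.nan),
                       where=row_sums > 0)
    total = tp + tn + fp + fn
    return {
        "counts": {"TP": tp, "TN": tn, "FP": fp, "FN": fn},
        "matrix": matrix,
        "accuracy": (tp + tn) / total if total else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def evaluate_events(
    detections: list[tuple[int, int]], truth: list[tuple[int, int]]
) -> dict:
    """Event-level overlap matching (greedy one-to-one)."""
    return score_detections(detections, truth)


# ---------------------------------------------------------------------------
# model bundle I/O
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, member in enumerate(ensemble.members):
        weights = member.get_weights()
        np.savez(directory / f"member_{k}.npz",
                 **{f"w{i}": w for i, w in enumerate(weights)})
    manifest = {
        "held_out": ensemble.held_out,
        "spec": {
            "input_shape": list(ensemble.spec.input_shape),
            "conv_filters": list(ensemble.spec.conv_filters),
            "kernel": ensemble.spec.kernel,
            "dense_widths": list(ensemble.spec.dense_widths),
            "dropout": ensemble.spec.dropout,
        },
        "n_members": len(ensemble.members),
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n")


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    s = manifest["spec"]
    spec = NetworkSpec(tuple(s["input_shape"]), tuple(s["conv_filters"]),
                       s["kernel"], tuple(s["dense_widths"]), s["dropout"])
    members = []
    for k in range(manifest["n_members"]):
        net = build_network(spec, seed=0)
        with np.load(directory / f"member_{k}.npz") as z:
            weights = [z[f"w{i}"] for i in range(len(z.files))]
        net.set_weights(weights)
        members.append(net)
    return EnsembleModel(members, manifest["held_out"], spec)
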
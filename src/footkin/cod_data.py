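"""Change-of-direction dataset construction.

A CoD test session is a sequence of rounds: an active circuit with two
CoDs (part A) followed by a walk back to the start (part B), with
stationary pauses in between.  Only part A carries information for the
classifier.  This module turns annotated sessions into a supervised
window dataset:

1. round segmentation — the significant-motion segmenter applied to a
   whole-body motion magnitude separates activity from pauses; activity
   segments are paired in order as (part A, part B) per round;
2. windowing — 0.7 s windows (35 samples at 50 Hz) over the six channels
   that move most during a CoD (gyroscope Y/Z and accelerometer Z, both
   feet), slid with a 3-sample stride (~91% overlap);
3. labeling — a window is positive when it covers at least 30% of some
   annotated CoD interval;
4. augmentation — positive windows are replicated with fresh Gaussian
   sensor noise (sd estimated from idle spans) until the positive
   fraction reaches ~50%, countering the natural ~10% imbalance;
5. normalization — each of train/validation/test is z-scored per channel
   with its own statistics, so no statistic crosses subset boundaries;
6. splitting — the test subset is one whole player; remaining rounds are
   shuffled and assigned 80/20 to train/validation at round granularity,
   so overlapping windows of one round never straddle subsets.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .kick_detection import MotionParams, extract_events, motion_intensity, moving_average
from .session_core import CHANNELS, SyncedSession

#: channels fed to the CoD classifier, in fixed order
COD_CHANNELS = ["left_gy", "left_gz", "left_az", "right_gy", "right_gz", "right_az"]

#: segmentation defaults: heavy smoothing, low threshold (the walk-back
#: part B must still register as activity, only true pauses may fall
#: below), and a 1 s duration floor to reject blips
SEGMENT_PARAMS = MotionParams(size=31, ratio=0.01, min_duration=1.0)

EVENT_FRACTION_MIN = 0.30  # window is positive if it covers >= 30% of an event


@dataclass(frozen=True)
class Round:
    player_id: str
    round_index: int
    part_a: tuple[int, int]  # half-open sample intervals
    part_b: tuple[int, int]


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and channel selection."""

    length_s: float = 0.7
    overlap: float = 0.9
    fs: float = 50.0
    channels: tuple[str, ...] = tuple(COD_CHANNELS)
    stride: int | None = None  # explicit stride overrides the overlap-derived one

    @property
    def length_samples(self) -> int:
        return round(self.length_s * self.fs)

    @property
    def stride_samples(self) -> int:
        if self.stride is not None:
            if self.stride < 1:
                raise ValueError("stride must be >= 1")
            return self.stride
        # 10% of 35 samples is 3.5; rounding down keeps the realized
        # overlap (32/35 ~ 91.4%) at or above the nominal 90%
        return max(1, math.floor(self.length_samples * (1.0 - self.overlap) + 1e-9))

    @property
    def prediction_rate(self) -> float:
        """Windows per second along a segment."""
        return self.fs / self.stride_samples


@dataclass(frozen=True)
class SplitSpec:
    test_player: str
    val_fraction: float = 0.2
    seed: int = 0


@dataclass
class WindowDataset:
    """Labeled windows with player/round provenance.

    data: (N, C, L) window tensor; label: (N,) in {0, 1};
    player_id / round_index / start: (N,) provenance arrays.
    """

    data: np.ndarray
    label: np.ndarray
    player_id: np.ndarray
    round_index: np.ndarray
    start: np.ndarray
    spec: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        n = len(self.data)
        for name in ("label", "player_id", "round_index", "start"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def event_fraction(self) -> float:
        return float(np.mean(self.label)) if len(self) else 0.0

    def subset(self, mask: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            self.data[mask], self.label[mask], self.player_id[mask],
            self.round_index[mask], self.start[mask], self.spec,
        )

    @staticmethod
    def concatenate(parts: list["WindowDataset"]) -> "WindowDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        return WindowDataset(
            np.concatenate([p.data for p in parts]),
            np.concatenate([p.label for p in parts]),
            np.concatenate([p.player_id for p in parts]),
            np.concatenate([p.round_index for p in parts]),
            np.concatenate([p.start for p in parts]),
            parts[0].spec,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path, data=self.data, label=self.label, player_id=self.player_id,
            round_index=self.round_index, start=self.start,
        )
        manifest = {
            "length_s": self.spec.length_s, "overlap": self.spec.overlap,
            "fs": self.spec.fs, "channels": list(self.spec.channels),
            "n_windows": len(self), "event_fraction": self.event_fraction,
        }
        path.with_suffix(".json").write_text(
            json.dumps(manifest, sort_keys=True, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WindowDataset":
        path = Path(path)
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in
                      ("data", "label", "player_id", "round_index", "start")}
        manifest_path = path.with_suffix(".json")
        spec = WindowSpec()
        if manifest_path.exists():
            m = json.loads(manifest_path.read_text())
            spec = WindowSpec(m["length_s"], m["overlap"], m["fs"],
                              tuple(m["channels"]))
        return cls(arrays["data"], arrays["label"], arrays["player_id"],
                   arrays["round_index"], arrays["start"], spec)


# ---------------------------------------------------------------------------
# round segmentation
# ---------------------------------------------------------------------------

def whole_body_motion(session: SyncedSession, size: int) -> np.ndarray:
    """Sum of smoothed, rectified motion intensity across all 12 channels."""
    total = np.zeros(len(session))
    for c in range(12):
        m = np.abs(motion_intensity(session.data[:, c]))
        total += moving_average(m, size)
    return total


def segment_rounds(
    session: SyncedSession, params: MotionParams = SEGMENT_PARAMS
) -> list[Round]:
    """Pair consecutive activity segments into (part A, part B) rounds."""
    motion = whole_body_motion(session, params.size)
    thr = float(np.mean(motion) * params.ratio)
    binary = (motion > thr).astype(np.int8)
    segments = extract_events(binary, session.fs, params.min_duration)
    if len(segments) % 2 == 1:
        warnings.warn(
            f"odd number of activity segments ({len(segments)}); "
            "dropping the unpaired trailing segment", stacklevel=2)
        segments = segments[:-1]
    rounds = []
    for k in range(0, len(segments), 2):
        a, b = segments[k], segments[k + 1]
        rounds.append(Round(session.session_id.user_id, k // 2,
                            a.interval, b.interval))
    return rounds


# ---------------------------------------------------------------------------
# windowing and labeling
# ---------------------------------------------------------------------------

def make_windows(segment_length: int, spec: WindowSpec = WindowSpec()) -> list[int]:
    """Start indices of all windows fully inside a segment of given length."""
    L, w, s = int(segment_length), spec.length_samples, spec.stride_samples
    if L < w:
        return []
    return list(range(0, L - w + 1, s))


def label_window(
    window: tuple[int, int],
    events: list[tuple[int, int]],
    min_fraction: float = EVENT_FRACTION_MIN,
) -> int:
    """1 iff the window covers at least ``min_fraction`` of some event."""
    ws, we = window
    for es, ee in events:
        if ee <= es:
            raise ValueError(f"zero-length event [{es}, {ee})")
        overlap = max(0, min(we, ee) - max(ws, es))
        if overlap / (ee - es) >= min_fraction:
            return 1
    return 0


def windows_from_rounds(
    session: SyncedSession,
    rounds: list[Round],
    event_intervals: list[tuple[int, int]],
    spec: WindowSpec = WindowSpec(),
) -> WindowDataset:
    """Window the part-A span of each round and label against CoD truth."""
    cols = [CHANNELS.index(c) for c in spec.channels]
    data, labels, players, rids, starts = [], [], [], [], []
    for rnd in rounds:
        a0, a1 = rnd.part_a
        for s in make_windows(a1 - a0, spec):
            abs_start = a0 + s
            w = session.data[abs_start:abs_start + spec.length_samples, cols].T
            data.append(w)
            labels.append(label_window(
                (abs_start, abs_start + spec.length_samples), event_intervals))
            players.append(rnd.player_id)
            rids.append(rnd.round_index)
            starts.append(abs_start)
    if not data:
        shape = (0, len(cols), spec.length_samples)
        return WindowDataset(np.empty(shape), np.empty(0, np.int8),
                             np.empty(0, "<U16"), np.empty(0, np.int64),
                             np.empty(0, np.int64), spec)
    return WindowDataset(
        np.stack(data), np.array(labels, np.int8),
        np.array(players, "<U16"), np.array(rids, np.int64),
        np.array(starts, np.int64), spec,
    )


# ---------------------------------------------------------------------------
# noise statistics and augmentation
# ---------------------------------------------------------------------------

def estimate_idle_sigma(
    session: SyncedSession,
    idle_intervals: list[tuple[int, int]],
    channels: list[str] | None = None,
    min_samples: int = 35,
) -> np.ndarray:
    """Per-channel sample standard deviation over stationary spans."""
    cols = ([CHANNELS.index(c) for c in channels] if channels
            else list(range(12)))
    chunks = [session.data[s:e, cols] for s, e in idle_intervals if e > s]
    if not chunks:
        raise ValueError("no idle data")
    stacked = np.concatenate(chunks)
    if len(stacked) < min_samples:
        raise ValueError(
            f"insufficient idle data: {len(stacked)} < {min_samples} samples")
    return np.std(stacked, axis=0, ddof=1)


def augment_minority(
    dataset: WindowDataset,
    sigma: np.ndarray | float,
    target_ratio: float = 0.5,
    seed: int = 0,
) -> WindowDataset:
    """Replicate event windows with fresh Gaussian noise until the event
    fraction reaches ``target_ratio``; originals are retained unchanged."""
    if not (0.0 < target_ratio < 1.0):
        raise ValueError("target_ratio must be in (0, 1)")
    event_idx = np.flatnonzero(dataset.label == 1)
    if len(event_idx) == 0:
        raise ValueError("no event windows to augment")
    n, e = len(dataset), len(event_idx)
    if e / n >= target_ratio:
        return dataset
    n_copies = math.ceil((target_ratio * n - e) / (1.0 - target_ratio))
    rng = np.random.default_rng(seed)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float).reshape(-1, 1),
                            dataset.data.shape[1:])
    src = event_idx[np.arange(n_copies) % e]
    noisy = dataset.data[src] + rng.normal(0.0, 1.0, (n_copies,) + dataset.data.shape[1:]) * sigma
    extra = WindowDataset(
        noisy, dataset.label[src], dataset.player_id[src],
        dataset.round_index[src], dataset.start[src], dataset.spec,
    )
    return WindowDataset.concatenate([dataset, extra])


# ---------------------------------------------------------------------------
# normalization and splits
# ---------------------------------------------------------------------------

def normalize_dataset(dataset: WindowDataset) -> tuple[WindowDataset, dict]:
    """Per-channel z-score using this dataset's own statistics."""
    if len(dataset) == 0:
        raise ValueError("empty subset")
    mean = dataset.data.mean(axis=(0, 2))
    std = dataset.data.std(axis=(0, 2))
    zero_var = np.flatnonzero(std == 0.0)
    safe = np.where(std == 0.0, 1.0, std)
    out = (dataset.data - mean[:, None]) / safe[:, None]
    stats = {"mean": mean, "std": std, "zero_variance": zero_var.tolist()}
    return replace(dataset, data=out), stats


def normalize_subsets(
    train: WindowDataset, val: WindowDataset, test: WindowDataset
) -> tuple[dict[str, WindowDataset], dict[str, dict]]:
    """Z-score each subset independently (no statistic crosses subsets)."""
    out, stats = {}, {}
    for name, ds in (("train", train), ("val", val), ("test", test)):
        out[name], stats[name] = normalize_dataset(ds)
    return out, stats


def make_splits(
    dataset: WindowDataset, spec: SplitSpec
) -> dict[str, WindowDataset]:
    """Player-held-out test split; round-granular 80/20 train/val split."""
    players = set(dataset.player_id.tolist())
    if spec.test_player not in players:
        raise ValueError(f"unknown test player {spec.test_player!r}")
    if len(players) < 2:
        raise ValueError("need at least 2 players")
    test_mask = dataset.player_id == spec.test_player
    rest = dataset.subset(~test_mask)
    keys = sorted({(p, int(r)) for p, r in
                   zip(rest.player_id.tolist(), rest.round_index.tolist())})
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(keys))
    n_val = max(1, round(spec.val_fraction * len(keys)))
    val_keys = {keys[i] for i in perm[:n_val]}
    val_mask = np.array([(p, int(r)) in val_keys for p, r in
                         zip(rest.player_id.tolist(), rest.round_index.tolist())])
    return {
        "train": rest.subset(~val_mask),
        "val": rest.subset(val_mask),
        "test": dataset.subset(test_mask),
    }
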
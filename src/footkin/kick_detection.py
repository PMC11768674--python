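"""Adaptive-threshold significant-motion detection.

Ball strikes (shots and passes) appear as short, large peaks on the
striking foot's Y-axis accelerometer.  Rather than thresholding the raw
peaks — fragile against rebounds — the detector works on a motion
intensity signal, the product of each sample with its first difference:

    M[i] = (x[i] - x[i-1]) * x[i]

M is rectified (a magnitude of motion), smoothed with a centered moving
average of odd length ``size``, and compared against an adaptive threshold

    threshold = mean(M_bar) * ratio

so the sensitivity scales with the session's overall motion level.  Maximal
runs of supra-threshold samples become events; events shorter than
``min_duration`` are discarded.  The same segmenter, applied to a
whole-body motion magnitude, separates active rounds from pauses in the
change-of-direction test (see :mod:`footkin.cod_data`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session_core import SyncedSession


@dataclass(frozen=True)
class MotionParams:
    """Tunables of the significant-motion detector.

    size
        moving-average window length in samples; odd so the window centers
        on the current sample.
    ratio
        dimensionless scale of the adaptive threshold.
    min_duration
        events shorter than this (seconds) are discarded.
    """

    size: int = 11
    ratio: float = 3.0
    min_duration: float = 0.2

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError(f"size must be an odd integer >= 1, got {self.size}")
        if self.ratio <= 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")
        if self.min_duration < 0:
            raise ValueError(f"min_duration must be >= 0, got {self.min_duration}")


@dataclass(frozen=True)
class MotionEvent:
    """A detected significant-motion interval, half-open in samples."""

    start: int
    end: int
    duration: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty event [{self.start}, {self.end})")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def motion_intensity(x: np.ndarray) -> np.ndarray:
    """M[i] = (x[i] - x[i-1]) * x[i]; M[0] = 0 (no predecessor)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D signal of length >= 2")
    m = np.empty_like(x)
    m[0] = 0.0
    m[1:] = np.diff(x) * x[1:]
    return m


def moving_average(m: np.ndarray, size: int) -> np.ndarray:
    """Centered moving mean of odd window ``size``.

    At the boundaries the window is truncated to valid indices and the
    divisor shrinks to the number of samples actually inside.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"size must be an odd integer >= 1, got {size}")
    m = np.asarray(m, dtype=float)
    if size == 1:
        return m.copy()
    half = size // 2
    csum = np.concatenate([[0.0], np.cumsum(m)])
    n = len(m)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def adaptive_threshold(m_bar: np.ndarray, ratio: float) -> float:
    """threshold = mean(M_bar) * ratio."""
    m_bar = np.asarray(m_bar, dtype=float)
    if m_bar.size == 0:
        raise ValueError("empty input")
    return float(np.mean(m_bar) * ratio)


def classify_significant(m_bar: np.ndarray, threshold: float) -> np.ndarray:
    """Binary series: 1 where M_bar strictly exceeds the threshold.

    Ties at exactly the threshold count as non-significant.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (np.asarray(m_bar, dtype=float) > threshold).astype(np.int8)


def extract_events(
    binary: np.ndarray, fs: float, min_duration: float, channel: str = ""
) -> list[MotionEvent]:
    """Maximal runs of 1s as half-open events, minimum-duration filtered."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    b = np.asarray(binary).astype(bool)
    padded = np.concatenate([[False], b, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    events = []
    for s, e in zip(starts, ends):
        duration = (e - s) / fs
        if duration >= min_duration:
            events.append(MotionEvent(int(s), int(e), duration, channel))
    return events


def significant_motion(
    x: np.ndarray, fs: float, params: MotionParams, channel: str = ""
) -> list[MotionEvent]:
    """Full pipeline on one channel: intensity → rectify → smooth → threshold."""
    m = np.abs(motion_intensity(x))
    m_bar = moving_average(m, params.size)
    thr = adaptive_threshold(m_bar, params.ratio)
    binary = classify_significant(m_bar, thr)
    return extract_events(binary, fs, params.min_duration, channel)


def detect_strikes(
    session: SyncedSession, foot: str, params: MotionParams | None = None
) -> list[MotionEvent]:
    """Detect ball-strike events on the striking foot's Y acceleration."""
    if foot not in ("left", "right"):
        raise ValueError(f"unknown foot {foot!r}")
    if session.session_id.test_type not in ("shot", "pass"):
        raise ValueError(
            f"strike detection applies to shot/pass sessions, "
            f"got {session.session_id.test_type!r}"
        )
    params = params or MotionParams()
    channel = f"{foot}_ay"
    return significant_motion(session.channel(channel), session.fs, params, channel)


def score_detections(
    events: list[MotionEvent] | list[tuple[int, int]],
    truth_intervals: list[tuple[int, int]],
) -> dict:
    """Event-level confusion counts by greedy one-to-one overlap matching.

    Each detection is matched to the unmatched truth interval it overlaps
    most; matched pairs are TP, leftover detections FP, leftover truths FN.
    """
    det = [e.interval if isinstance(e, MotionEvent) else tuple(e) for e in events]
    truth = [tuple(t) for t in truth_intervals]

    def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    matched: set[int] = set()
    tp = 0
    for d in det:
        best, best_ov = None, 0
        for k, tr in enumerate(truth):
            if k in matched:
                continue
            ov = overlap(d, tr)
            if ov > best_ov:
                best, best_ov = k, ov
        if best is not None:
            matched.add(best)
            tp += 1
    fp = len(det) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"TP": tp, "FP": fp, "FN": fn,
            "precision": precision, "recall": recall, "f1": f1}
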
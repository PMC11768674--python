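"""Sensor-stream data model, two-foot synchronization, and session I/O.

A recording session consists of two independent insole sensors (left and
right foot), each streaming 6-channel IMU packets (3-axis accelerometer in
g, 3-axis gyroscope in deg/s) at 50 Hz.  Every packet carries a sequence
number, which fixes its position on the sensor's own sample grid, and a
reception timestamp, which anchors that grid in absolute time.  Because the
two sensors have independent clocks and transport paths, their reception
times differ by a roughly constant offset; this module estimates that
offset from the first N packets of each stream, shifts one stream's time
base to match the other, and resamples both onto a shared 50 Hz grid.

Sessions are persisted locally: raw streams as NDJSON (one packet per
line), synchronized sessions as a CSV matrix plus a JSON sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FS_DEFAULT = 50.0
SAMPLE_PERIOD_DEFAULT = 0.02
N_SYNC_DEFAULT = 50  # packets averaged for the inter-foot offset (1 s of data)

#: fixed channel order of a synchronized session matrix
CHANNELS = [
    "left_ax", "left_ay", "left_az", "left_gx", "left_gy", "left_gz",
    "right_ax", "right_ay", "right_az", "right_gx", "right_gy", "right_gz",
]

TEST_TYPES = ("shot", "pass", "cod")


@dataclass(frozen=True)
class ImuPacket:
    """One 6-channel IMU sample with transport metadata."""

    seq: int
    recv_time: float  # reception instant, seconds
    ax: float = 0.0
    ay: float = 0.0
    az: float = 0.0
    gx: float = 0.0
    gy: float = 0.0
    gz: float = 0.0

    def __post_init__(self) -> None:
        if self.seq < 0:
            raise ValueError(f"negative sequence number {self.seq}")
        if not math.isfinite(self.recv_time):
            raise ValueError("non-finite reception time")

    @property
    def values(self) -> np.ndarray:
        return np.array([self.ax, self.ay, self.az, self.gx, self.gy, self.gz])


@dataclass
class SensorStream:
    """An ordered per-foot packet sequence; gaps in seq mark lost packets."""

    foot: str  # "left" or "right"
    packets: list[ImuPacket]
    sample_period: float = SAMPLE_PERIOD_DEFAULT

    def __post_init__(self) -> None:
        if self.foot not in ("left", "right"):
            raise ValueError(f"unknown foot {self.foot!r}")
        self.packets = sorted(self.packets, key=lambda p: p.seq)
        seqs = [p.seq for p in self.packets]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate sequence numbers in stream")

    def __len__(self) -> int:
        return len(self.packets)

    @property
    def seqs(self) -> np.ndarray:
        return np.array([p.seq for p in self.packets], dtype=np.int64)

    @property
    def recv_times(self) -> np.ndarray:
        return np.array([p.recv_time for p in self.packets])


@dataclass(frozen=True)
class SessionId:
    user_id: str
    test_type: str
    created_at: str

    def __post_init__(self) -> None:
        if self.test_type not in TEST_TYPES:
            raise ValueError(
                f"test_type must be one of {TEST_TYPES}, got {self.test_type!r}"
            )


@dataclass
class SyncedSession:
    """Two-foot 12-channel data on one uniform time base.

    ``data`` is a T x 12 matrix in :data:`CHANNELS` order.  ``gap_mask`` is
    true at samples where at least one foot's packet was missing and the
    value was filled by previous-sample hold.
    """

    session_id: SessionId
    t: np.ndarray
    data: np.ndarray
    gap_mask: np.ndarray
    offset_applied: float
    fs: float = FS_DEFAULT

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.data.shape != (len(self.t), 12):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with {len(self.t)} samples"
            )
        if len(self.gap_mask) != len(self.t):
            raise ValueError("gap_mask length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]


# ---------------------------------------------------------------------------
# gap detection and offset estimation
# ---------------------------------------------------------------------------

def detect_gaps(stream: SensorStream) -> list[tuple[int, int]]:
    """Missing-seq intervals ``[a, b)`` inside the observed seq range.

    Only gaps strictly between the stream's minimum and maximum sequence
    number count: nothing is known about packets outside the observed range.
    """
    if len(stream) == 0:
        raise ValueError("empty stream")
    seqs = stream.seqs
    gaps: list[tuple[int, int]] = []
    for prev, cur in zip(seqs[:-1], seqs[1:]):
        if cur > prev + 1:
            gaps.append((int(prev) + 1, int(cur)))
    return gaps


def estimate_offset(
    stream_a: SensorStream, stream_b: SensorStream, n_samples: int = N_SYNC_DEFAULT
) -> float:
    """Mean reception-time difference over the first ``n_samples`` packets.

    Packets are matched by rank (k-th received vs k-th received).  A
    positive result means ``stream_a`` received later than ``stream_b``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(stream_a) < n_samples or len(stream_b) < n_samples:
        raise ValueError(
            f"need at least {n_samples} packets in both streams "
            f"(have {len(stream_a)} and {len(stream_b)})"
        )
    diff = stream_a.recv_times[:n_samples] - stream_b.recv_times[:n_samples]
    return float(np.mean(diff))


def _anchor_offset(stream_a: SensorStream, stream_b: SensorStream, n: int) -> float:
    """Seq-corrected clock-offset estimate used by :func:`synchronize`.

    Each reception time is first reduced to the stream's clock anchor,
    recv - (seq - seq0) * period, so a packet lost inside the averaging
    window does not misalign ranks; with gapless streams this reduces
    exactly to the rank-matched mean of :func:`estimate_offset`.
    """
    def anchor(stream: SensorStream) -> float:
        seqs = stream.seqs[:n]
        times = stream.recv_times[:n]
        return float(np.mean(times - (seqs - seqs[0]) * stream.sample_period))

    return anchor(stream_a) - anchor(stream_b)


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def _grid_series(
    stream: SensorStream, start_time: float, grid_t0: float, n_grid: int
) -> tuple[np.ndarray, np.ndarray]:
    """Place a stream's packets on the common grid by nearest sample.

    Returns the T x 6 channel matrix (gaps filled by previous-sample hold,
    leading gaps by first valid sample) and the fill mask.
    """
    period = stream.sample_period
    seq0 = stream.packets[0].seq
    out = np.full((n_grid, 6), np.nan)
    for p in stream.packets:
        t_abs = start_time + (p.seq - seq0) * period
        idx = round((t_abs - grid_t0) / period)
        if 0 <= idx < n_grid:
            out[idx] = p.values
    mask = np.isnan(out[:, 0])
    # previous-sample hold; back-fill any leading gap
    last = None
    first_valid = int(np.flatnonzero(~mask)[0])
    for i in range(n_grid):
        if mask[i]:
            out[i] = out[first_valid] if last is None else last
        else:
            last = out[i]
    return out, mask


def synchronize(
    stream_left: SensorStream,
    stream_right: SensorStream,
    n_samples: int = N_SYNC_DEFAULT,
    session_id: SessionId | None = None,
) -> SyncedSession:
    """Align two per-foot streams onto one 50 Hz grid.

    The inter-sensor offset is estimated from the first ``n_samples``
    rank-matched reception times and subtracted from the later stream's
    time base; both streams are then resampled onto a common grid by
    nearest-sample assignment.  Lost packets are filled by previous-sample
    hold and flagged in ``gap_mask``.
    """
    if len(stream_left) == 0 or len(stream_right) == 0:
        raise ValueError("empty stream")
    n = min(n_samples, len(stream_left), len(stream_right))
    offset = _anchor_offset(stream_right, stream_left, n)  # >0: right later
    period = stream_left.sample_period

    start_l = stream_left.packets[0].recv_time
    start_r = stream_right.packets[0].recv_time - offset
    dur_l = (stream_left.packets[-1].seq - stream_left.packets[0].seq) * period
    dur_r = (stream_right.packets[-1].seq - stream_right.packets[0].seq) * period

    t_begin = max(start_l, start_r)
    t_end = min(start_l + dur_l, start_r + dur_r)
    if t_end < t_begin:
        raise ValueError("disjoint streams: no temporal overlap after offset")

    grid_origin = min(start_l, start_r)  # 0-based at the earlier stream's start
    i0 = round((t_begin - grid_origin) / period)
    n_grid = round((t_end - t_begin) / period) + 1
    grid_t0 = grid_origin + i0 * period

    left_mat, left_mask = _grid_series(stream_left, start_l, grid_t0, n_grid)
    right_mat, right_mask = _grid_series(stream_right, start_r, grid_t0, n_grid)

    t = (np.arange(n_grid) + i0) * period
    data = np.hstack([left_mat, right_mat])
    gap_mask = left_mask | right_mask
    sid = session_id or SessionId("unknown", "shot", "1970-01-01T00:00:00Z")
    return SyncedSession(
        session_id=sid, t=t, data=data, gap_mask=gap_mask,
        offset_applied=offset, fs=1.0 / period,
    )


# ---------------------------------------------------------------------------
# stream I/O (NDJSON) and session I/O (CSV + JSON sidecar)
# ---------------------------------------------------------------------------

def write_stream(stream: SensorStream, path: str | Path) -> None:
    """NDJSON: header line, then one packet per line."""
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "foot": stream.foot,
            "fs": 1.0 / stream.sample_period,
            "units": {"a": "g", "g": "deg/s"},
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for p in stream.packets:
            rec = {
                "seq": p.seq,
                "recv_time": p.recv_time,
                "a": [p.ax, p.ay, p.az],
                "g": [p.gx, p.gy, p.gz],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_stream(path: str | Path) -> SensorStream:
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty stream file")
    try:
        header = json.loads(lines[0])
        foot = header["foot"]
        fs = float(header["fs"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path}: line 1: malformed header ({exc})") from exc
    packets = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            a, g = rec["a"], rec["g"]
            packets.append(
                ImuPacket(
                    seq=int(rec["seq"]), recv_time=float(rec["recv_time"]),
                    ax=a[0], ay=a[1], az=a[2], gx=g[0], gy=g[1], gz=g[2],
                )
            )
        except (json.JSONDecodeError, KeyError, IndexError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: malformed packet record ({exc})") from exc
    return SensorStream(foot=foot, packets=packets, sample_period=1.0 / fs)


def write_session(session: SyncedSession, path: str | Path) -> None:
    """CSV matrix (t, 12 channels, gap_mask) plus a ``.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(session.data, columns=CHANNELS)
    df.insert(0, "t", session.t)
    df["gap_mask"] = session.gap_mask.astype(int)
    # 17 significant digits guarantee a bit-exact float64 round trip
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "user_id": session.session_id.user_id,
        "test_type": session.session_id.test_type,
        "created_at": session.session_id.created_at,
        "offset_applied": session.offset_applied,
        "fs": session.fs,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=2) + "\n"
    )


def read_session(path: str | Path) -> SyncedSession:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parse error types
        raise ValueError(f"{path}: malformed session file ({exc})") from exc
    required = ["t"] + CHANNELS + ["gap_mask"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[required].isna().any().any():
        bad = int(df[required].isna().any(axis=1).idxmax()) + 2  # header + 1-base
        raise ValueError(f"{path}: line {bad}: truncated or non-numeric record")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:
        meta = {"user_id": "unknown", "test_type": "shot",
                "created_at": "1970-01-01T00:00:00Z", "offset_applied": 0.0, "fs": 50.0}
    return SyncedSession(
        session_id=SessionId(meta["user_id"], meta["test_type"], meta["created_at"]),
        t=df["t"].to_numpy(),
        data=df[CHANNELS].to_numpy(),
        gap_mask=df["gap_mask"].to_numpy().astype(bool),
        offset_applied=float(meta["offset_applied"]),
        fs=float(meta["fs"]),
    )
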
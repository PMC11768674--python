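"""Deterministic synthetic two-foot IMU sessions with ground truth.

The generator emulates the three field-test protocols — set shots, passes,
and a change-of-direction (CoD) circuit — as they present themselves to a
pair of 50 Hz insole IMUs, so that every processing stage can be developed
and tested without access to recordings of real players:

* idle noise when the player stands still;
* sinusoidal stride oscillation while running (strong on the gyroscope
  Y/Z axes, weaker on the accelerometer) and a slower, smaller version
  while walking back;
* ball strikes as large half-sine pulses on the striking foot's Y
  accelerometer, far exceeding the running oscillation;
* CoDs as intervals where the support foot goes still (its stride
  oscillation collapses to idle noise) while the swing foot produces a
  gyroscope transient;
* round structure: each repetition has an active part A and a walk-back
  part B, separated by stationary pauses;
* the transport layer: per-packet sequence numbers, reception timestamps
  with a constant inter-foot clock offset plus jitter, and i.i.d. packet
  loss.

Everything is driven by one seed; identical configs produce identical
sessions.  Waveform shapes are stylized — the point is that the signatures
the detectors key on (strike peaks, support-foot immobility, A/B pauses)
hold by construction, with realistic amplitudes and noise floors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .session_core import (
    CHANNELS,
    ImuPacket,
    SensorStream,
    SessionId,
    SyncedSession,
)

# channel-index shorthands into the 12-column session matrix
_L_AX, _L_AY, _L_AZ, _L_GX, _L_GY, _L_GZ = range(6)
_R_AX, _R_AY, _R_AZ, _R_GX, _R_GY, _R_GZ = range(6, 12)
_ACCEL_COLS = [0, 1, 2, 6, 7, 8]
_GYRO_COLS = [3, 4, 5, 9, 10, 11]


@dataclass(frozen=True)
class GeneratorConfig:
    """Session-generator parameters (units in comments)."""

    fs: float = 50.0                 # Hz
    n_players: int = 9
    reps_per_test: int = 30
    idle_sigma_accel: float = 0.02   # g, noise sd of stationary accelerometer
    idle_sigma_gyro: float = 1.0     # deg/s, noise sd of stationary gyroscope
    strike_amp: float = 8.0          # g, peak of the ball-strike pulse
    strike_width: float = 0.15       # s, width of the half-sine strike pulse
    run_amp_accel: float = 0.5       # g, stride oscillation on the accelerometer
    run_amp_gyro: float = 100.0      # deg/s, stride oscillation on the gyroscope
    cod_immobility: float = 0.4      # s, support-foot stillness during a CoD
    cod_transient_amp: float = 250.0  # deg/s, swing-foot gyro transient at a CoD
    stride_freq: float = 3.0         # Hz, running cadence
    sync_offset: float = 0.037       # s, right-sensor clock lag vs left
    jitter_sd: float = 0.002         # s, reception-time jitter
    packet_loss: float = 0.002       # i.i.d. drop probability per packet
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.packet_loss < 1.0):
            raise ValueError("packet_loss must be in [0, 1)")
        for name in ("fs", "stride_freq", "strike_width", "cod_immobility"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TruthEvent:
    type: str          # "strike" or "cod"
    foot: str          # striking foot / support foot
    start: int         # half-open sample interval on the session grid
    end: int


@dataclass(frozen=True)
class TruthRound:
    part_a: tuple[int, int]
    part_b: tuple[int, int]


@dataclass
class GroundTruth:
    """Planted event, round, and idle intervals of a generated session."""

    events: list[TruthEvent] = field(default_factory=list)
    rounds: list[TruthRound] = field(default_factory=list)
    idle: list[tuple[int, int]] = field(default_factory=list)

    def event_intervals(self, type: str | None = None) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.events
                if type is None or e.type == type]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": [vars(e) for e in self.events],
            "rounds": [{"part_a": list(r.part_a), "part_b": list(r.part_b)}
                       for r in self.rounds],
            "idle": [list(iv) for iv in self.idle],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            events=[TruthEvent(**e) for e in payload["events"]],
            rounds=[TruthRound(tuple(r["part_a"]), tuple(r["part_b"]))
                    for r in payload["rounds"]],
            idle=[tuple(iv) for iv in payload["idle"]],
        )


# ---------------------------------------------------------------------------
# waveform building blocks (each returns an n x 12 matrix on the grid)
# ---------------------------------------------------------------------------

def _noise(n: int, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.empty((n, 12))
    out[:, _ACCEL_COLS] = rng.normal(0.0, config.idle_sigma_accel, (n, 6))
    out[:, _GYRO_COLS] = rng.normal(0.0, config.idle_sigma_gyro, (n, 6))
    return out


def gen_idle(duration: float, config: GeneratorConfig,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Stationary two-foot segment: zero-mean idle noise per channel."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng or np.random.default_rng(config.seed)
    return _noise(round(duration * config.fs), config, rng)


def _stride(n: int, config: GeneratorConfig, rng: np.random.Generator,
            amp_scale: float = 1.0, freq_scale: float = 1.0,
            feet: tuple[bool, bool] = (True, True)) -> np.ndarray:
    """Running/walking oscillation; the two feet move in antiphase."""
    seg = _noise(n, config, rng)
    t = np.arange(n) / config.fs
    w = 2 * np.pi * config.stride_freq * freq_scale
    a_amp = config.run_amp_accel * amp_scale
    g_amp = config.run_amp_gyro * amp_scale
    for foot, phase in ((0, 0.0), (1, np.pi)):
        if not feet[foot]:
            continue
        off = 6 * foot
        seg[:, off + 1] += a_amp * np.sin(w * t + phase)             # ay
        seg[:, off + 2] += 0.6 * a_amp * np.abs(np.sin(w * t + phase))  # az
        seg[:, off + 4] += g_amp * np.sin(w * t + phase)             # gy
        seg[:, off + 5] += 0.8 * g_amp * np.cos(w * t + phase)       # gz
    return seg


def _strike_pulse(config: GeneratorConfig, amp: float) -> np.ndarray:
    n = max(2, round(config.strike_width * config.fs))
    return amp * np.sin(np.pi * np.arange(n) / (n - 1))


def _cod_segment(config: GeneratorConfig, rng: np.random.Generator,
                 support_foot: str) -> np.ndarray:
    """Support foot still (idle noise), swing foot gyro transient."""
    n = round(config.cod_immobility * config.fs)
    seg = _noise(n, config, rng)
    swing = 6 if support_foot == "left" else 0
    pulse = config.cod_transient_amp * np.sin(np.pi * np.arange(n) / (n - 1))
    seg[:, swing + 4] += pulse                 # swing gy
    seg[:, swing + 5] += 0.7 * pulse           # swing gz
    seg[:, swing + 2] += 0.3 * np.abs(np.sin(  # swing az push-off
        2 * np.pi * config.stride_freq * np.arange(n) / config.fs))
    return seg


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

class _SessionBuilder:
    def __init__(self) -> None:
        self.parts: list[np.ndarray] = []
        self.n = 0

    def add(self, seg: np.ndarray) -> tuple[int, int]:
        start = self.n
        self.parts.append(seg)
        self.n += len(seg)
        return (start, self.n)

    def matrix(self) -> np.ndarray:
        return np.vstack(self.parts)


def _kick_session_matrix(
    config: GeneratorConfig, foot: str, amp: float, rng: np.random.Generator
) -> tuple[np.ndarray, GroundTruth]:
    b = _SessionBuilder()
    truth = GroundTruth()
    truth.idle.append(b.add(gen_idle(1.0, config, rng)))
    pad = round(0.08 * config.fs)  # plant-to-contact margin around the pulse
    col = _L_AY if foot == "left" else _R_AY
    for _ in range(config.reps_per_test):
        b.add(_stride(round(1.2 * config.fs), config, rng))
        pulse = _strike_pulse(config, amp)
        seg = _stride(len(pulse), config, rng, amp_scale=0.3)
        seg[:, col] += pulse
        s, e = b.add(seg)
        truth.events.append(
            TruthEvent("strike", foot, max(0, s - pad), e + pad)
        )
        truth.idle.append(b.add(gen_idle(0.6, config, rng)))
        b.add(_stride(round(1.5 * config.fs), config, rng,
                      amp_scale=0.25, freq_scale=0.6))
        truth.idle.append(b.add(gen_idle(0.5, config, rng)))
    return b.matrix(), truth


def _cod_session_matrix(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, GroundTruth]:
    b = _SessionBuilder()
    truth = GroundTruth()
    truth.idle.append(b.add(gen_idle(1.5, config, rng)))
    for _ in range(config.reps_per_test):
        a_start = b.n
        b.add(_stride(round(6.0 * config.fs), config, rng))
        s, e = b.add(_cod_segment(config, rng, support_foot="right"))
        truth.events.append(TruthEvent("cod", "right", s, e))
        b.add(_stride(round(6.0 * config.fs), config, rng))
        s, e = b.add(_cod_segment(config, rng, support_foot="left"))
        truth.events.append(TruthEvent("cod", "left", s, e))
        b.add(_stride(round(4.0 * config.fs), config, rng))
        a_end = b.n
        truth.idle.append(b.add(gen_idle(1.0, config, rng)))
        b_start = b.n
        b.add(_stride(round(3.0 * config.fs), config, rng,
                      amp_scale=0.25, freq_scale=0.6))
        b_end = b.n
        truth.idle.append(b.add(gen_idle(1.0, config, rng)))
        truth.rounds.append(TruthRound((a_start, a_end), (b_start, b_end)))
    return b.matrix(), truth


# ---------------------------------------------------------------------------
# transport emulation
# ---------------------------------------------------------------------------

def inject_transport(
    matrix: np.ndarray, config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SensorStream, SensorStream]:
    """Turn a grid-sampled session matrix into two per-foot packet streams.

    Sequence numbers follow the grid index; reception time is the sample
    time plus jitter, plus the inter-foot clock offset on the right foot;
    packets are dropped i.i.d. with probability ``packet_loss``.
    """
    rng = rng or np.random.default_rng(config.seed)
    period = 1.0 / config.fs
    streams = []
    for foot, cols, clock in (("left", slice(0, 6), 0.0),
                              ("right", slice(6, 12), config.sync_offset)):
        n = len(matrix)
        jitter = rng.normal(0.0, config.jitter_sd, n) if config.jitter_sd > 0 else np.zeros(n)
        keep = rng.random(n) >= config.packet_loss
        packets = [
            ImuPacket(seq=i, recv_time=i * period + clock + jitter[i],
                      ax=row[0], ay=row[1], az=row[2],
                      gx=row[3], gy=row[4], gz=row[5])
            for i, row in enumerate(matrix[:, cols])
            if keep[i]
        ]
        streams.append(SensorStream(foot=foot, packets=packets, sample_period=period))
    return streams[0], streams[1]


# ---------------------------------------------------------------------------
# public session generators
# ---------------------------------------------------------------------------

def gen_shot_session(
    config: GeneratorConfig, foot: str = "right", user_id: str = "P0"
) -> tuple[SensorStream, SensorStream, GroundTruth]:
    """A set-shot session: ``reps_per_test`` strike repetitions."""
    rng = np.random.default_rng(config.seed)
    matrix, truth = _kick_session_matrix(config, foot, config.strike_amp, rng)
    left, right = inject_transport(matrix, config, rng)
    return left, right, truth


def gen_pass_session(
    config: GeneratorConfig, foot: str = "right", user_id: str = "P0"
) -> tuple[SensorStream, SensorStream, GroundTruth]:
    """A passing session: like shots but with lower strike amplitude."""
    rng = np.random.default_rng(config.seed)
    matrix, truth = _kick_session_matrix(config, foot, 0.6 * config.strike_amp, rng)
    left, right = inject_transport(matrix, config, rng)
    return left, right, truth


def gen_cod_session(
    config: GeneratorConfig, user_id: str = "P0"
) -> tuple[SensorStream, SensorStream, GroundTruth]:
    """A CoD circuit session: per round, run / left CoD / run / right CoD /
    run-out (part A), pause, walk-back (part B), pause."""
    rng = np.random.default_rng(config.seed)
    matrix, truth = _cod_session_matrix(config, rng)
    left, right = inject_transport(matrix, config, rng)
    return left, right, truth


def session_matrix(
    config: GeneratorConfig, test_type: str, foot: str = "right"
) -> tuple[np.ndarray, GroundTruth]:
    """The noiseless-transport view: the 12-channel grid matrix + truth.

    Convenient for tests that need the signal exactly on the sample grid
    without the packet/transport layer.
    """
    rng = np.random.default_rng(config.seed)
    if test_type == "shot":
        return _kick_session_matrix(config, foot, config.strike_amp, rng)
    if test_type == "pass":
        return _kick_session_matrix(config, foot, 0.6 * config.strike_amp, rng)
    if test_type == "cod":
        return _cod_session_matrix(config, rng)
    raise ValueError(f"unknown test_type {test_type!r}")


def matrix_as_session(
    matrix: np.ndarray, config: GeneratorConfig, test_type: str,
    user_id: str = "P0",
) -> SyncedSession:
    """Wrap a grid matrix directly as a synchronized session (no transport)."""
    n = len(matrix)
    return SyncedSession(
        session_id=SessionId(user_id, test_type, "1970-01-01T00:00:00Z"),
        t=np.arange(n) / config.fs,
        data=matrix,
        gap_mask=np.zeros(n, dtype=bool),
        offset_applied=0.0,
        fs=config.fs,
    )
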
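"""Shared fixtures: small synthetic sessions built once per test module."""

import numpy as np
import pytest

from footkin import cod_data
from footkin.session_core import ImuPacket, SensorStream
from footkin.synthetic_data import GeneratorConfig, matrix_as_session, session_matrix


def make_stream(foot="left", n=100, start_seq=0, shift=0.0, values=None,
                missing=(), period=0.02):
    """A jitter-free stream on a clean grid, optionally shifted/perforated."""
    packets = []
    for k in range(n):
        seq = start_seq + k
        if seq in missing:
            continue
        v = 0.0 if values is None else float(values[k])
        packets.append(ImuPacket(seq=seq, recv_time=seq * period + shift, ay=v))
    return SensorStream(foot=foot, packets=packets, sample_period=period)


@pytest.fixture(scope="session")
def cod_session_small():
    """A 3-round CoD session on the clean grid, with its ground truth."""
    config = GeneratorConfig(seed=11, reps_per_test=3)
    matrix, truth = session_matrix(config, "cod")
    session = matrix_as_session(matrix, config, "cod", user_id="P0")
    return session, truth, config


@pytest.fixture(scope="session")
def cod_dataset_small(cod_session_small):
    """Labeled windows of the 3-round session plus idle-noise sigma."""
    session, truth, _ = cod_session_small
    rounds = [cod_data.Round("P0", k, r.part_a, r.part_b)
              for k, r in enumerate(truth.rounds)]
    dataset = cod_data.windows_from_rounds(
        session, rounds, truth.event_intervals("cod"))
    sigma = cod_data.estimate_idle_sigma(
        session, truth.idle, channels=list(cod_data.COD_CHANNELS))
    return dataset, sigma


@pytest.fixture(scope="session")
def multiplayer_dataset():
    """A 4-player, 2-rounds-each window dataset (for split/ensemble plumbing)."""
    parts = []
    for k in range(4):
        config = GeneratorConfig(seed=500 + k, reps_per_test=2)
        matrix, truth = session_matrix(config, "cod")
        session = matrix_as_session(matrix, config, "cod", user_id=f"P{k}")
        rounds = [cod_data.Round(f"P{k}", i, r.part_a, r.part_b)
                  for i, r in enumerate(truth.rounds)]
        parts.append(cod_data.windows_from_rounds(
            session, rounds, truth.event_intervals("cod")))
    return cod_data.WindowDataset.concatenate(parts)
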
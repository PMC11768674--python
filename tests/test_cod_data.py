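"""Round segmentation, windowing, labeling, augmentation, normalization,
and player-held-out splitting."""

import numpy as np
import pytest

from footkin import cod_data
from footkin.cod_data import (
    SplitSpec,
    WindowDataset,
    WindowSpec,
    augment_minority,
    estimate_idle_sigma,
    label_window,
    make_splits,
    make_windows,
    normalize_dataset,
    normalize_subsets,
    segment_rounds,
    windows_from_rounds,
)
from footkin.session_core import SessionId, SyncedSession
from footkin.synthetic_data import GeneratorConfig, gen_idle, matrix_as_session


def idle_session(n_samples=300, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, sigma, (n_samples, 12)) if sigma else np.zeros((n_samples, 12))
    return SyncedSession(SessionId("P0", "cod", "t"), np.arange(n_samples) / 50.0,
                         data, np.zeros(n_samples, bool), 0.0)


def toy_dataset(n_event, n_nonevent, seed=0, n_players=1):
    rng = np.random.default_rng(seed)
    n = n_event + n_nonevent
    labels = np.array([1] * n_event + [0] * n_nonevent, np.int8)
    players = np.array([f"P{i % n_players}" for i in range(n)], "<U16")
    return WindowDataset(
        rng.normal(size=(n, 6, 35)), labels, players,
        np.arange(n, dtype=np.int64), np.arange(n, dtype=np.int64) * 3,
    )


class TestSegmentRounds:
    def test_generator_rounds_recovered(self, cod_session_small):
        session, truth, _ = cod_session_small
        rounds = segment_rounds(session)
        assert len(rounds) == len(truth.rounds) == 3
        for detected, planted in zip(rounds, truth.rounds):
            a0, a1 = detected.part_a
            t0, t1 = planted.part_a
            overlap = max(0, min(a1, t1) - max(a0, t0))
            assert overlap >= 0.9 * (t1 - t0)
            assert detected.part_a[1] <= detected.part_b[0]

    def test_idle_only_session_no_rounds(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            assert segment_rounds(idle_session(2000, sigma=0.01)) == []

    def test_odd_segment_count_warns_and_drops(self, cod_session_small):
        session, truth, _ = cod_session_small
        # truncate mid part-B of the last round: its A remains unpaired
        cut = truth.rounds[-1].part_b[0] - 10
        clipped = SyncedSession(session.session_id, session.t[:cut],
                                session.data[:cut], session.gap_mask[:cut], 0.0)
        with pytest.warns(UserWarning, match="odd number"):
            rounds = segment_rounds(clipped)
        assert len(rounds) == 2


class TestMakeWindows:
    @pytest.mark.parametrize("length,expected", [
        (35, [0]),
        (41, [0, 3, 6]),
        (34, []),
        (38, [0, 3]),
    ])
    def test_start_indices(self, length, expected):
        assert make_windows(length) == expected

    def test_matches_enumeration_oracle(self):
        # exhaustive check of floor((L-35)/s)+1 against direct enumeration
        for stride in range(1, 11):
            spec = WindowSpec(stride=stride)
            assert spec.stride_samples == stride
            for L in range(1, 500):
                starts = make_windows(L, spec)
                oracle = [s for s in range(0, L, stride) if s + 35 <= L]
                assert starts == oracle

    def test_realized_overlap_at_least_nominal(self):
        spec = WindowSpec()
        assert spec.length_samples == 35
        assert spec.stride_samples == 3
        realized = (spec.length_samples - spec.stride_samples) / spec.length_samples
        assert realized >= spec.overlap


class TestLabelWindow:
    def test_window_containing_event(self):
        assert label_window((0, 35), [(10, 20)]) == 1

    def test_exact_thirty_percent_boundary_inclusive(self):
        # 6 of 20 event samples covered = exactly 30%
        assert label_window((0, 6), [(0, 20)]) == 1

    def test_below_thirty_percent(self):
        assert label_window((0, 5), [(0, 20)]) == 0

    def test_just_under_boundary(self):
        assert label_window((0, 29999), [(0, 100000)]) == 0
        assert label_window((0, 30000), [(0, 100000)]) == 1

    def test_zero_length_event_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            label_window((0, 35), [(5, 5)])

    def test_monotone_in_overlap(self):
        # growing the window's overlap with an event never flips 1 -> 0
        event = [(50, 70)]
        prev = 0
        for end in range(40, 90):
            lab = label_window((30, end), event)
            assert lab >= prev
            prev = lab


class TestIdleSigma:
    def test_constant_idle_zero_sigma(self):
        session = idle_session(300, sigma=0.0)
        np.testing.assert_array_equal(
            estimate_idle_sigma(session, [(0, 300)]), np.zeros(12))

    def test_recovers_planted_sigma(self):
        session = idle_session(5000, sigma=0.1, seed=4)
        sigma = estimate_idle_sigma(session, [(0, 5000)])
        np.testing.assert_allclose(sigma, 0.1, atol=0.01)

    def test_per_channel_sigmas_distinct(self):
        rng = np.random.default_rng(8)
        data = np.empty((5000, 12))
        planted = np.linspace(0.05, 1.2, 12)
        for c in range(12):
            data[:, c] = rng.normal(0, planted[c], 5000)
        session = SyncedSession(SessionId("P0", "cod", "t"),
                                np.arange(5000) / 50.0, data,
                                np.zeros(5000, bool), 0.0)
        sigma = estimate_idle_sigma(session, [(0, 5000)])
        np.testing.assert_allclose(sigma, planted, rtol=0.1)

    def test_insufficient_idle_errors(self):
        with pytest.raises(ValueError, match="insufficient idle"):
            estimate_idle_sigma(idle_session(300), [(0, 10)])


class TestAugmentMinority:
    def test_counting_to_target(self):
        ds = toy_dataset(10, 90)
        out = augment_minority(ds, sigma=0.1, target_ratio=0.5, seed=1)
        assert len(out) == 180  # 80 synthetic copies added
        assert out.event_fraction >= 0.5

    def test_already_balanced_unchanged(self):
        ds = toy_dataset(50, 50)
        assert augment_minority(ds, 0.1, 0.5, seed=1) is ds

    def test_zero_sigma_copies_identical(self):
        ds = toy_dataset(2, 8)
        out = augment_minority(ds, 0.0, 0.5, seed=1)
        added = out.data[len(ds):]
        event_data = ds.data[ds.label == 1]
        for copy, src in zip(added, event_data[np.arange(len(added)) % 2]):
            np.testing.assert_array_equal(copy, src)

    def test_originals_and_labels_untouched(self):
        ds = toy_dataset(10, 90, seed=2)
        before = ds.data.copy()
        out = augment_minority(ds, 0.5, 0.5, seed=3)
        np.testing.assert_array_equal(out.data[:100], before)
        np.testing.assert_array_equal(out.label[:100], ds.label)
        assert (out.label[100:] == 1).all()

    def test_deterministic_under_seed(self):
        ds = toy_dataset(10, 90)
        a = augment_minority(ds, 0.1, 0.5, seed=7)
        b = augment_minority(ds, 0.1, 0.5, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no event windows"):
            augment_minority(toy_dataset(0, 10), 0.1, 0.5)


class TestNormalization:
    def test_zscore_definition(self):
        ds = toy_dataset(5, 45, seed=3)
        out, stats = normalize_dataset(ds)
        np.testing.assert_allclose(out.data.mean(axis=(0, 2)), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.data.std(axis=(0, 2)), 1.0, atol=1e-9)
        assert stats["zero_variance"] == []

    def test_scale_invariance(self):
        ds = toy_dataset(5, 45, seed=3)
        doubled = WindowDataset(2.0 * ds.data, ds.label, ds.player_id,
                                ds.round_index, ds.start)
        a, _ = normalize_dataset(ds)
        b, _ = normalize_dataset(doubled)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_zero_variance_channel_centered_and_flagged(self):
        ds = toy_dataset(5, 45, seed=3)
        ds.data[:, 2, :] = 7.0
        out, stats = normalize_dataset(ds)
        assert stats["zero_variance"] == [2]
        np.testing.assert_allclose(out.data[:, 2, :], 0.0)

    def test_subsets_independent(self):
        # test statistics must not depend on train contents
        train1, train2 = toy_dataset(5, 45, seed=1), toy_dataset(5, 45, seed=2)
        val = toy_dataset(3, 17, seed=3)
        test = toy_dataset(4, 26, seed=4)
        out1, _ = normalize_subsets(train1, val, test)
        out2, _ = normalize_subsets(train2, val, test)
        np.testing.assert_array_equal(out1["test"].data, out2["test"].data)
        np.testing.assert_array_equal(out1["val"].data, out2["val"].data)


class TestMakeSplits:
    def test_test_player_isolated(self, multiplayer_dataset):
        splits = make_splits(multiplayer_dataset, SplitSpec("P3", seed=1))
        assert set(splits["test"].player_id) == {"P3"}
        assert "P3" not in set(splits["train"].player_id)
        assert "P3" not in set(splits["val"].player_id)
        total = sum(len(splits[k]) for k in splits)
        assert total == len(multiplayer_dataset)

    def test_rounds_never_straddle_train_val(self, multiplayer_dataset):
        splits = make_splits(multiplayer_dataset, SplitSpec("P3", seed=5))
        train_keys = set(zip(splits["train"].player_id.tolist(),
                             splits["train"].round_index.tolist()))
        val_keys = set(zip(splits["val"].player_id.tolist(),
                           splits["val"].round_index.tolist()))
        assert not train_keys & val_keys

    def test_deterministic(self, multiplayer_dataset):
        a = make_splits(multiplayer_dataset, SplitSpec("P2", seed=9))
        b = make_splits(multiplayer_dataset, SplitSpec("P2", seed=9))
        np.testing.assert_array_equal(a["train"].start, b["train"].start)
        np.testing.assert_array_equal(a["val"].start, b["val"].start)

    def test_unknown_player_errors(self, multiplayer_dataset):
        with pytest.raises(ValueError, match="unknown test player"):
            make_splits(multiplayer_dataset, SplitSpec("P99"))


class TestWindowsFromRounds:
    def test_event_fraction_near_ten_percent(self, cod_dataset_small):
        dataset, _ = cod_dataset_small
        assert 0.05 <= dataset.event_fraction <= 0.15

    def test_window_shapes_and_provenance(self, cod_dataset_small):
        dataset, _ = cod_dataset_small
        assert dataset.data.shape[1:] == (6, 35)
        assert set(dataset.round_index.tolist()) == {0, 1, 2}
        assert set(dataset.player_id.tolist()) == {"P0"}

    def test_npz_round_trip(self, cod_dataset_small, tmp_path):
        dataset, _ = cod_dataset_small
        path = tmp_path / "windows.npz"
        dataset.save(path)
        back = WindowDataset.load(path)
        np.testing.assert_array_equal(back.data, dataset.data)
        np.testing.assert_array_equal(back.label, dataset.label)
        np.testing.assert_array_equal(back.player_id, dataset.player_id)
        assert back.spec == dataset.spec
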
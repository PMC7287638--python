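"""Movement-image augmentation: arrangements, expansion, windows, targets."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmgdecode.augment import (
    PAPER_ARRANGEMENT_10,
    Arrangement,
    InsufficientLengthError,
    UnsupportedFixtureError,
    assign_targets,
    build_arrangement,
    expand_signals,
    fit_standardizer,
    load_image_dataset,
    make_image_dataset,
    save_image_dataset,
    slice_windows,
    standardize_trial,
)


class TestArrangement:
    def test_three_channel_worked_example(self):
        arr = build_arrangement(3, "paper_fixture")
        assert arr.channels == (1, 2, 3, 1)
        assert arr.length == 4

    def test_ten_channel_fixture_is_verbatim(self):
        arr = build_arrangement(10, "paper_fixture")
        assert arr.channels == PAPER_ARRANGEMENT_10
        assert arr.length == 42

    def test_ten_channel_fixture_misses_exactly_four_pairs(self):
        # documented discrepancy: the published sequence is NOT pair-complete
        arr = build_arrangement(10, "paper_fixture")
        assert arr.missing_pairs() == {
            frozenset(p) for p in [(2, 7), (3, 8), (4, 9), (5, 10)]
        }

    def test_fixture_undefined_for_other_sizes(self):
        with pytest.raises(UnsupportedFixtureError):
            build_arrangement(5, "paper_fixture")

    def test_two_channels_pair_complete_is_single_pair(self):
        assert build_arrangement(2, "pair_complete").channels == (1, 2)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_pair_complete_covers_every_pair(self, n):
        arr = build_arrangement(n, "pair_complete")
        assert arr.missing_pairs() == set()

    def test_four_channels_minimal_length_is_eight(self):
        # exhaustive search: no length-7 sequence over 4 channels covers all
        # 6 pairs (K4 has four odd-degree vertices, no Eulerian path)
        all_pairs = {frozenset(p) for p in itertools.combinations(range(1, 5), 2)}
        for seq in itertools.product(range(1, 5), repeat=7):
            covered = {
                frozenset((a, b)) for a, b in zip(seq, seq[1:]) if a != b
            }
            assert covered != all_pairs or set(seq) != {1, 2, 3, 4} or True
            if covered >= all_pairs:
                pytest.fail(f"length-7 covering sequence exists: {seq}")
        assert build_arrangement(4, "pair_complete").length == 8

    def test_pair_complete_deterministic(self):
        a = build_arrangement(7, "pair_complete")
        b = build_arrangement(7, "pair_complete")
        assert a.channels == b.channels

    def test_arrangement_must_cover_all_channels(self):
        with pytest.raises(ValueError):
            Arrangement((1, 2, 2), 3)
        with pytest.raises(ValueError):
            Arrangement((1, 2, 4), 3)


class TestExpandSignals:
    def test_identity_arrangement_is_noop(self, rng):
        x = rng.standard_normal((30, 5))
        arr = Arrangement((1, 2, 3, 4, 5), 5)
        assert np.array_equal(expand_signals(x, arr), x)

    def test_worked_example_duplicates_first_column(self, rng):
        x = rng.standard_normal((20, 3))
        out = expand_signals(x, build_arrangement(3, "paper_fixture"))
        assert out.shape == (20, 4)
        assert np.array_equal(out[:, 0], out[:, 3])

    def test_every_output_column_copies_its_source(self, rng):
        x = rng.standard_normal((50, 5))
        arr = build_arrangement(5, "pair_complete")
        out = expand_signals(x, arr)
        for j, ch in enumerate(arr.channels):
            assert np.array_equal(out[:, j], x[:, ch - 1])

    def test_expansion_lossless(self, rng):
        # original recoverable from first occurrence of each channel
        x = rng.standard_normal((25, 6))
        arr = build_arrangement(6, "pair_complete")
        out = expand_signals(x, arr)
        first = [arr.channels.index(c) for c in range(1, 7)]
        assert np.array_equal(out[:, first], x)

    def test_channel_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            expand_signals(rng.standard_normal((10, 4)), build_arrangement(3, "paper_fixture"))


class TestSliceWindows:
    def test_published_window_counts(self, rng):
        windows, _ = slice_windows(rng.standard_normal((1000, 42)), 42)
        assert windows.shape == (958, 42, 42)

    def test_nine_concatenated_trials_count(self, rng):
        windows, _ = slice_windows(rng.standard_normal((9000, 3)), 42)
        assert windows.shape[0] == 8958

    def test_single_window_contains_last_sample(self, rng):
        x = rng.standard_normal((43, 4))
        windows, starts = slice_windows(x, 42)
        assert windows.shape[0] == 1
        assert starts[0] == 1
        assert np.array_equal(windows[0], x[1:43])

    def test_windows_match_source_rows_exactly(self, rng):
        x = rng.standard_normal((60, 3))
        windows, starts = slice_windows(x, 10)
        assert len(starts) == 50
        for w, s in zip(windows, starts):
            assert np.array_equal(w, x[s : s + 10])

    def test_too_short_signal_rejected(self, rng):
        with pytest.raises(InsufficientLengthError):
            slice_windows(rng.standard_normal((42, 5)), 42)


class TestAssignTargets:
    def test_constant_window(self):
        labels = np.full(42, 3)
        angles = np.linspace(0, 77.0, 42)
        assert assign_targets(labels, angles) == (3, 77.0)

    def test_majority_wins(self):
        labels = np.array([1] * 20 + [2] * 22)
        label, _ = assign_targets(labels, np.zeros(42))
        assert label == 2

    def test_tie_goes_to_later_occurring_class(self):
        labels = np.array([1] * 21 + [2] * 21)
        label, _ = assign_targets(labels, np.zeros(42))
        assert label == 2
        # and symmetrically when the later run is the lower class index
        labels = np.array([2] * 21 + [1] * 21)
        assert assign_targets(labels, np.zeros(42))[0] == 1

    def test_angle_is_last_time_step(self, rng):
        angles = rng.uniform(0, 90, size=42)
        _, a = assign_targets(np.zeros(42, dtype=int), angles)
        assert a == pytest.approx(angles[-1])

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            assign_targets(np.array([], dtype=int), np.array([]))

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_mode_matches_bincount_oracle(self, labels):
        label, _ = assign_targets(np.array(labels), np.zeros(len(labels)))
        counts = np.bincount(labels, minlength=5)
        assert counts[label] == counts.max()


class TestStandardizer:
    def test_two_point_channel(self):
        from fmgdecode.simulate import TrialRecording

        t = TrialRecording(0, 0, np.array([[2.0], [4.0]]), np.zeros(2, int),
                           np.array([10.0, 20.0]), 40.0)
        params = fit_standardizer([t])
        assert params.channel_mean[0] == pytest.approx(3.0)
        assert params.channel_sd[0] == pytest.approx(1.0)  # population sd
        z, a = standardize_trial(t, params)
        assert np.allclose(z.ravel(), [-1.0, 1.0])

    def test_training_columns_standardized(self, tiny_trials):
        train = tiny_trials[:2]
        params = fit_standardizer(train)
        z = np.concatenate([standardize_trial(t, params)[0] for t in train])
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_channel_guarded(self):
        from fmgdecode.simulate import TrialRecording

        t = TrialRecording(0, 0, np.full((10, 2), 5.0), np.zeros(10, int),
                           np.arange(10.0), 40.0)
        params = fit_standardizer([t])
        z, _ = standardize_trial(t, params)
        assert np.allclose(z, 0.0)

    def test_round_trip_identity(self, tiny_trials):
        params = fit_standardizer(tiny_trials[:2])
        t = tiny_trials[0]
        z, a = standardize_trial(t, params)
        back = z * params.channel_sd + params.channel_mean
        assert np.allclose(back, t.pressures, atol=1e-9)
        assert np.allclose(a * params.angle_sd + params.angle_mean, t.angles, atol=1e-9)


@pytest.fixture(scope="module")
def arrangement():
    return build_arrangement(10, "paper_fixture")


class TestMakeImageDataset:

    def test_single_trial_count(self, tiny_trials, arrangement):
        params = fit_standardizer(tiny_trials[:1])
        ds = make_image_dataset(tiny_trials[:1], arrangement, 42, params, "per_trial")
        n = tiny_trials[0].n_samples
        assert len(ds) == n - 42
        assert ds.images.shape[1:] == (42, 42)

    def test_concat_mode_counts(self, tiny_trials, arrangement):
        trials = tiny_trials[:3]
        params = fit_standardizer(trials)
        total = sum(t.n_samples for t in trials)
        ds_paper = make_image_dataset(trials, arrangement, 42, params, "paper")
        ds_per = make_image_dataset(trials, arrangement, 42, params, "per_trial")
        assert len(ds_paper) == total - 42
        assert len(ds_per) == sum(t.n_samples - 42 for t in trials)

    def test_per_trial_windows_never_cross_boundaries(self, tiny_trials, arrangement):
        trials = tiny_trials[:3]
        params = fit_standardizer(trials)
        ds = make_image_dataset(trials, arrangement, 42, params, "per_trial")
        assert np.array_equal(ds.trial_start, ds.trial_end)

    def test_end_to_end_determinism(self, tiny_trials, arrangement):
        params = fit_standardizer(tiny_trials[:2])
        a = make_image_dataset(tiny_trials[:2], arrangement, 42, params, "paper")
        b = make_image_dataset(tiny_trials[:2], arrangement, 42, params, "paper")
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.labels, b.labels)

    def test_mixed_channel_counts_rejected(self, tiny_trials, arrangement):
        from fmgdecode.evaluate import restrict_channels

        bad = restrict_channels(tiny_trials[1:2], (1, 2, 3))
        params = fit_standardizer(tiny_trials[:1])
        with pytest.raises(ValueError):
            make_image_dataset([tiny_trials[0], bad[0]], arrangement, 42, params)

    def test_npz_round_trip(self, tiny_trials, arrangement, tmp_path):
        params = fit_standardizer(tiny_trials[:1])
        ds = make_image_dataset(tiny_trials[:1], arrangement, 42, params, "per_trial")
        path = tmp_path / "images.npz"
        save_image_dataset(ds, path)
        back = load_image_dataset(path)
        assert np.array_equal(back.images, ds.images)
        assert np.array_equal(back.labels, ds.labels)
        assert back.arrangement == ds.arrangement
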
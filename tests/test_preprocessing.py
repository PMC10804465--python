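import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sonorsa as s
from sonorsa.preprocessing import DegenerateStateError

from _oracles import oracle_dissimilarity, oracle_downsample


def _trial(frames, movement="power", trial_index=1, limb="affected"):
    return s.TrialRecording(
        subject_id="t", limb=limb, movement=movement,
        trial_index=trial_index, frames=np.asarray(frames, dtype=float),
    )


class TestDownsample:
    def test_constant_frame_stays_constant(self):
        out = s.downsample_frame(np.full((8, 8), 3.25), (4, 4))
        assert out.shape == (4, 4)
        assert np.allclose(out, 3.25)

    def test_block_means_of_labeled_blocks(self):
        frame = np.kron(np.array([[0.0, 1.0], [2.0, 3.0]]), np.ones((2, 2)))
        assert np.array_equal(s.downsample_frame(frame, (2, 2)), [[0, 1], [2, 3]])

    def test_matches_explicit_double_loop(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 255, size=(256, 256))
        assert np.allclose(s.downsample_frame(frame, (32, 32)),
                           oracle_downsample(frame, (32, 32)))

    def test_preserves_global_mean(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 255, size=(64, 64))
        assert s.downsample_frame(frame, (16, 16)).mean() == pytest.approx(frame.mean())

    def test_non_divisible_shapes_rejected(self):
        with pytest.raises(ValueError, match=r"\(10, 10\).*\(4, 4\)"):
            s.downsample_frame(np.zeros((10, 10)), (4, 4))


class TestStaticPixelMask:
    def test_margin_pixel_count_on_128_grid(self):
        # 4-pixel static border on a 128x128 grid: 128^2 - (128^2 - 120^2) kept
        frames = np.zeros((3, 128, 128))
        frames[1:, 4:-4, 4:-4] = 1.0
        mask = s.build_static_pixel_mask([_trial(frames)])
        assert mask.n_kept == 120 * 120 == 14400

    def test_kept_if_deviates_in_any_trial(self):
        quiet = np.zeros((2, 4, 4))
        active = np.zeros((2, 4, 4))
        active[1, 1, 2] = 5.0
        active[1, 3, 0] = -1.0
        mask = s.build_static_pixel_mask([_trial(quiet), _trial(active, trial_index=2)])
        assert mask.n_kept == 2
        assert mask.keep[1, 2] and mask.keep[3, 0]

    def test_all_static_is_degenerate(self):
        frames = np.ones((5, 8, 8))
        with pytest.raises(DegenerateStateError):
            s.build_static_pixel_mask([_trial(frames)])

    def test_infinite_tolerance_keeps_nothing(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(size=(5, 8, 8))
        with pytest.raises(DegenerateStateError):
            s.build_static_pixel_mask([_trial(frames)], tol=np.inf)


class TestMuscleStates:
    def test_extract_row_major_order(self):
        frame = np.arange(16.0).reshape(4, 4)
        keep = np.zeros((4, 4), dtype=bool)
        keep[0, 3] = keep[2, 1] = keep[3, 0] = True
        ms = s.extract_features(frame, s.FeatureMask(keep=keep))
        assert np.array_equal(ms.values, [3.0, 9.0, 12.0])

    def test_full_mask_keeps_every_pixel(self):
        frame = np.arange(12.0).reshape(3, 4)
        ms = s.extract_features(frame, s.FeatureMask(keep=np.ones((3, 4), bool)))
        assert np.array_equal(ms.values, frame.ravel())

    def test_masked_out_pixels_are_invisible(self):
        keep = np.zeros((4, 4), dtype=bool)
        keep[:2] = True
        mask = s.FeatureMask(keep=keep)
        a = np.arange(16.0).reshape(4, 4)
        b = a.copy()
        b[3, 3] = 99.0
        assert np.array_equal(s.extract_features(a, mask).values,
                              s.extract_features(b, mask).values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            s.extract_features(np.zeros((4, 4)), s.FeatureMask(keep=np.ones((3, 3), bool)))

    def test_initial_state_is_frame_zero_only(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(size=(6, 4, 4))
        mask = s.FeatureMask(keep=np.ones((4, 4), bool))
        before = s.initial_muscle_state(_trial(frames), mask)
        shuffled = frames.copy()
        shuffled[1:] = shuffled[1:][::-1]
        after = s.initial_muscle_state(_trial(shuffled), mask)
        assert before.source == "initial"
        assert np.array_equal(before.values, after.values)
        assert np.array_equal(before.values, frames[0].ravel())

    def test_end_state_is_mean_of_last_five(self):
        frames = np.zeros((8, 2, 2))
        frames[3:, 0, 0] = [1, 2, 3, 4, 5]
        mask = s.FeatureMask(keep=np.ones((2, 2), bool))
        ms = s.end_muscle_state(_trial(frames), mask, n_end=5)
        assert ms.values[0] == pytest.approx(3.0)
        assert ms.source == "end"

    def test_end_state_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(size=(9, 3, 3))
        mask = s.FeatureMask(keep=np.ones((3, 3), bool))
        ms = s.end_muscle_state(_trial(frames), mask, n_end=5)
        expected = sum(frames[i].ravel() for i in range(4, 9)) / 5.0
        assert np.allclose(ms.values, expected)

    def test_end_state_needs_enough_frames(self):
        with pytest.raises(ValueError, match="fewer than"):
            s.end_muscle_state(_trial(np.random.default_rng(0).uniform(size=(3, 2, 2))),
                               s.FeatureMask(keep=np.ones((2, 2), bool)), n_end=5)

    def test_masking_commutes_with_averaging(self):
        rng = np.random.default_rng(5)
        frames = rng.uniform(size=(7, 5, 5))
        keep = rng.uniform(size=(5, 5)) > 0.4
        mask = s.FeatureMask(keep=keep)
        via_trial = s.end_muscle_state(_trial(frames), mask, n_end=5)
        via_mean = s.extract_features(frames[-5:].mean(axis=0), mask)
        assert np.allclose(via_trial.values, via_mean.values)


class TestPearsonDissimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2, 3), (2, 4, 6), 0.0),
            ((1, 2, 3), (3, 2, 1), 2.0),
            ((1, 0, 0, 1), (1, 1, 0, 0), 1.0),
        ],
    )
    def test_hand_values(self, a, b, expected):
        assert s.pearson_dissimilarity(a, b) == pytest.approx(expected)

    def test_symmetric_and_zero_on_identical(self):
        rng = np.random.default_rng(6)
        a, b = rng.uniform(size=20), rng.uniform(size=20)
        assert s.pearson_dissimilarity(a, b) == pytest.approx(s.pearson_dissimilarity(b, a))
        assert s.pearson_dissimilarity(a, a) == pytest.approx(0.0)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a, b = rng.normal(size=15), rng.normal(size=15)
            assert s.pearson_dissimilarity(a, b) == pytest.approx(
                oracle_dissimilarity(a, b))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        alpha=st.floats(min_value=0.01, max_value=100),
        beta=st.floats(min_value=-50, max_value=50),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_invariant_under_positive_affine_maps(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=12), rng.normal(size=12)
        d = s.pearson_dissimilarity(a, b)
        assert s.pearson_dissimilarity(a, alpha * b + beta) == pytest.approx(d, abs=1e-9)
        assert s.pearson_dissimilarity(a, -alpha * b + beta) == pytest.approx(
            2.0 - d, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStateError):
            s.pearson_dissimilarity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            s.pearson_dissimilarity([1.0, 2.0], [1.0, 2.0, 3.0])
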
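import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorcascade import (
    LabelVolume,
    PredictionSet,
    TransformParams,
    add_noise,
    apply_transform,
    invert_transform,
    majority_vote,
    sample_transform,
    tta_predict,
)
from tumorcascade.errors import TransformError
from tumorcascade.train import dice_score
from tumorcascade.volume_io import labels_to_task_mask


class TestPriors:
    def test_flip_rotation_scale_priors(self, rng):
        draws = [sample_transform(rng) for _ in range(10_000)]
        flips = np.array([d.f for d in draws], dtype=float)
        scales = np.array([d.s for d in draws])
        rotations = np.array([d.r for d in draws])
        for axis in range(3):
            assert 0.45 <= flips[:, axis].mean() <= 0.55
        assert scales.min() >= 0.8 and scales.max() <= 1.2
        assert scales.min() < 0.85 and scales.max() > 1.15  # covers the range
        assert rotations.min() >= 0.0 and rotations.max() < 2 * np.pi
        assert abs(rotations.mean() - np.pi) < 0.1

    def test_same_seed_same_sequence(self):
        a = [sample_transform(np.random.default_rng(5)) for _ in range(3)]
        b = [sample_transform(np.random.default_rng(5)) for _ in range(3)]
        assert a == b

    def test_in_plane_only_restricts_rotation(self, rng):
        params = sample_transform(rng, in_plane_only=True)
        assert params.r[0] == 0.0 and params.r[1] == 0.0


class TestApplyInvert:
    def test_identity_params_change_nothing(self, rng):
        x = rng.standard_normal((8, 8, 8)).astype(np.float32)
        out = apply_transform(x, TransformParams.identity(), "linear")
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_double_flip_is_identity(self, rng):
        x = rng.standard_normal((7, 8, 9)).astype(np.float32)
        params = TransformParams(r=(0, 0, 0), f=(True, False, True), s=1.0)
        out = apply_transform(apply_transform(x, params, "linear"), params, "linear")
        np.testing.assert_allclose(out, x, atol=1e-5)

    def test_pure_flip_roundtrip_exact(self, rng):
        x = rng.standard_normal((6, 7, 8)).astype(np.float32)
        params = TransformParams(r=(0, 0, 0), f=(False, True, True), s=1.0)
        out = invert_transform(apply_transform(x, params, "nearest"), params, "nearest")
        np.testing.assert_array_equal(out, x)

    def test_quarter_turn_conserves_label_counts(self, phantom_case):
        _, labels = phantom_case
        params = TransformParams(r=(0.0, 0.0, np.pi / 2), f=(False,) * 3, s=1.0)
        turned = np.rint(apply_transform(labels.labels.astype(np.float32), params,
                                         "nearest")).astype(int)
        for code in (1, 2, 4):
            before = int((labels.labels == code).sum())
            after = int((turned == code).sum())
            assert abs(after - before) <= 0.02 * before + 1

    def test_random_roundtrip_dice(self, phantom_case, rng):
        _, labels = phantom_case
        arr = labels.labels.astype(np.float32)
        for _ in range(8):
            params = sample_transform(rng)
            back = np.rint(invert_transform(apply_transform(arr, params, "nearest"),
                                            params, "nearest")).astype(np.int16)
            d = dice_score(labels_to_task_mask(LabelVolume(labels=back), "whole"),
                           labels_to_task_mask(labels, "whole"))
            assert d >= 0.95

    def test_invalid_params_rejected(self):
        with pytest.raises(TransformError):
            TransformParams(r=(np.nan, 0, 0), f=(False,) * 3, s=1.0)
        with pytest.raises(TransformError):
            TransformParams(r=(0, 0, 0), f=(False,) * 3, s=0.0)


class TestNoise:
    def test_moments_and_determinism(self):
        x = np.zeros((50, 50, 50), dtype=np.float32)
        noised = add_noise(x, np.random.default_rng(2), std=0.05)
        n = x.size
        assert abs(noised.mean()) < 3 * 0.05 / np.sqrt(n)
        assert 0.045 <= noised.std() <= 0.055
        again = add_noise(x, np.random.default_rng(2), std=0.05)
        np.testing.assert_array_equal(noised, again)


class TestMajorityVote:
    def _vote(self, member_values):
        members = [np.full((1, 1, 1), v, dtype=np.int16) for v in member_values]
        return int(majority_vote(PredictionSet(members=members))[0, 0, 0])

    @pytest.mark.parametrize("members,expected", [
        ([1, 1, 0], 1),
        ([0, 0, 1], 0),
        ([1] * 10 + [0] * 10, 1),  # exact binary tie -> foreground
        ([2, 2, 4, 4], 4),  # tie among tumor codes -> deeper structure
    ])
    def test_vote_rules(self, members, expected):
        assert self._vote(members) == expected

    @given(st.permutations(list(range(6))))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_order_invariance(self, order):
        rng = np.random.default_rng(9)
        members = [rng.choice([0, 1, 2, 4], size=(3, 3, 2)) for _ in range(6)]
        base = majority_vote(PredictionSet(members=members))
        shuffled = majority_vote(PredictionSet(members=[members[i] for i in order]))
        np.testing.assert_array_equal(base, shuffled)

    def test_vote_label_always_among_member_labels(self, rng):
        members = [rng.choice([0, 1, 2, 4], size=(4, 4, 3)) for _ in range(5)]
        vote = majority_vote(PredictionSet(members=members))
        stack = np.stack(members)
        assert np.all((vote[None] == stack).any(axis=0))


class TestTtaPredict:
    def test_single_identity_draw_equals_plain_prediction(self, normalized_case):
        volume, labels = normalized_case

        def threshold_predictor(v):
            return (v.channels["FLAIR"] > 1.0).astype(np.int16)

        pset, vote = tta_predict(volume, threshold_predictor, n=1,
                                 rng=np.random.default_rng(0), noise_std=0.0,
                                 identity_transforms=True)
        np.testing.assert_array_equal(vote.labels, threshold_predictor(volume))

    def test_constant_predictor_gives_identical_members(self, normalized_case):
        volume, _ = normalized_case
        fixed = np.zeros(volume.shape, dtype=np.int16)
        fixed[10:20, 10:20, 10:15] = 1
        # constant in the *aligned* frame requires identity transforms
        pset, vote = tta_predict(volume, lambda v: fixed, n=4,
                                 rng=np.random.default_rng(1), noise_std=0.05,
                                 identity_transforms=True)
        for member in pset.members:
            np.testing.assert_array_equal(member, fixed)
        np.testing.assert_array_equal(vote.labels, fixed)

    def test_draw_index_in_predictor_error(self, normalized_case):
        volume, _ = normalized_case

        def failing(v):
            raise ValueError("boom")

        with pytest.raises(ValueError, match="TTA draw 0"):
            tta_predict(volume, failing, n=2, rng=np.random.default_rng(0))
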
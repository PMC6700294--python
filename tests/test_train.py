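import numpy as np
import pytest

from tumorcascade import (
    TrainConfig,
    dice_loss,
    dice_score,
    hausdorff_distance,
    sample_training_patch,
    train_stage,
)
from tumorcascade.errors import FormatError, UndefinedDistanceError


class TestDiceLoss:
    def test_perfect_and_disjoint(self):
        g = np.zeros((4, 4, 2))
        g[:2] = 1
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-4)
        assert dice_loss(1 - g, g) == pytest.approx(1.0, abs=1e-4)

    def test_half_overlap_hand_value(self):
        # two 4-voxel rectangles sharing 2 voxels: soft Dice 0.5 -> loss 0.5
        p = np.zeros((3, 2, 1))
        g = np.zeros((3, 2, 1))
        p[:2, :, 0] = 1.0  # rows 0-1
        g[1:, :, 0] = 1.0  # rows 1-2, overlap = row 1 (2 voxels)
        assert dice_loss(p, g) == pytest.approx(0.5, abs=1e-4)

    def test_loss_plus_score_is_one_for_binary(self, rng):
        p = (rng.uniform(size=(6, 6, 3)) > 0.6).astype(float)
        g = (rng.uniform(size=(6, 6, 3)) > 0.5).astype(float)
        assert dice_loss(p, g) + dice_score(p.astype(bool), g.astype(bool)) \
            == pytest.approx(1.0, abs=1e-3)

    def test_shape_mismatch(self):
        with pytest.raises(FormatError):
            dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestDiceScore:
    def test_reference_values(self):
        a = np.zeros((4, 2, 1), dtype=bool)
        b = np.zeros((4, 2, 1), dtype=bool)
        a[:2] = True
        b[1:3] = True  # |a|=|b|=4, overlap 2
        assert dice_score(a, b) == pytest.approx(0.5)
        assert dice_score(a, a) == 1.0
        assert dice_score(a, ~a) == 0.0

    def test_empty_mask_conventions(self):
        empty = np.zeros((3, 3, 3), dtype=bool)
        full = np.ones((3, 3, 3), dtype=bool)
        assert dice_score(empty, empty) == 1.0
        assert dice_score(empty, full) == 0.0


class TestHausdorff:
    def test_identical_masks(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        assert hausdorff_distance(m, m) == 0.0

    def test_point_distance(self):
        a = np.zeros((10, 4, 4), dtype=bool)
        b = np.zeros((10, 4, 4), dtype=bool)
        a[2, 1, 1] = True
        b[5, 1, 1] = True  # 3 voxels apart at 1 mm
        assert hausdorff_distance(a, b) == pytest.approx(3.0)

    def test_spacing_scales_distance(self):
        a = np.zeros((10, 4, 4), dtype=bool)
        b = np.zeros((10, 4, 4), dtype=bool)
        a[2, 1, 1] = True
        b[5, 1, 1] = True
        assert hausdorff_distance(a, b, spacing=(2.0, 1.0, 1.0)) == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_percentile_below_maximum(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=(10, 10, 6)) > 0.7
        b = rng.uniform(size=(10, 10, 6)) > 0.7
        assert hausdorff_distance(a, b, percentile=95) <= hausdorff_distance(a, b, percentile=100)

    def test_empty_mask_undefined(self):
        m = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(UndefinedDistanceError):
            hausdorff_distance(np.zeros((4, 4, 4), dtype=bool), m)


class TestPatchSampling:
    @pytest.mark.parametrize("stage", ["whole", "core", "enhancing"])
    def test_patch_extents_match_config(self, small_cohort, stage, rng):
        volume, labels, _ = small_cohort[0]
        cfg = TrainConfig.tiny_config()
        x, y = sample_training_patch(volume, labels, stage, rng, cfg)
        assert x.shape == (4,) + tuple(cfg.stage_patch[stage])
        assert y.shape == tuple(cfg.stage_patch[stage])
        assert set(np.unique(y)) <= {0.0, 1.0}

    def test_deterministic_without_augmentation(self, small_cohort):
        volume, labels, _ = small_cohort[0]
        cfg = TrainConfig.tiny_config(augment=False)
        x1, y1 = sample_training_patch(volume, labels, "whole", np.random.default_rng(3), cfg)
        x2, y2 = sample_training_patch(volume, labels, "whole", np.random.default_rng(3), cfg)
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)

    def test_foreground_bias_hits_target_often(self, small_cohort, rng):
        volume, labels, _ = small_cohort[0]
        cfg = TrainConfig.tiny_config(augment=False)
        hits = sum(sample_training_patch(volume, labels, "whole", rng, cfg)[1].any()
                   for _ in range(200))
        assert hits >= 100  # at least the foreground-centred half

    def test_training_augmentation_shares_tta_implementation(self, small_cohort, monkeypatch):
        """The augment code path is literally tta.augment_case."""
        import tumorcascade.train as train_mod

        calls = {"n": 0}
        original = train_mod.augment_case

        def counting(*args, **kwargs):
            calls["n"] += 1
            return original(*args, **kwargs)

        monkeypatch.setattr(train_mod, "augment_case", counting)
        volume, labels, _ = small_cohort[0]
        cfg = TrainConfig.tiny_config(augment=True)
        sample_training_patch(volume, labels, "whole", np.random.default_rng(0), cfg)
        assert calls["n"] == 1
        from tumorcascade.tta import augment_case as tta_augment
        assert original is tta_augment


@pytest.fixture(scope="module")
def mini_cohort():
    from tumorcascade import PhantomSpec, generate_cohort, normalize_case
    cases = generate_cohort(3, base_spec=PhantomSpec(shape=(40, 40, 20),
                                                     radii_whole=(9.0, 8.0, 5.0),
                                                     radii_core=(6.0, 5.0, 3.0),
                                                     radii_enh=(3.0, 3.0, 2.0)),
                            seed=5, lgg_fraction=0.0)
    return [(normalize_case(v), l) for v, l, s in cases]


class TestTrainStage:
    def test_loss_decreases(self, mini_cohort):
        cfg = TrainConfig.tiny_config(seed=1, iterations=40, log_every=39)
        predictor, log = train_stage(mini_cohort, "whole", cfg)
        assert log[-1][1] < log[0][1]
        fg = predictor(mini_cohort[0][0].stacked())
        assert fg.shape == mini_cohort[0][0].shape
        assert 0.0 <= fg.min() and fg.max() <= 1.0

    def test_same_seed_reproduces_loss_curve(self, mini_cohort):
        cfg = TrainConfig.tiny_config(seed=2, iterations=10, log_every=3)
        _, log1 = train_stage(mini_cohort, "whole", cfg)
        _, log2 = train_stage(mini_cohort, "whole", cfg)
        assert log1 == log2
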
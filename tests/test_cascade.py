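import numpy as np
import pytest

from tumorcascade import (
    MultiModalVolume,
    mask_bounding_box,
    multiview_predict,
    run_cascade,
    sliding_window_infer,
)
from tumorcascade.cascade import VIEW_AXES, permute_to_view, unpermute_from_view
from tumorcascade.errors import ConfigError
from tumorcascade.volume_io import MODALITIES, TASKS, labels_to_task_mask


class TestBoundingBox:
    def test_single_voxel(self):
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[5, 6, 7] = 1
        box = mask_bounding_box(mask)
        assert box.lo == (5, 6, 7) and box.hi == (6, 7, 8)

    def test_empty_mask_is_none(self):
        assert mask_bounding_box(np.zeros((4, 4, 4))) is None

    def test_margin_clipped_to_grid(self):
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[0, 0, 0] = 1
        mask[9, 9, 9] = 1
        box = mask_bounding_box(mask, margin=(2, 2, 2))
        assert box.lo == (0, 0, 0) and box.hi == (10, 10, 10)


class TestViews:
    @pytest.mark.parametrize("view", sorted(VIEW_AXES))
    def test_permute_roundtrip_identity(self, view):
        arr = np.arange(2 * 3 * 4 * 5).reshape(2, 3, 4, 5)
        np.testing.assert_array_equal(
            unpermute_from_view(permute_to_view(arr, view), view), arr)
        np.testing.assert_array_equal(
            unpermute_from_view(permute_to_view(arr[0], view), view), arr[0])

    def test_multiview_average_of_constants(self):
        channels = np.zeros((4, 4, 4, 4), dtype=np.float32)

        def const(value):
            return lambda x: np.full(x.shape[1:], value, dtype=np.float32)

        fused = multiview_predict(channels, {
            "axial": const(0.6), "sagittal": const(0.7), "coronal": const(0.8)})
        np.testing.assert_allclose(fused, 0.7, atol=1e-6)

    def test_identical_predictor_equals_single_view(self):
        rng = np.random.default_rng(0)
        channels = rng.standard_normal((4, 6, 6, 6)).astype(np.float32)

        def mean_intensity(x):  # permutation-invariant per voxel
            return x.mean(axis=0)

        fused = multiview_predict(channels, {v: mean_intensity for v in VIEW_AXES})
        np.testing.assert_allclose(fused, mean_intensity(channels), atol=1e-6)

    def test_missing_view_is_config_error(self):
        with pytest.raises(ConfigError, match="coronal"):
            multiview_predict(np.zeros((4, 4, 4, 4)), {"axial": lambda x: x[0]})


class TestSlidingWindow:
    def test_volume_smaller_than_patch_preserves_shape(self):
        x = np.random.default_rng(0).standard_normal((4, 5, 5, 3)).astype(np.float32)

        def half(patch):
            return np.full((2,) + patch.shape[1:], 0.5, dtype=np.float32)

        probs = sliding_window_infer(x, half, (8, 8, 8))
        assert probs.shape == (2, 5, 5, 3)

    def test_constant_predictor_any_stride(self):
        x = np.zeros((4, 12, 12, 6), dtype=np.float32)

        def const(patch):
            out = np.zeros((2,) + patch.shape[1:], dtype=np.float32)
            out[0], out[1] = 0.3, 0.7
            return out

        for stride in [(6, 6, 6), (4, 4, 3), None]:
            probs = sliding_window_infer(x, const, (6, 6, 6), stride=stride)
            np.testing.assert_allclose(probs[1], 0.7, atol=1e-6)

    def test_half_stride_overlap_is_mean_of_patch_outputs(self):
        """Overlap voxels average the outputs of the two covering patches."""
        x = np.zeros((4, 12, 4, 4), dtype=np.float32)
        x[0, 8:, :, :] = 1.0  # second patch sees different content

        def patch_mean(patch):
            out = np.empty((2,) + patch.shape[1:], dtype=np.float32)
            out[1] = patch[0].mean()
            out[0] = 1.0 - out[1]
            return out

        probs = sliding_window_infer(x, patch_mean, (8, 4, 4), stride=(4, 4, 4))
        p_first = x[0, 0:8].mean()   # patch starting at 0
        p_second = x[0, 4:12].mean()  # patch starting at 4
        np.testing.assert_allclose(probs[1, 5, 0, 0], (p_first + p_second) / 2, atol=1e-6)

    def test_stride_larger_than_patch_rejected(self):
        with pytest.raises(ConfigError):
            sliding_window_infer(np.zeros((4, 8, 8, 8)), lambda p: p[:2], (4, 4, 4),
                                 stride=(5, 4, 4))


def _oracle_volume(labels):
    """Encode ground truth into the intensities so stage oracles are exact:
    FLAIR = whole mask, T1 = core mask, T1ce = enhancing mask."""
    masks = {t: labels_to_task_mask(labels, t).mask.astype(np.float32) for t in TASKS}
    channels = {"FLAIR": masks["whole"], "T1": masks["core"],
                "T1ce": masks["enhancing"], "T2": np.zeros(labels.shape, np.float32)}
    return MultiModalVolume(channels=channels)


ORACLES = {"whole": lambda r: r[0], "core": lambda r: r[1], "enhancing": lambda r: r[2]}


class TestRunCascade:
    def test_oracle_predictors_recover_ground_truth(self, phantom_case):
        _, labels = phantom_case
        out, probs = run_cascade(_oracle_volume(labels), ORACLES)
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_nesting_invariant_on_cohort(self, small_cohort):
        for _, labels, _ in small_cohort:
            out, _ = run_cascade(_oracle_volume(labels), ORACLES)
            w, c, e = (labels_to_task_mask(out, t).mask for t in TASKS)
            assert np.all(e <= c) and np.all(c <= w)

    def test_empty_whole_short_circuits_downstream(self, phantom_case):
        _, labels = phantom_case
        calls = {"core": 0, "enhancing": 0}

        def counting(stage):
            def f(region):
                calls[stage] += 1
                return np.ones(region.shape[1:], dtype=np.float32)
            return f

        predictors = {"whole": lambda r: np.zeros(r.shape[1:], dtype=np.float32),
                      "core": counting("core"), "enhancing": counting("enhancing")}
        out, _ = run_cascade(_oracle_volume(labels), predictors)
        assert out.labels.sum() == 0
        assert calls == {"core": 0, "enhancing": 0}

    def test_downstream_positives_outside_whole_are_masked(self, phantom_case):
        _, labels = phantom_case
        predictors = dict(ORACLES)
        predictors["core"] = lambda r: np.ones(r.shape[1:], dtype=np.float32)
        out, _ = run_cascade(_oracle_volume(labels), predictors)
        whole_truth = labels_to_task_mask(labels, "whole").mask
        core_pred = labels_to_task_mask(out, "core").mask
        assert np.all(core_pred <= whole_truth)

    def test_no_label_outside_stage1_bounding_box(self, phantom_case):
        _, labels = phantom_case
        out, _ = run_cascade(_oracle_volume(labels), ORACLES, margin=(2, 2, 1))
        box = mask_bounding_box(labels_to_task_mask(labels, "whole").mask, (2, 2, 1))
        outside = np.ones(out.shape, dtype=bool)
        outside[box.slices] = False
        assert out.labels[outside].sum() == 0
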
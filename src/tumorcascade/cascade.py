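"""Sequential WNet→TNet→ENet inference with cropping, masking and fusion.

The cascade decomposes multi-class tumor segmentation into three binary
problems solved coarse-to-fine: the whole tumor is segmented on the full
volume, the volume is cropped to the whole tumor's bounding box (plus a
context margin) and the tumor core segmented inside it, then cropped once
more for the enhancing core.  Each upstream mask is applied *crisply* — a
downstream stage can never label a voxel its predecessor rejected — which
guarantees the anatomical nesting enhancing ⊆ core ⊆ whole by construction.

Stage predictors are plain callables mapping a stacked ``(4, X, Y, Z)``
intensity array to a foreground-probability grid of the same spatial shape;
multi-view fusion, sliding-window tiling and test-time augmentation are
composable wrappers that produce such callables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .errors import ConfigError, FormatError
from .volume_io import LabelVolume, MultiModalVolume, TaskMask, masks_to_labels

STAGES = ("whole", "core", "enhancing")

#: Default context margin around the upstream bounding box, voxels
#: (in-plane x, in-plane y, through-plane z).
DEFAULT_MARGIN = (5, 5, 3)

#: Axis orders placing the through-plane direction along each anatomical axis.
VIEW_AXES = {"axial": (0, 1, 2), "sagittal": (1, 2, 0), "coronal": (0, 2, 1)}


@dataclass(frozen=True)
class BoundingBox:
    """Half-open voxel box [lo, hi) per axis."""

    lo: tuple
    hi: tuple

    def __post_init__(self):
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise FormatError(f"degenerate bounding box {self.lo}..{self.hi}")

    @property
    def slices(self) -> tuple:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


@dataclass
class ProbabilityVolume:
    """Per-class probability grids (Cl, X, Y, Z); classes sum to one."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs)
        if p.ndim != 4:
            raise FormatError(f"expected (Cl, X, Y, Z), got shape {p.shape}")
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise FormatError("probabilities outside [0, 1]")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-5):
            raise FormatError("class probabilities do not sum to 1")
        self.probs = p

    @property
    def foreground(self) -> np.ndarray:
        return self.probs[1]


def mask_bounding_box(mask, margin=(0, 0, 0)):
    """Tightest half-open box around positive voxels, expanded and clipped.

    Returns ``None`` for an all-zero mask (the empty sentinel).
    """
    arr = mask.mask if isinstance(mask, TaskMask) else np.asarray(mask)
    positive = np.argwhere(arr)
    if positive.size == 0:
        return None
    lo = positive.min(axis=0) - np.asarray(margin)
    hi = positive.max(axis=0) + 1 + np.asarray(margin)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, arr.shape)
    return BoundingBox(lo=tuple(int(v) for v in lo), hi=tuple(int(v) for v in hi))


def permute_to_view(arr: np.ndarray, view: str) -> np.ndarray:
    """Reorder spatial axes so the through-plane axis is last for ``view``.

    Works on (X, Y, Z) or (C, X, Y, Z) arrays; axial is the native order.
    """
    if view not in VIEW_AXES:
        raise ConfigError(f"unknown view {view!r}; expected one of {sorted(VIEW_AXES)}")
    perm = VIEW_AXES[view]
    if arr.ndim == 4:
        return np.transpose(arr, (0,) + tuple(p + 1 for p in perm))
    return np.transpose(arr, perm)


def unpermute_from_view(arr: np.ndarray, view: str) -> np.ndarray:
    perm = VIEW_AXES[view]
    inv = tuple(int(i) for i in np.argsort(perm))
    if arr.ndim == 4:
        return np.transpose(arr, (0,) + tuple(p + 1 for p in inv))
    return np.transpose(arr, inv)


def multiview_predict(channels: np.ndarray, predictors_by_view: dict) -> np.ndarray:
    """Average foreground probabilities over axial/sagittal/coronal models.

    Each per-view predictor receives the volume permuted into its canonical
    axis order and its output is permuted back before the (equal-weight)
    softmax average.
    """
    missing = [v for v in VIEW_AXES if v not in predictors_by_view]
    if missing:
        raise ConfigError(f"missing view predictors: {missing}")
    acc = None
    for view, predictor in predictors_by_view.items():
        if view not in VIEW_AXES:
            raise ConfigError(f"unknown view {view!r}")
        out = predictor(permute_to_view(channels, view))
        out = unpermute_from_view(np.asarray(out), view)
        acc = out if acc is None else acc + out
    return acc / len(predictors_by_view)


def sliding_window_infer(channels: np.ndarray, patch_predictor, patch_extent,
                         stride=None) -> np.ndarray:
    """Tile a volume with overlapping patches and average class probabilities.

    ``patch_predictor`` maps a (4, px, py, pz) patch to (Cl, px, py, pz)
    probabilities.  Volumes smaller than the patch are zero-padded and
    cropped back.  Every voxel is covered at least once; overlap regions
    average the covering patch outputs.
    """
    patch_extent = tuple(int(p) for p in patch_extent)
    stride = patch_extent if stride is None else tuple(int(s) for s in stride)
    if any(s > p for s, p in zip(stride, patch_extent)):
        raise ConfigError(f"stride {stride} exceeds patch extent {patch_extent}")
    if any(s < 1 for s in stride):
        raise ConfigError("stride must be positive")

    spatial = channels.shape[1:]
    padded_shape = tuple(max(n, p) for n, p in zip(spatial, patch_extent))
    x = channels
    if padded_shape != spatial:
        pad = tuple((0, ps - n) for ps, n in zip(padded_shape, spatial))
        x = np.pad(channels, ((0, 0),) + pad)

    starts = []
    for n, p, s in zip(padded_shape, patch_extent, stride):
        pos = list(range(0, n - p + 1, s))
        if pos[-1] != n - p:
            pos.append(n - p)  # final patch flush with the boundary
        starts.append(pos)

    acc = None
    count = np.zeros(padded_shape, dtype=np.float32)
    for corner in product(*starts):
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_extent))
        probs = np.asarray(patch_predictor(x[(slice(None),) + sl]))
        if acc is None:
            acc = np.zeros((probs.shape[0],) + padded_shape, dtype=np.float32)
        acc[(slice(None),) + sl] += probs
        count[sl] += 1.0
    acc /= count[None]
    return acc[(slice(None),) + tuple(slice(0, n) for n in spatial)]


def run_cascade(volume: MultiModalVolume, stage_predictors: dict,
                margin=DEFAULT_MARGIN, threshold: float = 0.5):
    """Hierarchical three-stage segmentation of one (normalized) case.

    ``stage_predictors`` maps each of ``whole``/``core``/``enhancing`` to a
    callable producing a foreground-probability grid for a stacked input.
    Stage probabilities are binarized at ``threshold`` with ties toward
    foreground.  If a stage comes back empty, downstream stages are skipped
    (their masks are necessarily empty under crisp masking).  Returns the
    recombined :class:`LabelVolume` and per-stage full-grid foreground
    probabilities.
    """
    missing = [s for s in STAGES if s not in stage_predictors]
    if missing:
        raise ConfigError(f"missing stage predictors: {missing}")
    channels = volume.stacked().astype(np.float32)
    shape = volume.shape

    masks = {}
    probs = {}
    box = None
    upstream = None
    for stage in STAGES:
        full_prob = np.zeros(shape, dtype=np.float32)
        mask = np.zeros(shape, dtype=np.uint8)
        if stage == "whole":
            region = channels
            region_slices = tuple(slice(0, n) for n in shape)
        elif box is None:
            masks[stage] = TaskMask(task=stage, mask=mask, spacing=volume.spacing)
            probs[stage] = full_prob
            continue
        else:
            region_slices = box.slices
            region = channels[(slice(None),) + region_slices]
        try:
            fg = np.asarray(stage_predictors[stage](region), dtype=np.float32)
        except Exception as exc:
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        if fg.shape != region.shape[1:]:
            raise FormatError(
                f"stage {stage!r} predictor returned shape {fg.shape} for region {region.shape[1:]}"
            )
        full_prob[region_slices] = fg
        stage_mask = (fg >= threshold).astype(np.uint8)
        if upstream is not None:
            stage_mask &= upstream[region_slices]
        mask[region_slices] = stage_mask
        masks[stage] = TaskMask(task=stage, mask=mask, spacing=volume.spacing)
        probs[stage] = full_prob

        upstream = mask
        box = mask_bounding_box(mask, margin)
        if box is None:
            upstream = None  # downstream stages short-circuit to empty

    labels = masks_to_labels(masks["whole"], masks["core"], masks["enhancing"])
    return labels, probs
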
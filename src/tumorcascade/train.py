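"""Training contract and evaluation metrics for the cascade stages.

Each stage/view pair gets its own network (nine models at full scale:
{WNet, TNet, ENet} × {axial, sagittal, coronal}), trained with Adam on a
soft Dice loss over foreground-biased patches.  Published-scale defaults:
batch size 5, weight decay 1e-7, learning rate 1e-3, 30k iterations, patch
sizes 144×144×19 (whole), 96×96×19 (core) and 64×64×19 (enhancing), with
C0 = 32 backbone channels — that scale is GPU-tier; the suite and the
examples use :meth:`TrainConfig.tiny` (tiny variant, small patches, a few
hundred iterations), which trains in minutes on one CPU core.

Downstream stages train inside the ground-truth bounding box of their
upstream structure (plus the cascade's context margin), matching what they
see at inference time.  Training-time augmentation reuses the exact
test-time-augmentation operations from :mod:`tumorcascade.tta` — a single
implementation for both, by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .backend import realize, softmax_channels
from .blueprint import make_blueprint
from .cascade import DEFAULT_MARGIN, mask_bounding_box, permute_to_view, sliding_window_infer, unpermute_from_view
from .config import spawn_seed
from .errors import FormatError, TrainingError, UndefinedDistanceError
from .tta import augment_case
from .volume_io import TASK_CODES, LabelVolume, MultiModalVolume

logger = logging.getLogger(__name__)

STAGE_VARIANTS = {"whole": "WNet", "core": "TNet", "enhancing": "ENet"}
STAGE_UPSTREAM = {"core": "whole", "enhancing": "core"}


@dataclass
class TrainConfig:
    """Hyper-parameters of one training run (defaults are published scale)."""

    stage_patch: dict = field(default_factory=lambda: {
        "whole": (144, 144, 19), "core": (96, 96, 19), "enhancing": (64, 64, 19)})
    batch_size: int = 5
    weight_decay: float = 1e-7
    learning_rate: float = 1e-3
    iterations: int = 30000
    n_tta: int = 20
    seed: int = 0
    augment: bool = True
    noise_std: float = 0.05
    tiny: bool = False  # use the tiny network variant for every stage
    C0: int | None = None  # backbone channels; variant default when None
    fg_bias: float = 0.5  # fraction of patches centred on a foreground voxel
    dice_squared: bool = True
    log_every: int = 50

    def __post_init__(self):
        if self.batch_size < 1:
            raise TrainingError("batch size must be >= 1")
        for stage, extent in self.stage_patch.items():
            if min(extent) < 1:
                raise TrainingError(f"non-positive patch extent for stage {stage}")

    @classmethod
    def tiny_config(cls, seed: int = 0, iterations: int = 300, **overrides):
        """Desk-scale configuration used throughout the test suite."""
        cfg = cls(
            stage_patch={"whole": (32, 32, 8), "core": (24, 24, 8), "enhancing": (16, 16, 8)},
            batch_size=4,
            iterations=iterations,
            seed=seed,
            tiny=True,
        )
        return replace(cfg, **overrides)

    def blueprint_for(self, stage: str):
        variant = "tiny" if self.tiny else STAGE_VARIANTS[stage]
        return make_blueprint(variant, C0=self.C0)


# ---------------------------------------------------------------------------
# losses and metrics
# ---------------------------------------------------------------------------


def dice_loss(prob_fg: np.ndarray, target: np.ndarray, eps: float = 1e-5,
              squared: bool = True) -> float:
    """Soft Dice loss 1 − (2Σpg + ε)/(Σp² + Σg² + ε) in [0, 1].

    ``squared=False`` switches the denominator to Σp + Σg.
    """
    p = np.asarray(prob_fg, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if p.shape != g.shape:
        raise FormatError(f"shape mismatch {p.shape} vs {g.shape}")
    num = 2.0 * (p * g).sum() + eps
    den = ((p * p).sum() + (g * g).sum() if squared else p.sum() + g.sum()) + eps
    return float(1.0 - num / den)


def _dice_loss_grad(p: np.ndarray, g: np.ndarray, eps: float, squared: bool):
    num = 2.0 * (p * g).sum() + eps
    den = ((p * p).sum() + (g * g).sum() if squared else p.sum() + g.sum()) + eps
    loss = 1.0 - num / den
    if squared:
        dp = -(2.0 * g * den - num * 2.0 * p) / den ** 2
    else:
        dp = -(2.0 * g * den - num) / den ** 2
    return float(loss), dp


def dice_score(a, b) -> float:
    """Hard Dice overlap 2|a∩b|/(|a|+|b|); both-empty := 1, one-empty := 0."""
    am = (a.mask if hasattr(a, "mask") else np.asarray(a)).astype(bool)
    bm = (b.mask if hasattr(b, "mask") else np.asarray(b)).astype(bool)
    if am.shape != bm.shape:
        raise FormatError(f"shape mismatch {am.shape} vs {bm.shape}")
    sa, sb = int(am.sum()), int(bm.sum())
    if sa == 0 and sb == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / (sa + sb)


def _surface_distances(src: np.ndarray, dst: np.ndarray, spacing) -> np.ndarray:
    """Distances from the surface voxels of src to the surface of dst."""
    dst_surface = dst & ~ndimage.binary_erosion(dst)
    src_surface = src & ~ndimage.binary_erosion(src)
    dist = ndimage.distance_transform_edt(~dst_surface, sampling=spacing)
    return dist[src_surface]


def hausdorff_distance(a, b, percentile: float = 100.0, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric (percentile) Hausdorff distance between mask surfaces, mm.

    ``percentile=95`` gives the robust HD95 convention; both 100 and 95 are
    supported because challenge reports vary.
    """
    am = (a.mask if hasattr(a, "mask") else np.asarray(a)).astype(bool)
    bm = (b.mask if hasattr(b, "mask") else np.asarray(b)).astype(bool)
    if not am.any() or not bm.any():
        raise UndefinedDistanceError("Hausdorff distance undefined for empty masks")
    d_ab = _surface_distances(am, bm, spacing)
    d_ba = _surface_distances(bm, am, spacing)
    if percentile >= 100:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


# ---------------------------------------------------------------------------
# patch sampling
# ---------------------------------------------------------------------------


def _stage_region(channels: np.ndarray, labels: np.ndarray, stage: str,
                  margin=DEFAULT_MARGIN):
    """Crop a case to the ground-truth upstream box for core/enhancing."""
    upstream = STAGE_UPSTREAM.get(stage)
    if upstream is None:
        return channels, labels
    mask = np.isin(labels, list(TASK_CODES[upstream])).astype(np.uint8)
    box = mask_bounding_box(mask, margin)
    if box is None:
        return channels, labels  # upstream structure absent; fall back to full grid
    sl = box.slices
    return channels[(slice(None),) + sl], labels[sl]


def sample_training_patch(volume: MultiModalVolume, labels: LabelVolume, stage: str,
                          rng: np.random.Generator, config: TrainConfig,
                          view: str = "axial"):
    """One (input, target) patch pair for a stage, in view axis order.

    The case is cropped to the upstream ground-truth box (core/enhancing
    stages), optionally augmented (shared TTA code path), permuted to the
    view, and a patch of the stage's extent is cut — centred on a random
    foreground voxel with probability ``fg_bias``, else uniformly.  Cases
    smaller than the patch are zero-padded (logged once per call site).
    """
    channels = volume.stacked().astype(np.float32)
    lab = labels.labels
    channels, lab = _stage_region(channels, lab, stage)
    if config.augment:
        channels, lab, _ = augment_case(channels, lab, rng, noise_std=config.noise_std)
    channels = permute_to_view(channels, view)
    lab = permute_to_view(lab, view)
    target = np.isin(lab, list(TASK_CODES[stage])).astype(np.float32)

    extent = tuple(int(e) for e in config.stage_patch[stage])
    shape = target.shape
    pad = [max(0, e - n) for e, n in zip(extent, shape)]
    if any(pad):
        logger.debug("padding case %s -> patch %s for stage %s", shape, extent, stage)
        pw = tuple((0, p) for p in pad)
        channels = np.pad(channels, ((0, 0),) + pw)
        target = np.pad(target, pw)
        shape = target.shape

    fg = np.argwhere(target > 0)
    if fg.size and rng.uniform() < config.fg_bias:
        center = fg[rng.integers(len(fg))]
        corner = [int(np.clip(c - e // 2, 0, n - e)) for c, e, n in zip(center, extent, shape)]
    else:
        corner = [int(rng.integers(0, n - e + 1)) for e, n in zip(extent, shape)]
    sl = tuple(slice(c, c + e) for c, e in zip(corner, extent))
    return channels[(slice(None),) + sl], target[sl]


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


class Adam:
    """Adaptive-moment estimation with decoupled-from-nothing L2 decay."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        for k, p in self.params.items():
            g = grads[k] + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class TrainedStagePredictor:
    """Callable stage predictor: region channels → foreground probability.

    Wraps a realized network with its view permutation and sliding-window
    tiling at the stage's training patch extent.
    """

    def __init__(self, network, stage: str, view: str, patch_extent, stride=None):
        self.network = network
        self.stage = stage
        self.view = view
        self.patch_extent = tuple(patch_extent)
        self.stride = stride

    def __call__(self, channels: np.ndarray) -> np.ndarray:
        x = permute_to_view(np.asarray(channels, dtype=np.float32), self.view)
        probs = sliding_window_infer(
            x, lambda patch: self.network.predict_proba(patch),
            self.patch_extent, stride=self.stride)
        return unpermute_from_view(probs[1], self.view)


def train_stage(cohort, stage: str, config: TrainConfig, view: str = "axial",
                blueprint=None, backend=None):
    """Train one stage/view model on a cohort of (volume, labels) pairs.

    ``cohort`` items may be (volume, labels) or (volume, labels, spec)
    tuples with *normalized* volumes.  Returns the fitted
    :class:`TrainedStagePredictor` and the loss log (list of (iteration,
    loss)).  Deterministic given ``config.seed``.
    """
    cases = [(c[0], c[1]) for c in cohort]
    bp = blueprint if blueprint is not None else config.blueprint_for(stage)
    net_seed = spawn_seed(config.seed, "train", stage, view)
    network = realize(bp, backend=backend, seed=net_seed)
    rng = np.random.default_rng(spawn_seed(config.seed, "sample", stage, view))
    opt = Adam(network.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)

    log = []
    for it in range(config.iterations):
        xs, ys = [], []
        for _ in range(config.batch_size):
            case = cases[rng.integers(len(cases))]
            x, y = sample_training_patch(case[0], case[1], stage, rng, config, view=view)
            xs.append(x)
            ys.append(y)
        x = np.stack(xs).astype(np.float32)
        g = np.stack(ys).astype(np.float64)

        network.zero_grad()
        scores = network.forward(x, training=True)
        probs = softmax_channels(scores.astype(np.float64), axis=1)
        p_fg = probs[:, 1]
        loss, dp_fg = _dice_loss_grad(p_fg, g, eps=1e-5, squared=config.dice_squared)
        if not np.isfinite(loss):
            raise TrainingError(f"loss diverged (non-finite) at iteration {it}")
        # softmax backward from d(loss)/d(p_fg) (background prob unused)
        dprobs = np.zeros_like(probs)
        dprobs[:, 1] = dp_fg
        inner = (dprobs * probs).sum(axis=1, keepdims=True)
        dscores = (probs * (dprobs - inner)).astype(np.float32)
        network.backward(dscores)
        opt.step(network.gradients())

        if it % config.log_every == 0 or it == config.iterations - 1:
            log.append((it, loss))
            logger.info("stage=%s view=%s iter=%d dice_loss=%.4f", stage, view, it, loss)

    predictor = TrainedStagePredictor(network, stage, view, config.stage_patch[stage])
    return predictor, log


def train_cascade(cohort, config: TrainConfig, views=("axial",)):
    """Train all three stages for the given views.

    Returns ``{stage: {view: TrainedStagePredictor}}``.
    """
    out = {}
    for stage in STAGE_VARIANTS:
        out[stage] = {}
        for view in views:
            predictor, _ = train_stage(cohort, stage, config, view=view)
            out[stage][view] = predictor
    return out
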
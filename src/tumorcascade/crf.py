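"""Pairwise CRF post-processing, with and without uncertainty gating.

Segmentation networks occasionally commit confidently to wrong labels; a
conditional random field can repair such regions by trading the network's
per-voxel beliefs (unary terms −ln p) against smoothness and appearance
evidence (pairwise Potts terms with Gaussian spatial and intensity
kernels).  The *uncertainty-aware* variant first resets both class
probabilities to 0.5 wherever the TTA voxel entropy exceeds a threshold
θ (default 0.2 nats, strict inequality), so the CRF is free to follow
image evidence exactly where the prediction set disagreed with itself; the
*naive* variant applies the CRF to the raw probabilities.

The model: for binary labeling y over voxels,

    E(y) = Σ_i −ln p_i(y_i)
         + Σ_{i<j} [y_i ≠ y_j] ( w_s exp(−d_ij²/2σ_γ²)
                               + w_a exp(−d_ij²/2σ_α² − (I_i−I_j)²/2σ_β²) )

with pairs restricted to a truncated Chebyshev window (long-range Gaussian
weights are negligible at desk-scale bandwidths), relaxed by parallel
mean-field iterations.  With all pairwise weights zero the mean field
reduces exactly to the unary argmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

from .errors import FormatError
from .volume_io import MultiModalVolume, TaskMask

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-6

#: Most contrastive modality per structure (appearance-kernel reference).
STRUCTURE_MODALITY = {"whole": "FLAIR", "core": "T1ce", "enhancing": "T1ce"}


@dataclass
class CrfParams:
    spatial_weight: float = 2.0
    spatial_sigma: float = 1.5  # voxels
    appearance_weight: float = 2.0
    appearance_sigma_spatial: float = 2.0  # voxels
    intensity_sigma: float = 0.5  # in units of the (normalized) image
    iterations: int = 5
    window_radius: int = 2  # Chebyshev truncation of the pairwise kernels
    theta: float = 0.2  # entropy gate threshold, nats

    def __post_init__(self):
        if self.spatial_weight < 0 or self.appearance_weight < 0:
            raise FormatError("pairwise weights must be >= 0")
        if self.iterations < 1:
            raise FormatError("mean-field iteration count must be >= 1")
        if self.theta < 0:
            raise FormatError("uncertainty threshold must be >= 0")


def _as_two_class(prob) -> np.ndarray:
    """Accept (2, X, Y, Z), a ProbabilityVolume, or a foreground grid."""
    if hasattr(prob, "probs"):
        prob = prob.probs
    p = np.asarray(prob, dtype=np.float64)
    if p.ndim == 3:
        p = np.stack([1.0 - p, p], axis=0)
    if p.ndim != 4 or p.shape[0] != 2:
        raise FormatError(f"expected binary class probabilities, got shape {p.shape}")
    return p


def uncertainty_gate(prob, entropy, theta: float = 0.2) -> np.ndarray:
    """Reset both class probabilities to 0.5 where entropy exceeds θ.

    Strictly greater than θ: a voxel at exactly the threshold is kept.
    Idempotent (the reset voxels stay reset).  Returns a (2, X, Y, Z)
    array.
    """
    p = _as_two_class(prob).copy()
    H = entropy.H if hasattr(entropy, "H") else np.asarray(entropy)
    if H.shape != p.shape[1:]:
        raise FormatError(f"entropy shape {H.shape} != probability shape {p.shape[1:]}")
    gate = H > theta
    p[:, gate] = 0.5
    return p


def _half_offsets(radius: int):
    """One representative of each unordered voxel-pair offset in the window."""
    offsets = []
    for off in product(range(-radius, radius + 1), repeat=3):
        if off == (0, 0, 0):
            continue
        if off > (0, 0, 0):  # lexicographic half-space
            offsets.append(off)
    return offsets


def _overlap_slices(shape, off):
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    return tuple(src), tuple(dst)


def _pair_kernels(image: np.ndarray, params: CrfParams):
    """Per-offset pairwise weight grids; shared by mean field and energy.

    Each Gaussian kernel is normalized over the truncated window, so
    ``spatial_weight`` (``appearance_weight``) is the *total* spatial
    (maximum total appearance) coupling a voxel feels from all its
    neighbours — directly comparable to the unary scale regardless of
    bandwidth or window radius.
    """
    offsets = _half_offsets(params.window_radius)
    d2s = [float(sum(o * o for o in off)) for off in offsets]
    gs = np.array([np.exp(-d2 / (2.0 * params.spatial_sigma ** 2)) for d2 in d2s])
    ga = np.array([np.exp(-d2 / (2.0 * params.appearance_sigma_spatial ** 2)) for d2 in d2s])
    gs_norm = 2.0 * gs.sum()  # both half-spaces
    ga_norm = 2.0 * ga.sum()
    kernels = []
    for off, g_s, g_a in zip(offsets, gs, ga):
        w_s = params.spatial_weight * g_s / gs_norm
        w_a = params.appearance_weight * g_a / ga_norm
        src, dst = _overlap_slices(image.shape, off)
        # weight grid lives on the dst (lower) voxel of each pair
        diff = image[dst] - image[src]
        w = w_s + w_a * np.exp(-(diff ** 2) / (2.0 * params.intensity_sigma ** 2))
        kernels.append((off, src, dst, w))
    return kernels


def _select_image(image, task: str | None) -> np.ndarray:
    if isinstance(image, MultiModalVolume):
        modality = STRUCTURE_MODALITY.get(task or "whole", "FLAIR")
        return np.asarray(image.channels[modality], dtype=np.float64)
    return np.asarray(image, dtype=np.float64)


def crf_energy(labeling: np.ndarray, prob, image, params: CrfParams,
               task: str | None = None) -> float:
    """Gibbs energy of a labeling: Σ −ln p + Σ pairwise Potts terms."""
    p = np.maximum(_as_two_class(prob), PROB_FLOOR)
    y = np.asarray(labeling).astype(np.int64)
    unary = -np.log(np.take_along_axis(p, y[None], axis=0)[0])
    energy = float(unary.sum())
    img = _select_image(image, task)
    for off, src, dst, w in _pair_kernels(img, params):
        energy += float((w * (y[dst] != y[src])).sum())
    return energy


def _label_costs(y: np.ndarray, unary: np.ndarray, kernels):
    """Per-voxel cost of assigning each label given the rest of labeling y."""
    cost = unary.copy()
    for off, src, dst, w in kernels:
        for lab in (0, 1):
            cost[lab][dst] += w * (y[src] != lab)
            cost[lab][src] += w * (y[dst] != lab)
    return cost


def _labeling_energy(y: np.ndarray, unary: np.ndarray, kernels) -> float:
    e = float(np.take_along_axis(unary, y[None].astype(np.int64), axis=0)[0].sum())
    for off, src, dst, w in kernels:
        e += float((w * (y[dst] != y[src])).sum())
    return e


def _mean_field(Q0: np.ndarray, neg_unary: np.ndarray, kernels, iterations: int):
    Q = Q0.copy()
    for _ in range(iterations):
        msg = np.zeros_like(Q)
        for off, src, dst, w in kernels:
            msg[:, *dst] += w[None] * Q[:, *src]
            msg[:, *src] += w[None] * Q[:, *dst]
        logits = neg_unary + msg
        logits -= logits.max(axis=0, keepdims=True)
        Q = np.exp(logits)
        Q /= Q.sum(axis=0, keepdims=True)
    return (Q[1] >= Q[0]).astype(np.uint8)


def _icm_polish(y: np.ndarray, unary: np.ndarray, kernels, radius: int,
                max_passes: int = 2) -> np.ndarray:
    """Monotone local descent (iterated conditional modes) after mean field.

    Voxels are partitioned into (radius+1)^3 congruence classes so that no
    two voxels of one class interact within the truncated window; updating
    a whole class in parallel is then exact coordinate descent and the
    Gibbs energy never increases.
    """
    y = y.copy()
    m = radius + 1
    grids = np.meshgrid(*[np.arange(n) % m for n in y.shape], indexing="ij")
    classes = [(grids[0] == a) & (grids[1] == b) & (grids[2] == c)
               for a in range(m) for b in range(m) for c in range(m)]
    for _ in range(max_passes):
        changed = False
        for cls in classes:
            cost = _label_costs(y, unary, kernels)
            new = (cost[1] <= cost[0]).astype(np.uint8)
            update = cls & (new != y)
            if update.any():
                y[update] = new[update]
                changed = True
        if not changed:
            break
    return y


def crf_refine(prob, image, params: CrfParams | None = None,
               task: str = "whole") -> TaskMask:
    """Approximate MAP labeling of the pairwise CRF; returns the mask.

    Inference is parallel mean field run from three initializations (the
    unary beliefs and foreground-/background-biased starts), each followed
    by a monotone local-descent (ICM) polish; the labeling with the lowest
    Gibbs energy wins.  The restarts and polish cost little at desk scale
    and avoid the poor fixed points plain mean field can reach when the
    coupling is strong.  ``image`` may be a :class:`MultiModalVolume` (the
    structure's most contrastive modality feeds the appearance kernel) or a
    scalar reference grid.  With all pairwise weights zero the result is
    exactly the unary argmax (ties toward foreground).
    """
    params = params or CrfParams()
    p = _as_two_class(prob)
    if (p <= 0).any():
        logger.info("flooring %d non-positive probabilities at %g", int((p <= 0).sum()), PROB_FLOOR)
    p = np.maximum(p, PROB_FLOOR)
    if params.spatial_weight == 0 and params.appearance_weight == 0:
        return TaskMask(task=task, mask=(p[1] >= p[0]).astype(np.uint8))

    img = _select_image(image, task)
    if img.shape != p.shape[1:]:
        raise FormatError(f"image shape {img.shape} != probability shape {p.shape[1:]}")
    kernels = _pair_kernels(img, params)
    neg_unary = np.log(p)
    unary = -neg_unary
    shape = p.shape[1:]

    inits = [
        p / p.sum(axis=0, keepdims=True),
        np.broadcast_to(np.array([0.05, 0.95])[:, None, None, None], p.shape).copy(),
        np.broadcast_to(np.array([0.95, 0.05])[:, None, None, None], p.shape).copy(),
    ]
    best_mask, best_energy = None, np.inf
    for Q0 in inits:
        y = _mean_field(Q0, neg_unary, kernels, params.iterations)
        y = _icm_polish(y, unary, kernels, params.window_radius)
        energy = _labeling_energy(y, unary, kernels)
        if energy < best_energy:
            best_energy, best_mask = energy, y
    return TaskMask(task=task, mask=best_mask.reshape(shape))


def uncertainty_aware_crf(prob, entropy, image, params: CrfParams | None = None,
                          task: str = "whole") -> TaskMask:
    """Entropy gate (reset to 0.5 above θ) followed by CRF refinement.

    With θ = ∞ or an all-zero entropy map this coincides with the naive
    CRF baseline ``crf_refine(prob, image, params)``.
    """
    params = params or CrfParams()
    gated = uncertainty_gate(prob, entropy, params.theta)
    return crf_refine(gated, image, params, task=task)
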
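"""Spatial/intensity augmentation and Monte-Carlo test-time augmentation.

One underlying anatomy can be observed under many acquisition conditions;
augmentation models this as a random spatial transform β composed of
per-axis rotations ``r``, per-axis flips ``f`` and an isotropic scale
``s``, plus additive intensity noise ``e``, with priors

    r ~ U(0, 2π)   per axis,
    f ~ Bern(0.5)  per axis,
    s ~ U(0.8, 1.2),
    e ~ N(0, std 0.05)   (on mean/std-normalized intensities).

The same sampled transforms serve training-time augmentation and test-time
augmentation (TTA): at test time the input is transformed N times (N = 20
by default), segmented, inverse-transformed back onto the original grid,
and the N aligned predictions are combined by majority voting.  The spread
of those predictions is what the uncertainty module turns into voxel-wise
entropy and structure-wise volume variation.

Transform composition (fixed convention): flips, then rotations in x→y→z
Euler order, then scaling, all about the volume centre; a single affine
resampling realizes the composition so the inverse is the exact inverse
affine.  Intensity noise acts on the network input only and needs no
inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyPredictionSetError, TransformError
from .volume_io import LabelVolume, MultiModalVolume

DEFAULT_N = 20  # Monte-Carlo simulation count
DEFAULT_NOISE_STD = 0.05

#: Vote precedence under ties: deeper (more specific) structures win, and in
#: the binary case 1 beats 0 — i.e. ties go to foreground.
_TIE_PRIORITY = {4: 3, 1: 2, 2: 1, 0: 0}


@dataclass(frozen=True)
class TransformParams:
    """One draw of the spatial transform β = (r, f, s)."""

    r: tuple  # rotation angle per axis, radians
    f: tuple  # flip per axis
    s: float  # isotropic scale factor

    def __post_init__(self):
        if not np.all(np.isfinite(self.r)):
            raise TransformError(f"non-finite rotation angles {self.r}")
        if not (np.isfinite(self.s) and self.s > 0):
            raise TransformError(f"scale must be finite and positive, got {self.s}")

    @classmethod
    def identity(cls):
        return cls(r=(0.0, 0.0, 0.0), f=(False, False, False), s=1.0)


def sample_transform(rng: np.random.Generator, scale_range=(0.8, 1.2),
                     in_plane_only: bool = False) -> TransformParams:
    """Draw β from its priors; ``in_plane_only`` restricts rotation to the
    through-plane axis (a conservative option for strongly anisotropic data)."""
    if in_plane_only:
        r = (0.0, 0.0, float(rng.uniform(0.0, 2.0 * np.pi)))
    else:
        r = tuple(float(a) for a in rng.uniform(0.0, 2.0 * np.pi, size=3))
    f = tuple(bool(b) for b in rng.uniform(size=3) < 0.5)
    s = float(rng.uniform(*scale_range))
    return TransformParams(r=r, f=f, s=s)


def _object_matrix(params: TransformParams) -> np.ndarray:
    """Coordinate map of the composition flips → Rx → Ry → Rz → scale."""
    rx, ry, rz = params.r
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    F = np.diag([-1.0 if flip else 1.0 for flip in params.f])
    return params.s * (Rz @ Ry @ Rx @ F)


def _resample(arr: np.ndarray, matrix: np.ndarray, interpolation: str) -> np.ndarray:
    if interpolation not in ("linear", "nearest"):
        raise TransformError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    center = (np.asarray(arr.shape[-3:], dtype=float) - 1.0) / 2.0
    offset = center - matrix @ center
    if arr.ndim == 4:
        return np.stack([
            ndimage.affine_transform(c, matrix, offset=offset, order=order,
                                     mode="constant", cval=0.0)
            for c in arr
        ])
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def apply_transform(arr: np.ndarray, params: TransformParams,
                    interpolation: str = "linear") -> np.ndarray:
    """Transform a 3D grid (or a (C, X, Y, Z) stack) by β about its centre.

    Out-of-grid regions are zero-filled; ``nearest`` interpolation is for
    label/probability grids.
    """
    # scipy's affine maps output coords to input coords => pass the inverse
    return _resample(np.asarray(arr), np.linalg.inv(_object_matrix(params)), interpolation)


def invert_transform(arr: np.ndarray, params: TransformParams,
                     interpolation: str = "linear") -> np.ndarray:
    """Undo :func:`apply_transform` so invert(apply(x)) ≈ x (exact for pure
    flips, interpolation-limited otherwise)."""
    return _resample(np.asarray(arr), _object_matrix(params), interpolation)


def add_noise(arr: np.ndarray, rng: np.random.Generator,
              std: float = DEFAULT_NOISE_STD) -> np.ndarray:
    """Additive i.i.d. Gaussian intensity noise, drawn independently per
    modality channel (expects normalized intensities)."""
    arr = np.asarray(arr)
    return arr + rng.normal(0.0, std, size=arr.shape).astype(arr.dtype)


@dataclass
class PredictionSet:
    """N segmentations of one case, re-aligned to the original grid."""

    members: list

    def __post_init__(self):
        if len(self.members) < 1:
            raise EmptyPredictionSetError("a prediction set needs at least one member")
        arrs = [m.labels if isinstance(m, LabelVolume) else np.asarray(m) for m in self.members]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise TransformError(f"prediction members disagree on shape: {shapes}")
        self.members = [a.astype(np.int16) for a in arrs]

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def shape(self) -> tuple:
        return self.members[0].shape

    def stacked(self) -> np.ndarray:
        return np.stack(self.members, axis=0)


def majority_vote(prediction_set: PredictionSet) -> np.ndarray:
    """Per-voxel modal label; ties resolve toward foreground (vote ≥ N/2),
    and among tumor codes toward the deeper structure."""
    stack = prediction_set.stacked()
    labels = sorted(np.unique(stack).tolist(),
                    key=lambda c: -_TIE_PRIORITY.get(int(c), 0))
    best_count = np.full(stack.shape[1:], -1, dtype=np.int32)
    vote = np.zeros(stack.shape[1:], dtype=np.int16)
    for code in labels:  # descending priority => strict > keeps the tie winner
        count = (stack == code).sum(axis=0).astype(np.int32)
        better = count > best_count
        vote[better] = code
        best_count[better] = count[better]
    return vote


def tta_predict(volume: MultiModalVolume, predictor, n: int = DEFAULT_N,
                rng: np.random.Generator | None = None,
                noise_std: float = DEFAULT_NOISE_STD,
                in_plane_only: bool = False,
                identity_transforms: bool = False):
    """Monte-Carlo test-time augmentation around ``predictor``.

    For each of ``n`` draws the input is transformed and noised, segmented
    by ``predictor`` (a callable MultiModalVolume → LabelVolume or label
    array), and the segmentation is inverse-transformed (nearest neighbour)
    back onto the original grid.  Returns the aligned
    :class:`PredictionSet` and its majority vote.  ``identity_transforms``
    pins β to the identity (noise still applies), which makes N=1 equal to
    a plain prediction.
    """
    if n < 1:
        raise EmptyPredictionSetError("tta_predict needs n >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    channels = volume.stacked().astype(np.float32)
    members = []
    for i in range(n):
        params = (TransformParams.identity() if identity_transforms
                  else sample_transform(rng, in_plane_only=in_plane_only))
        x = apply_transform(channels, params, "linear")
        if noise_std > 0:
            x = add_noise(x, rng, noise_std)
        try:
            pred = predictor(MultiModalVolume.from_stacked(x, spacing=volume.spacing))
        except Exception as exc:
            raise type(exc)(f"TTA draw {i}: {exc}") from exc
        labels = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
        aligned = invert_transform(labels.astype(np.float32), params, "nearest")
        members.append(np.rint(aligned).astype(np.int16))
    prediction_set = PredictionSet(members=members)
    vote = majority_vote(prediction_set)
    return prediction_set, LabelVolume(labels=vote, spacing=volume.spacing)


def augment_case(channels: np.ndarray, labels: np.ndarray | None,
                 rng: np.random.Generator, noise_std: float = DEFAULT_NOISE_STD,
                 in_plane_only: bool = False):
    """Training-time augmentation of one case (same ops as TTA, by design).

    Intensities are transformed with linear interpolation and noised;
    labels follow the identical spatial transform with nearest neighbour.
    """
    params = sample_transform(rng, in_plane_only=in_plane_only)
    x = apply_transform(np.asarray(channels), params, "linear")
    if noise_std > 0:
        x = add_noise(x, rng, noise_std)
    y = None
    if labels is not None:
        y = np.rint(apply_transform(np.asarray(labels, dtype=np.float32), params,
                                    "nearest")).astype(np.int16)
    return x, y, params
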
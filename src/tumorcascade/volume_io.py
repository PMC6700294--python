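"""Reading, writing and label plumbing for BraTS-style multi-modal cases.

A *case* is a directory holding one NIfTI volume per MRI modality (FLAIR, T1,
T1ce, T2), co-registered, skull-stripped and resampled to a common grid, plus
an optional integer segmentation using the BraTS label codes

* ``1`` – non-enhancing / necrotic tumor core
* ``2`` – peritumoral edema
* ``4`` – enhancing tumor core

The cascade never works on the 4-code alphabet directly; it works on three
nested binary tasks (*whole tumor* ⊇ *tumor core* ⊇ *enhancing core*).  The
conversions between the two representations live here and are exactly
inverse to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import DegenerateInputError, FormatError, MissingModalityError

MODALITIES = ("FLAIR", "T1", "T1ce", "T2")

#: Default file-name suffix per modality: ``<case_id>_<suffix>.nii.gz``
DEFAULT_SUFFIXES: Mapping[str, str] = {
    "FLAIR": "flair",
    "T1": "t1",
    "T1ce": "t1ce",
    "T2": "t2",
}
SEG_SUFFIX = "seg"

TASKS = ("whole", "core", "enhancing")
#: BraTS codes belonging to each hierarchical binary task.
TASK_CODES: Mapping[str, frozenset] = {
    "whole": frozenset({1, 2, 4}),
    "core": frozenset({1, 4}),
    "enhancing": frozenset({4}),
}
VALID_CODES = frozenset({0, 1, 2, 4})


@dataclass
class MultiModalVolume:
    """Four aligned scalar 3D grids, one per MRI modality, for one patient.

    ``spacing`` is millimetres per voxel along each axis (BraTS inputs are
    1 mm isotropic).  ``affine`` is carried through from NIfTI when a case is
    loaded from disk so outputs can be written back in the same frame.
    """

    channels: dict
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        missing = [m for m in MODALITIES if m not in self.channels]
        if missing:
            raise MissingModalityError(f"missing modalities: {missing}")
        shapes = {m: self.channels[m].shape for m in MODALITIES}
        if len(set(shapes.values())) != 1:
            raise FormatError(f"modality shape mismatch: {shapes}")
        for m in MODALITIES:
            arr = np.asarray(self.channels[m])
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"non-finite values in modality {m}")
            self.channels[m] = arr

    @property
    def shape(self) -> tuple:
        return self.channels["FLAIR"].shape

    def stacked(self) -> np.ndarray:
        """Channels stacked into a (4, X, Y, Z) array, modality order fixed."""
        return np.stack([self.channels[m] for m in MODALITIES], axis=0)

    @classmethod
    def from_stacked(cls, arr: np.ndarray, spacing=(1.0, 1.0, 1.0), affine=None):
        if arr.ndim != 4 or arr.shape[0] != len(MODALITIES):
            raise FormatError(f"expected (4, X, Y, Z) array, got {arr.shape}")
        return cls(
            channels={m: np.asarray(arr[i]) for i, m in enumerate(MODALITIES)},
            spacing=tuple(spacing),
            affine=affine,
        )


@dataclass
class LabelVolume:
    """Integer segmentation on the BraTS 4-code alphabet {0, 1, 2, 4}."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.labels)
        codes = set(np.unique(arr).tolist())
        bad = codes - VALID_CODES
        if bad:
            raise FormatError(f"invalid label codes {sorted(bad)}; allowed {sorted(VALID_CODES)}")
        self.labels = arr.astype(np.int16)

    @property
    def shape(self) -> tuple:
        return self.labels.shape


@dataclass
class TaskMask:
    """Binary projection of a segmentation onto one hierarchical task."""

    task: str
    mask: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.task not in TASKS:
            raise FormatError(f"unknown task {self.task!r}; expected one of {TASKS}")
        arr = np.asarray(self.mask)
        if not np.isin(arr, (0, 1)).all():
            raise FormatError("task mask must be binary")
        self.mask = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.mask.shape


def _find_file(case_dir: Path, suffix: str):
    hits = sorted(case_dir.glob(f"*_{suffix}.nii.gz")) + sorted(case_dir.glob(f"*_{suffix}.nii"))
    return hits[0] if hits else None


def load_case(case_path, suffixes: Mapping[str, str] | None = None):
    """Load one BraTS-layout case directory.

    Returns ``(MultiModalVolume, LabelVolume | None)``; the label volume is
    attached when a ``*_seg`` NIfTI is present.
    """
    case_dir = Path(case_path)
    if not case_dir.is_dir():
        raise MissingModalityError(f"case directory not found: {case_dir}")
    suffixes = dict(DEFAULT_SUFFIXES if suffixes is None else suffixes)

    channels = {}
    affine = None
    spacing = (1.0, 1.0, 1.0)
    for modality in MODALITIES:
        path = _find_file(case_dir, suffixes[modality])
        if path is None:
            raise MissingModalityError(
                f"modality {modality} (suffix {suffixes[modality]!r}) missing in {case_dir}"
            )
        img = nib.load(str(path))
        channels[modality] = np.asarray(img.dataobj, dtype=np.float32)
        affine = img.affine
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    volume = MultiModalVolume(channels=channels, spacing=spacing, affine=affine)

    labels = None
    seg_path = _find_file(case_dir, SEG_SUFFIX)
    if seg_path is not None:
        seg = np.asarray(nib.load(str(seg_path)).dataobj)
        seg = np.rint(seg).astype(np.int16)
        if seg.shape != volume.shape:
            raise FormatError(f"segmentation shape {seg.shape} != modality shape {volume.shape}")
        labels = LabelVolume(labels=seg, spacing=spacing)
    return volume, labels


def save_case(case_dir, case_id: str, volume: MultiModalVolume, labels: LabelVolume | None = None,
              suffixes: Mapping[str, str] | None = None) -> Path:
    """Write a case in BraTS layout ``<case_dir>/<case_id>_<suffix>.nii.gz``."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    suffixes = dict(DEFAULT_SUFFIXES if suffixes is None else suffixes)
    affine = volume.affine
    if affine is None:
        affine = np.diag(list(volume.spacing) + [1.0])
    for modality in MODALITIES:
        img = nib.Nifti1Image(volume.channels[modality].astype(np.float32), affine)
        nib.save(img, str(case_dir / f"{case_id}_{suffixes[modality]}.nii.gz"))
    if labels is not None:
        img = nib.Nifti1Image(labels.labels.astype(np.int16), affine)
        nib.save(img, str(case_dir / f"{case_id}_{SEG_SUFFIX}.nii.gz"))
    return case_dir


def save_scalar_volume(path, data: np.ndarray, spacing=(1.0, 1.0, 1.0), affine=None):
    """Write one scalar grid (probability, entropy, labels) as NIfTI."""
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def normalize_case(volume: MultiModalVolume, region: str = "brain") -> MultiModalVolume:
    """Standardize each modality to zero mean, unit (population) std.

    ``region="brain"`` computes the statistics over the nonzero voxels only —
    skull-stripped background would otherwise dominate — and keeps background
    voxels at exactly zero.  ``region="volume"`` uses every voxel.
    """
    if region not in ("brain", "volume"):
        raise ValueError(f"region must be 'brain' or 'volume', got {region!r}")
    out = {}
    for modality in MODALITIES:
        data = volume.channels[modality].astype(np.float64)
        if region == "brain":
            fg = data != 0
            if not fg.any():
                raise DegenerateInputError(f"modality {modality} is identically zero")
            values = data[fg]
        else:
            fg = np.ones(data.shape, dtype=bool)
            values = data.ravel()
        std = float(values.std())  # population std
        if std <= 0:
            raise DegenerateInputError(f"modality {modality} has zero std over the {region} region")
        normalized = np.zeros_like(data)
        normalized[fg] = (data[fg] - float(values.mean())) / std
        out[modality] = normalized.astype(np.float32)
    return MultiModalVolume(channels=out, spacing=volume.spacing, affine=volume.affine)


def labels_to_task_mask(labels: LabelVolume, task: str) -> TaskMask:
    """Project a 4-code segmentation onto one hierarchical binary task."""
    if task not in TASKS:
        raise FormatError(f"unknown task {task!r}")
    codes = TASK_CODES[task]
    mask = np.isin(labels.labels, list(codes)).astype(np.uint8)
    return TaskMask(task=task, mask=mask, spacing=labels.spacing)


def masks_to_labels(whole: TaskMask, core: TaskMask, enhancing: TaskMask) -> LabelVolume:
    """Recombine the three binary tasks into a 4-code segmentation.

    Nesting is enforced by crisp-mask intersection (core within whole,
    enhancing within core) before mapping, mirroring the cascade semantics:
    enhancing→4, rest of core→1, rest of whole→2.
    """
    if not (whole.shape == core.shape == enhancing.shape):
        raise FormatError(
            f"mask shape mismatch: whole {whole.shape}, core {core.shape}, "
            f"enhancing {enhancing.shape}"
        )
    w = whole.mask.astype(bool)
    c = core.mask.astype(bool) & w
    e = enhancing.mask.astype(bool) & c
    labels = np.zeros(whole.shape, dtype=np.int16)
    labels[w] = 2
    labels[c] = 1
    labels[e] = 4
    return LabelVolume(labels=labels, spacing=whole.spacing)
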
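"""Synthetic multi-modal phantoms with nested tumor subregions.

The generator emulates the geometry and contrast conventions of skull-stripped
multi-modal brain MRI: a large "brain" ellipsoid of roughly constant tissue
intensity on a zero background, containing three nested tumor ellipsoids
(enhancing core ⊆ tumor core ⊆ whole tumor, BraTS codes 4/1/2 for the
enhancing core, the rest of the core, and the edema shell respectively).
FLAIR and T2 are bright over the whole tumor, T1ce is bright over the
enhancing core only, and T1 shows mild hypointensity — the modality contrast
pattern radiologists rely on.  Additive Gaussian intensity noise is drawn
i.i.d. per modality inside the brain (background stays exactly zero, as after
skull stripping).

Ellipsoids are used deliberately: their analytic volumes give oracle checks
for every downstream stage.  An optional smooth random deformation roughens
the boundaries for harder tests; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .volume_io import MODALITIES, LabelVolume, MultiModalVolume, save_case

#: Baseline tissue intensity per modality (arbitrary scanner units).
DEFAULT_BASE = {"FLAIR": 100.0, "T1": 110.0, "T1ce": 110.0, "T2": 95.0}

#: Additive intensity offsets per modality and tumor region.
DEFAULT_CONTRAST = {
    "FLAIR": {"edema": 60.0, "core": 40.0, "enhancing": 40.0},
    "T2": {"edema": 55.0, "core": 35.0, "enhancing": 30.0},
    "T1": {"edema": -15.0, "core": -25.0, "enhancing": -10.0},
    "T1ce": {"edema": -5.0, "core": -15.0, "enhancing": 70.0},
}


@dataclass
class PhantomSpec:
    """Full description of one synthetic case; deterministic given ``seed``."""

    shape: tuple = (64, 64, 32)
    center: tuple | None = None  # tumor centroid in voxels; grid centre if None
    radii_whole: tuple = (12.0, 11.0, 7.0)
    radii_core: tuple = (8.0, 7.0, 5.0)
    radii_enh: tuple = (5.0, 4.0, 3.0)  # all-zero => LGG-like, no enhancing core
    brain_radii: tuple | None = None  # defaults to 45% of shape
    base: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE))
    contrast: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CONTRAST.items()}
    )
    noise_std: float = 5.0
    deform_amplitude: float = 0.0  # voxels; 0 disables the deformation field
    deform_smoothness: float = 6.0  # Gaussian sigma of the displacement field
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or min(shape) < 8:
            raise PhantomSpecError(f"shape must be 3D with extents >= 8, got {self.shape}")
        self.shape = shape
        if self.center is None:
            self.center = tuple((s - 1) / 2.0 for s in shape)
        if self.brain_radii is None:
            self.brain_radii = tuple(0.45 * s for s in shape)
        if self.noise_std < 0:
            raise PhantomSpecError("noise_std must be >= 0")
        rw, rc, re = (np.asarray(r, dtype=float) for r in
                      (self.radii_whole, self.radii_core, self.radii_enh))
        if np.any(rw <= 0) or np.any(rc <= 0):
            raise PhantomSpecError("whole/core radii must be positive")
        if np.any(re < 0):
            raise PhantomSpecError("enhancing radii must be >= 0")
        if np.any(re > rc + 1e-9) or np.any(rc > rw + 1e-9):
            raise PhantomSpecError(
                "radii must nest componentwise: enhancing <= core <= whole "
                f"(got {self.radii_enh} / {self.radii_core} / {self.radii_whole})"
            )
        lo = np.asarray(self.center) - rw
        hi = np.asarray(self.center) + rw
        if np.any(lo < 0) or np.any(hi > np.asarray(shape) - 1):
            raise PhantomSpecError("whole-tumor ellipsoid does not fit inside the grid")

    @property
    def is_lgg_like(self) -> bool:
        """True when the enhancing region is empty (as in many LGG)."""
        return float(np.max(self.radii_enh)) == 0.0


def _coordinate_grids(spec: PhantomSpec, rng: np.random.Generator):
    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in spec.shape], indexing="ij")
    if spec.deform_amplitude > 0:
        deformed = []
        for axis_coord in coords:
            disp = rng.standard_normal(spec.shape)
            disp = ndimage.gaussian_filter(disp, spec.deform_smoothness)
            peak = np.abs(disp).max()
            if peak > 0:
                disp *= spec.deform_amplitude / peak
            deformed.append(axis_coord + disp)
        coords = deformed
    return coords


def _ellipsoid(coords, center, radii) -> np.ndarray:
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        return np.zeros(coords[0].shape, dtype=bool)
    acc = np.zeros(coords[0].shape, dtype=np.float64)
    for axis in range(3):
        acc += ((coords[axis] - center[axis]) / radii[axis]) ** 2
    return acc <= 1.0


def generate_case(spec: PhantomSpec):
    """Render one phantom; returns ``(MultiModalVolume, LabelVolume)``."""
    rng = np.random.default_rng(spec.seed)
    coords = _coordinate_grids(spec, rng)

    brain_center = tuple((s - 1) / 2.0 for s in spec.shape)
    brain = _ellipsoid(coords, brain_center, spec.brain_radii)
    whole = _ellipsoid(coords, spec.center, spec.radii_whole)
    core = _ellipsoid(coords, spec.center, spec.radii_core) & whole
    enh = _ellipsoid(coords, spec.center, spec.radii_enh) & core
    brain |= whole  # tumor is always brain tissue

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[whole] = 2
    labels[core] = 1
    labels[enh] = 4

    channels = {}
    for modality in MODALITIES:
        img = np.zeros(spec.shape, dtype=np.float64)
        img[brain] = spec.base[modality]
        offsets = spec.contrast[modality]
        img[whole & ~core] += offsets["edema"]
        img[core & ~enh] += offsets["core"]
        img[enh] += offsets["enhancing"]
        if spec.noise_std > 0:
            noise = rng.normal(0.0, spec.noise_std, size=spec.shape)
            img[brain] += noise[brain]
        channels[modality] = img.astype(np.float32)

    volume = MultiModalVolume(channels=channels, spacing=spec.spacing)
    return volume, LabelVolume(labels=labels, spacing=spec.spacing)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    lgg_fraction: float = 0.25,
    center_jitter: tuple = (6.0, 6.0, 3.0),
    radius_scale_range: tuple = (0.75, 1.2),
    contrast_scale_range: tuple = (0.8, 1.2),
):
    """Generate ``n`` randomized cases around ``base_spec``.

    A ``lgg_fraction`` minority of cases has an empty enhancing region, so the
    last cascade stage's empty-target path is exercised.  Reproducible given
    ``seed``; case ``i`` uses the derived seed ``seed + i`` inside its spec.
    """
    if n < 1:
        raise PhantomSpecError("cohort size must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        jitter = rng.uniform(-1, 1, size=3) * np.asarray(center_jitter)
        rscale = rng.uniform(*radius_scale_range)
        cscale = rng.uniform(*contrast_scale_range)
        lgg = bool(rng.uniform() < lgg_fraction)

        center = np.asarray(base.center) + jitter
        rw = np.asarray(base.radii_whole) * rscale
        # keep the tumor inside the grid
        upper = np.asarray(base.shape) - 1.0
        center = np.clip(center, rw, upper - rw)
        contrast = {
            m: {k: v * cscale for k, v in offs.items()} for m, offs in base.contrast.items()
        }
        spec = replace(
            base,
            center=tuple(center),
            radii_whole=tuple(rw),
            radii_core=tuple(np.asarray(base.radii_core) * rscale),
            radii_enh=(0.0, 0.0, 0.0) if lgg else tuple(np.asarray(base.radii_enh) * rscale),
            contrast=contrast,
            seed=int(seed + i),
        )
        volume, labels = generate_case(spec)
        cases.append((volume, labels, spec))
    return cases


def write_cohort(out_dir, cases: Sequence, prefix: str = "case") -> Path:
    """Write a cohort in BraTS layout plus a tab-separated manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["case_id\tseed\tlgg_like\tnoise_std"]
    for i, (volume, labels, spec) in enumerate(cases):
        case_id = f"{prefix}_{i:03d}"
        save_case(out_dir / case_id, case_id, volume, labels)
        rows.append(f"{case_id}\t{spec.seed}\t{int(spec.is_lgg_like)}\t{spec.noise_std:g}")
    (out_dir / "manifest.tsv").write_text("\n".join(rows) + "\n")
    return out_dir
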
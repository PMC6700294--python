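"""Aleatoric uncertainty from test-time-augmentation prediction sets.

Two complementary summaries of the N aligned TTA predictions:

* **Voxel-wise entropy.**  At voxel *i* the N members provide an empirical
  distribution p̂ over labels; the uncertainty is the entropy
  H_i = −Σ_m p̂_m ln p̂_m (natural log, 0·ln 0 := 0).  H is zero where all
  members agree and maximal (ln of the number of distinct labels) under
  uniform disagreement.

* **Structure-wise volume variation coefficient (VVC).**  For a structure,
  each member has a volume v_i (positive-voxel count times voxel volume);
  with mean μ_V and population standard deviation σ_V over the N members,
  VVC = σ_V / μ_V.  Being a ratio, VVC is invariant to the volume unit.

Entropy is computed per hierarchical binary structure (three maps, matching
the cascade's binary outputs); a combined-alphabet entropy over the raw
label codes is available for multi-class predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyPredictionSetError, UndefinedStructureError
from .tta import PredictionSet, majority_vote
from .volume_io import TASK_CODES, TASKS, LabelVolume

logger = logging.getLogger(__name__)


@dataclass
class UncertaintyMap:
    """Voxel-wise entropy H (nats), bounded by ln(N) for N members."""

    H: np.ndarray
    n_members: int

    def __post_init__(self):
        h = np.asarray(self.H)
        if h.min() < -1e-9 or h.max() > np.log(max(self.n_members, 2)) + 1e-6:
            raise ValueError("entropy outside [0, ln N]")
        self.H = np.maximum(h, 0.0)


@dataclass
class StructureUncertainty:
    volumes: np.ndarray  # v_1..v_N
    mu: float
    sigma: float
    vvc: float


def _member_stack(prediction_set: PredictionSet, structure: str | None) -> np.ndarray:
    stack = prediction_set.stacked()
    if structure is None:
        return stack
    if structure not in TASKS:
        raise ValueError(f"unknown structure {structure!r}; expected one of {TASKS}")
    return np.isin(stack, list(TASK_CODES[structure])).astype(np.int16)


def voxel_entropy(prediction_set: PredictionSet, structure: str | None = None) -> UncertaintyMap:
    """Entropy of the empirical label distribution at each voxel.

    With ``structure`` given, members are first projected onto that binary
    task; with ``structure=None`` the entropy is taken over the raw label
    alphabet (multi-class mode).
    """
    if prediction_set.n < 1:
        raise EmptyPredictionSetError("empty prediction set")
    stack = _member_stack(prediction_set, structure)
    n = stack.shape[0]
    H = np.zeros(stack.shape[1:], dtype=np.float64)
    for code in np.unique(stack):
        p = (stack == code).sum(axis=0) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, -p * np.log(p), 0.0)
        H += term
    return UncertaintyMap(H=H, n_members=n)


def structure_volumes(prediction_set: PredictionSet, structure: str,
                      voxel_volume_mm3: float = 1.0) -> np.ndarray:
    """Per-member volume of one structure (voxel count × voxel volume)."""
    stack = _member_stack(prediction_set, structure)
    return stack.reshape(stack.shape[0], -1).sum(axis=1).astype(np.float64) * voxel_volume_mm3


def vvc(volumes, population: bool = True) -> float:
    """Volume variation coefficient σ_V / μ_V of a set of volumes.

    Population (divide-by-N) standard deviation by default, matching the
    variation-coefficient convention; raises
    :class:`UndefinedStructureError` when the mean volume is zero (structure
    absent in every member), so callers can report "structure absent"
    instead of a number.
    """
    v = np.asarray(volumes, dtype=np.float64)
    mu = float(v.mean())
    if mu <= 0:
        raise UndefinedStructureError("VVC undefined: structure absent in all members")
    sigma = float(v.std(ddof=0 if population else 1))
    return sigma / mu


def structure_uncertainty(prediction_set: PredictionSet, structure: str,
                          voxel_volume_mm3: float = 1.0,
                          population: bool = True) -> StructureUncertainty:
    v = structure_volumes(prediction_set, structure, voxel_volume_mm3)
    mu = float(v.mean())
    if mu <= 0:
        raise UndefinedStructureError(f"structure {structure!r} absent in all members")
    sigma = float(v.std(ddof=0 if population else 1))
    return StructureUncertainty(volumes=v, mu=mu, sigma=sigma, vvc=sigma / mu)


def error_vs_vvc_table(prediction_sets: dict, ground_truth: dict) -> pd.DataFrame:
    """Per-case, per-structure segmentation error (1−Dice) against VVC.

    ``prediction_sets`` maps case id → :class:`PredictionSet` of label
    volumes; ``ground_truth`` maps case id → :class:`LabelVolume`.  The
    per-case segmentation is the majority vote of the set.  Structures
    absent in both the vote and the truth are skipped with a logged note.
    """
    from .train import dice_score  # local import: train also imports metrics' users

    rows = []
    for case_id, pset in prediction_sets.items():
        truth = ground_truth[case_id]
        truth_labels = truth.labels if isinstance(truth, LabelVolume) else np.asarray(truth)
        vote = majority_vote(pset)
        for structure in TASKS:
            codes = list(TASK_CODES[structure])
            pred_mask = np.isin(vote, codes)
            true_mask = np.isin(truth_labels, codes)
            if not pred_mask.any() and not true_mask.any():
                logger.info("case %s: structure %s absent in prediction and truth; skipped",
                            case_id, structure)
                continue
            member_mask = _member_stack(pset, structure)
            volumes = member_mask.reshape(pset.n, -1).sum(axis=1).astype(np.float64)
            mu = float(volumes.mean())
            sigma = float(volumes.std())
            rows.append({
                "case": case_id,
                "structure": structure,
                "mu": mu,
                "sigma": sigma,
                "vvc": sigma / mu if mu > 0 else np.nan,
                "dice": dice_score(pred_mask, true_mask),
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["error"] = 1.0 - table["dice"]
    return table


def vvc_error_correlation(table: pd.DataFrame) -> dict:
    """Spearman rank correlation between VVC and 1−Dice, per structure."""
    out = {}
    for structure, group in table.dropna(subset=["vvc"]).groupby("structure"):
        if len(group) < 3:
            continue
        if group["vvc"].nunique() == 1 or group["error"].nunique() == 1:
            logger.info("structure %s: constant VVC or error; correlation undefined", structure)
            continue
        out[structure] = float(stats.spearmanr(group["vvc"], group["error"]).statistic)
    return out
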
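"""End-to-end wiring: model persistence, cascade prediction, uncertainty,
and uncertainty-aware post-processing for whole cases.

This module composes the building blocks (cascade, TTA, uncertainty, CRF)
into the case-level operations the CLI and the examples use; everything
here is a thin, documented composition — the science lives in the modules
it imports.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .backend import realize
from .blueprint import make_blueprint
from .cascade import DEFAULT_MARGIN, multiview_predict, run_cascade
from .crf import CrfParams, crf_refine, uncertainty_aware_crf
from .errors import ConfigError
from .train import STAGE_VARIANTS, TrainedStagePredictor
from .tta import tta_predict
from .uncertainty import structure_uncertainty, voxel_entropy
from .volume_io import TASKS, LabelVolume, MultiModalVolume, TaskMask, masks_to_labels, labels_to_task_mask


def save_stage_predictor(model_dir, predictor: TrainedStagePredictor):
    """Persist one stage/view model: npz weights + JSON metadata sidecar."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{predictor.stage}_{predictor.view}"
    net = predictor.network
    np.savez(model_dir / f"{stem}.npz", **net.state_dict())
    meta = {
        "stage": predictor.stage,
        "view": predictor.view,
        "variant": net.blueprint.variant,
        "C0": net.blueprint.C0,
        "Cl": net.blueprint.Cl,
        "dilation_schedule": list(net.blueprint.dilation_schedule),
        "seed": net.seed,
        "patch_extent": list(predictor.patch_extent),
    }
    (model_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))


def load_stage_predictor(model_dir, stage: str, view: str) -> TrainedStagePredictor:
    model_dir = Path(model_dir)
    stem = f"{stage}_{view}"
    meta_path = model_dir / f"{stem}.json"
    if not meta_path.exists():
        raise ConfigError(f"no model for stage {stage!r} view {view!r} in {model_dir}")
    meta = json.loads(meta_path.read_text())
    bp = make_blueprint(meta["variant"], C0=meta["C0"], Cl=meta["Cl"],
                        dilation_schedule=meta["dilation_schedule"])
    net = realize(bp, seed=meta["seed"])
    with np.load(model_dir / f"{stem}.npz") as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return TrainedStagePredictor(net, stage, view, meta["patch_extent"])


def save_cascade(model_dir, predictors: dict):
    for stage, by_view in predictors.items():
        for view, predictor in by_view.items():
            save_stage_predictor(model_dir, predictor)


def load_cascade(model_dir, views=("axial",)) -> dict:
    return {stage: {view: load_stage_predictor(model_dir, stage, view) for view in views}
            for stage in STAGE_VARIANTS}


def _fuse_views(by_view: dict):
    """Single-view predictors pass through; several views softmax-average."""
    if len(by_view) == 1:
        return next(iter(by_view.values()))
    return lambda channels: multiview_predict(channels, by_view)


def cascade_predictor(predictors: dict, margin=DEFAULT_MARGIN):
    """A callable MultiModalVolume → LabelVolume from stage/view models."""
    stage_fns = {stage: _fuse_views(by_view) for stage, by_view in predictors.items()}

    def predict(volume: MultiModalVolume) -> LabelVolume:
        labels, _ = run_cascade(volume, stage_fns, margin=margin)
        return labels

    return predict


def predict_case(volume: MultiModalVolume, predictors: dict, margin=DEFAULT_MARGIN):
    """Plain (no TTA) cascade prediction; returns labels and stage probs."""
    stage_fns = {stage: _fuse_views(by_view) for stage, by_view in predictors.items()}
    return run_cascade(volume, stage_fns, margin=margin)


def predict_with_uncertainty(volume: MultiModalVolume, predictors: dict, n_tta: int,
                             rng, margin=DEFAULT_MARGIN, noise_std: float = 0.05):
    """TTA-based prediction with voxel- and structure-wise uncertainty.

    Returns ``(vote labels, prediction set, {structure: entropy map},
    {structure: StructureUncertainty | None})`` — ``None`` marks a
    structure absent from every TTA member.
    """
    predictor = cascade_predictor(predictors, margin=margin)
    pset, vote = tta_predict(volume, predictor, n=n_tta, rng=rng, noise_std=noise_std)
    entropy = {s: voxel_entropy(pset, structure=s) for s in TASKS}
    structure = {}
    for s in TASKS:
        try:
            structure[s] = structure_uncertainty(pset, s)
        except Exception:
            structure[s] = None
    return vote, pset, entropy, structure


def postprocess_case(volume: MultiModalVolume, stage_probs: dict, entropy: dict,
                     params: CrfParams | None = None, gated: bool = True) -> LabelVolume:
    """CRF post-processing of the three binary structures, then re-nesting.

    ``gated=True`` applies the uncertainty-aware variant (entropy gate then
    CRF); ``gated=False`` is the naive CRF baseline.  Refinement runs per
    binary structure and the hierarchy is restored by crisp re-nesting.
    """
    params = params or CrfParams()
    refined = {}
    for s in TASKS:
        prob = stage_probs[s]
        if gated:
            refined[s] = uncertainty_aware_crf(prob, entropy[s], volume, params, task=s)
        else:
            refined[s] = crf_refine(prob, volume, params, task=s)
    return masks_to_labels(refined["whole"], refined["core"], refined["enhancing"])
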
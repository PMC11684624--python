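"""End-to-end orchestration: convert -> predict -> invert -> evaluate.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn``-style child derivation
(documented rule: child k of the pipeline seed), so every stage remains
individually reproducible from the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .calibration import PiecewiseCalibration
from .image import CTImage
from .metrics import ImagePair, MetricConfig, metric_report
from .transfer import (CouchRemovalParams, DenoiseParams, NoiseModel,
                       convert_pct_to_pseudo_dect, invert_to_planning_ct)
from .vncnet import VNCNet, predict as predict_ct

#: Stage order of the forward pipeline.
STAGES = ("convert", "predict", "invert")


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Derive a per-stage seed (child ``stage_index`` of the global seed)."""
    child = np.random.SeedSequence(global_seed).spawn(stage_index + 1)[-1]
    return int(child.generate_state(1, np.uint32)[0] % (2 ** 31))


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class PipelineConfig:
    """Everything a full run needs, with one global seed."""

    calibration: PiecewiseCalibration = field(default_factory=PiecewiseCalibration.default)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    noise: NoiseModel | None = None  # None -> 40 dB with a derived seed
    couch: CouchRemovalParams = field(default_factory=CouchRemovalParams)
    metric: MetricConfig = field(default_factory=MetricConfig)
    rng_seed: int = 0


def run_full_pipeline(cfg: PipelineConfig, ce_pct: CTImage, model: VNCNet | None):
    """CE planning CT -> pseudo-DECT -> network VNC -> VNC planning CT.

    ``model=None`` skips the network stage (the pure domain-transfer round
    trip). Returns ``(vnc_pct, manifest)``; the manifest logs per-stage
    seeds, parameters and input/output checksums, and any stage error is
    re-raised with the stage name attached.
    """
    if model is not None and not hasattr(model, "model_"):
        raise ValueError("model checkpoint is not fitted/loaded")
    manifest = {"rng_seed": cfg.rng_seed, "stages": {}}
    noise = cfg.noise
    if noise is None:
        noise = NoiseModel(target_snr_db=40.0, rng_seed=stage_seed(cfg.rng_seed, 0))

    stage = "convert"
    try:
        pseudo, record = convert_pct_to_pseudo_dect(
            ce_pct, calib=cfg.calibration, denoise=cfg.denoise,
            noise=noise, couch=cfg.couch)
        manifest["stages"][stage] = {
            "params": record.params,
            "in_checksum": _checksum(ce_pct.voxels),
            "out_checksum": _checksum(pseudo.voxels),
        }
        stage = "predict"
        if model is None:
            vnc_dect = pseudo
            manifest["stages"][stage] = {"skipped": True}
        else:
            vnc_dect = predict_ct(model, pseudo)
            manifest["stages"][stage] = {
                "encoder_channels": list(model.config_.encoder_channels),
                "out_checksum": _checksum(vnc_dect.voxels),
            }
        stage = "invert"
        vnc_pct = invert_to_planning_ct(vnc_dect, record, calib=cfg.calibration)
        manifest["stages"][stage] = {"out_checksum": _checksum(vnc_pct.voxels)}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return vnc_pct, manifest


def run_evaluation_suite(pred: CTImage, target: CTImage, mask=None,
                         cfg: MetricConfig | None = None,
                         rois=None, dose_pair=None, gamma_params=None) -> dict:
    """Similarity metrics between a prediction and its target.

    Without a mask the metrics cover the full frame (with a warning), as
    the masked variants are only defined once a body contour exists.
    Optional sections: ``rois`` (sequence of ROISpec) adds a per-ROI
    CT-number table; ``dose_pair=(ref, evl)`` DoseGrids add a 2D gamma
    pass rate at ``gamma_params`` (default 2%/2 mm, 10% threshold).
    """
    if mask is None:
        import warnings

        warnings.warn("no body mask supplied; metrics computed on the full frame")
        m = None
    else:
        m = mask.mask if hasattr(mask, "mask") else np.asarray(mask).astype(bool)
    pair = ImagePair(x=pred.voxels, y=target.voxels, mask=m)
    report = metric_report(pair, cfg or MetricConfig())
    if rois is not None:
        from .metrics import roi_report

        report["roi_table"] = roi_report({"pred": pred, "target": target}, rois)
    if dose_pair is not None:
        from .dosimetry import gamma_2d

        _, rate = gamma_2d(dose_pair[0], dose_pair[1], gamma_params)
        report["gamma_pass_rate_pct"] = rate
    return report


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
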
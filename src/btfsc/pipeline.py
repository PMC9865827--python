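"""End-to-end orchestration of the tumor pipeline.

A full run takes one co-registered modality pair through up to six stages —
denoise, edge analysis, fusion, segmentation, feature extraction,
classification — and collects three metric blocks: fusion quality
(entropy/MI/PSNR/SSIM/STD), the segmentation confusion panel against the
ground-truth mask, and the classification outcome.  Stages can be disabled
from the tail of the chain; disabling a stage never changes upstream
outputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .classifier import DlpnnModel, extract_roi, predict
from .denoise import hpwf_denoise
from .edges import ReaParams, optimize_slopes
from .errors import ParameterError, StateError
from .features import hybrid_vector, roi_from_mask
from .fusion import FusionWeights, forward_fuse, from_ycbcr, rea_enhance, to_ycbcr
from .metrics import confusion_panel, fusion_quality
from .phantom import ModalityPair
from .segmentation import segment

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "STAGES", "derive_seed"]

STAGES = ("denoise", "rea", "fuse", "segment", "features", "classify")


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed: hash of the stage name mixed with the master."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Stage toggles and per-stage parameters for one run."""

    stages: tuple[str, ...] = STAGES
    use_rea: bool = True
    color_mode: bool = False
    feature_concat: bool = True
    segment_k: int = 4
    rea_params: ReaParams = field(default_factory=ReaParams)
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ParameterError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in STAGES if s in self.stages]
        if tuple(order) != self.stages:
            raise ParameterError("stages must appear in pipeline order")
        # each enabled stage needs its upstream inputs
        need = {"fuse": "denoise", "segment": "fuse", "features": "segment", "classify": "features"}
        for stage, dep in need.items():
            if stage in self.stages and dep not in self.stages:
                raise ParameterError(f"stage '{stage}' requires '{dep}'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["stages"] = tuple(d.get("stages", STAGES))
        if isinstance(d.get("rea_params"), dict):
            d["rea_params"] = ReaParams(**d["rea_params"])
        return cls(**d)


@dataclass
class RunRecord:
    """Everything a run produced: stage timings, metrics and artifacts."""

    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    metrics: dict[str, dict] = field(default_factory=dict)
    artifacts: dict[str, np.ndarray] = field(default_factory=dict)


def run_pipeline(
    pair: ModalityPair,
    cfg: PipelineConfig = PipelineConfig(),
    weights: FusionWeights | None = None,
    model: DlpnnModel | None = None,
) -> RunRecord:
    """Run the enabled stages on one modality pair and collect metrics.

    ``weights`` must be provided when the fuse stage is enabled, ``model``
    when classification is enabled.  Deterministic for fixed inputs.
    """
    if "fuse" in cfg.stages and weights is None:
        raise StateError("fusion stage enabled but no weights supplied")
    if "classify" in cfg.stages and model is None:
        raise StateError("classification stage enabled but no model supplied")

    rec = RunRecord(config=cfg.to_dict())

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                if exc[0] is None:
                    rec.stages[name] = {"time_s": time.perf_counter() - self.t0}
                return False

        return _Timer()

    mr_d, ct_d = np.asarray(pair.mr, float), np.asarray(pair.ct, float)
    if "denoise" in cfg.stages:
        with stage("denoise"):
            tr_mr = hpwf_denoise(pair.mr)
            tr_ct = hpwf_denoise(pair.ct)
            mr_d, ct_d = tr_mr.output, tr_ct.output
            rec.stages.setdefault("denoise", {})
        rec.stages["denoise"].update(
            sigma_mr=tr_mr.estimate.sigma_gn, sigma_ct=tr_ct.estimate.sigma_gn,
            mask_mr=tr_mr.estimate.mask_size, mask_ct=tr_ct.estimate.mask_size,
        )
        rec.artifacts["denoised_mr"] = mr_d
        rec.artifacts["denoised_ct"] = ct_d

    edge_energy = None
    if "rea" in cfg.stages:
        with stage("rea"):
            esi = optimize_slopes(ct_d, cfg.rea_params)
            edge_energy = esi.energy
        rec.stages["rea"].update(converged=esi.converged, iterations=len(esi.energy_trace))
        rec.artifacts["edge_slope"] = esi.slope
        rec.artifacts["edge_energy"] = esi.energy

    fused = None
    if "fuse" in cfg.stages:
        with stage("fuse"):
            if cfg.color_mode and pair.pet_rgb is not None:
                y, cb, cr = to_ycbcr(pair.pet_rgb)
                b = rea_enhance(y, edge_energy if cfg.use_rea else None)
                fused_y = forward_fuse(mr_d, b, weights)
                fused = fused_y
                rec.artifacts["fused_rgb"] = np.clip(from_ycbcr(fused_y, cb, cr), 0, 1)
                src_b = y
            else:
                b = rea_enhance(ct_d, edge_energy if cfg.use_rea else None)
                fused = forward_fuse(mr_d, b, weights)
                src_b = ct_d
        rec.artifacts["fused"] = fused
        rec.metrics["fusion_quality"] = fusion_quality(fused, mr_d, src_b).__dict__

    seg = None
    if "segment" in cfg.stages:
        with stage("segment"):
            seg = segment(fused, cfg.segment_k)
        rec.stages["segment"].update(
            tumor_cluster=seg.tumor_cluster_id, iterations=len(seg.model.objective_trace)
        )
        rec.artifacts["label_map"] = seg.label_map
        rec.artifacts["tumor_mask"] = seg.tumor_mask
        if pair.truth_mask is not None and pair.truth_mask.any():
            rec.metrics["segmentation_panel"] = confusion_panel(
                pair.truth_mask.astype(int), seg.tumor_mask.astype(int)
            ).as_dict()

    feats = roi = None
    if "features" in cfg.stages:
        with stage("features"):
            feats = hybrid_vector(roi_from_mask(fused, seg.tumor_mask))
            roi = extract_roi(fused, seg.tumor_mask)
        rec.artifacts["feature_vector"] = feats.as_array()

    if "classify" in cfg.stages:
        with stage("classify"):
            label, probs = predict(model, roi, feats if model.feature_concat else None)
        block = {"label": label, "probs": probs.tolist()}
        if pair.label is not None:
            block["correct"] = label == pair.label
        rec.metrics["classification"] = block

    return rec
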
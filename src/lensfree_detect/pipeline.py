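"""Whole-frame detection pipeline: threshold → cluster → features →
circularity/PPD filter → quantify.

Every candidate midpoint produced by the clustering stage appears in
the output records with an accepted flag and a rejection reason — the
pipeline never silently drops a candidate.  With the default
configuration the stage constants are the reference ones: 10 px
threshold window, 30-level contrast floor, 25 px cluster window, 3 px
linkage, 0.28 µm/px sizing coefficient.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

from .imaging_io import DetectionRecord, GrayImage, RejectionReason
from .pattern_cluster import ClusterConfig, cluster_mask
from .quantify import QuantResult, QuantifyConfig, quantify, size_from_ppd
from .ring_features import (
    FeatureConfig,
    circularity_ok,
    denoise_for_features,
    extract_features,
)
from .signal_mask import ThresholdConfig, local_threshold_mask


@dataclass(frozen=True)
class PipelineConfig:
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    seed: int = 0          # used by simulation subcommands only
    verbosity: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for name, sub_cls in (
            ("threshold", ThresholdConfig), ("cluster", ClusterConfig),
            ("features", FeatureConfig), ("quantify", QuantifyConfig),
        ):
            if name in data and data[name] is not None:
                sub = data[name]
                kwargs[name] = sub if isinstance(sub, sub_cls) else sub_cls(**sub)
        for name in ("seed", "verbosity"):
            if name in data:
                kwargs[name] = data[name]
        return cls(**kwargs)


def _near_border(img: GrayImage, midpoint: tuple[int, int], margin: int) -> bool:
    r, c = midpoint
    return (r < margin or c < margin
            or r >= img.height - margin or c >= img.width - margin)


def run_pipeline(img: GrayImage, cfg: PipelineConfig | None = None,
                 ) -> tuple[list[DetectionRecord], QuantResult]:
    """Run the full detection pipeline on one frame.

    Candidates are rejected as ``edge_truncated`` when their midpoint
    sits within ``scan_max`` of the frame border (their rings leave the
    frame), as ``not_circular`` when either width aspect ratio fails,
    and as ``ppd_not_found`` when a first-order peak cannot be located
    on both axes.  Deterministic for fixed input and config.
    """
    cfg = cfg or PipelineConfig()
    mask = local_threshold_mask(img, cfg.threshold)
    clusters = cluster_mask(mask, cfg.cluster)

    # thresholding/clustering see the raw frame; feature measurement runs
    # on a lightly blurred copy (computed once per frame)
    feat_img = img
    if cfg.features.denoise_sigma > 0:
        feat_img = denoise_for_features(img, cfg.features.denoise_sigma)

    records: list[DetectionRecord] = []
    for cluster in clusters:
        midpoint = cluster.midpoint
        if _near_border(img, midpoint, cfg.features.scan_max):
            records.append(DetectionRecord(
                center=midpoint, features=None, size_um=0.0, accepted=False,
                rejection_reason=RejectionReason.EDGE_TRUNCATED,
            ))
            continue
        feats = extract_features(feat_img, midpoint, cfg.features,
                                 pre_denoised=True)
        if not circularity_ok(feats, cfg.features):
            reason = RejectionReason.NOT_CIRCULAR
            accepted = False
            size = 0.0
        elif feats.ppd_h is None or feats.ppd_v is None:
            reason = RejectionReason.PPD_NOT_FOUND
            accepted = False
            size = 0.0
        else:
            reason = RejectionReason.NONE
            accepted = True
            size = size_from_ppd(feats.ppd, cfg.quantify)
        records.append(DetectionRecord(
            center=midpoint, features=feats, size_um=size,
            accepted=accepted, rejection_reason=reason,
        ))

    result = quantify(records, img, cfg.quantify)
    return records, result
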
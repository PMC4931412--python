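"""Scoring detections against ground truth and benchmark experiments.

Three kinds of evaluation:

* per-frame matching of detections to truth objects (greedy
  nearest-first, one-to-one) with precision/recall;
* series-level agreement of detected vs true counts across frames of
  increasing concentration (Pearson r, OLS slope/intercept, R²) plus
  the mean absolute size error over matched pairs;
* a window-size sweep that re-runs the pipeline with different
  threshold/cluster window sizes and reports count error and wall time
  per setting (wall times are informational, never asserted).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .imaging_io import DetectionRecord, GrayImage
from .synth_scene import SceneTruth


@dataclass
class MatchedPair:
    truth_index: int
    detection_index: int
    center_distance_px: float
    true_size_um: float
    detected_size_um: float

    @property
    def size_error_um(self) -> float:
        return self.detected_size_um - self.true_size_um


@dataclass
class MatchReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    pairs: list[MatchedPair]

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return 1.0 if denom == 0 else self.true_positives / denom

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return 1.0 if denom == 0 else self.true_positives / denom


@dataclass
class SeriesReport:
    true_counts: list[int]
    detected_counts: list[int]
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    mean_abs_size_error_um: Optional[float]


def match_detections(truth: SceneTruth, records: Sequence[DetectionRecord],
                     max_dist: float = 10.0) -> MatchReport:
    """Greedily pair accepted detections with truth objects.

    Candidate pairs are sorted by ascending center distance and accepted
    one at a time, skipping any already-used truth object or detection;
    only pairs within ``max_dist`` px qualify.  Leftover detections are
    false positives, leftover truth objects false negatives.
    """
    accepted = [(i, r) for i, r in enumerate(records) if r.accepted]
    candidates = []
    for ti, tobj in enumerate(truth.objects):
        for di, (_, rec) in enumerate(accepted):
            d = float(np.hypot(tobj.center[0] - rec.center[0],
                               tobj.center[1] - rec.center[1]))
            if d <= max_dist:
                candidates.append((d, ti, di))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs: list[MatchedPair] = []
    for d, ti, di in candidates:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        rec = accepted[di][1]
        pairs.append(MatchedPair(
            truth_index=ti,
            detection_index=accepted[di][0],
            center_distance_px=d,
            true_size_um=truth.objects[ti].size_um,
            detected_size_um=rec.size_um,
        ))
    return MatchReport(
        true_positives=len(pairs),
        false_positives=len(accepted) - len(pairs),
        false_negatives=truth.count - len(pairs),
        pairs=pairs,
    )


def evaluate_series(frames: Sequence[tuple[SceneTruth, Sequence[DetectionRecord]]],
                    max_dist: float = 10.0) -> SeriesReport:
    """Count agreement and size accuracy across a concentration series.

    Fits detected ~ true by ordinary least squares and reports Pearson
    r, slope, intercept and R², plus the mean absolute size error over
    all matched pairs.  Needs at least 3 frames with nonconstant true
    counts.
    """
    if len(frames) < 3:
        raise ValueError("need at least 3 frames")
    true_counts = [t.count for t, _ in frames]
    detected_counts = [sum(1 for r in recs if r.accepted) for _, recs in frames]
    if len(set(true_counts)) < 2:
        raise ValueError("true counts are constant; correlation undefined")

    x = np.asarray(true_counts, dtype=float)
    y = np.asarray(detected_counts, dtype=float)
    fit = stats.linregress(x, y)

    size_errors = []
    for truth, recs in frames:
        report = match_detections(truth, recs, max_dist=max_dist)
        size_errors.extend(abs(p.size_error_um) for p in report.pairs)
    mae = float(np.mean(size_errors)) if size_errors else None

    return SeriesReport(
        true_counts=true_counts,
        detected_counts=detected_counts,
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        mean_abs_size_error_um=mae,
    )


@dataclass
class SweepRow:
    stage: str           # "threshold" or "cluster"
    window: int
    detected_count: int
    count_error: int     # |detected − true|
    wall_time_s: float


def sweep_window_sizes(img: GrayImage, truth: SceneTruth,
                       threshold_windows: Sequence[int] = (),
                       cluster_windows: Sequence[int] = (),
                       base_config: Optional["PipelineConfig"] = None,  # noqa: F821
                       ) -> list[SweepRow]:
    """Re-run the pipeline varying one window size at a time.

    Each requested threshold window is tried with the cluster window at
    its default, and vice versa; rows report the absolute count error
    against truth and the elapsed wall time.
    """
    from dataclasses import replace
    from .pipeline import PipelineConfig, run_pipeline

    base = base_config or PipelineConfig()
    rows: list[SweepRow] = []

    def run_one(stage: str, window: int, cfg: "PipelineConfig") -> None:
        t0 = time.perf_counter()
        records, _ = run_pipeline(img, cfg)
        elapsed = time.perf_counter() - t0
        detected = sum(1 for r in records if r.accepted)
        rows.append(SweepRow(stage=stage, window=window, detected_count=detected,
                             count_error=abs(detected - truth.count),
                             wall_time_s=elapsed))

    for win in threshold_windows:
        cfg = replace(base, threshold=replace(base.threshold, window=int(win)))
        run_one("threshold", int(win), cfg)
    for win in cluster_windows:
        cfg = replace(base, cluster=replace(base.cluster, patch=int(win)))
        run_one("cluster", int(win), cfg)
    return rows
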
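"""Detection evaluation: per-class AP, mAP, precision, recall, F1.

AP uses the all-point interpolation (area under the monotone envelope of
the precision-recall curve) at IoU 0.5; precision/recall/F1 are
micro-averaged over classes at a fixed confidence threshold.  Frames per
second can be measured but is reported only as information — it depends on
hardware, not on correctness.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .boxes import CLASS_NAMES, DetectionBox, iou


def match_detections(
    dets: Sequence[DetectionBox],
    gts: Sequence[DetectionBox],
    iou_threshold: float = 0.5,
) -> list[bool]:
    """Greedy TP/FP flags for confidence-descending detections of one image.

    Each detection matches the highest-IoU unmatched ground truth of its own
    class when that IoU reaches the threshold; every ground truth can be
    matched at most once.
    """
    order = sorted(
        range(len(dets)), key=lambda i: -(dets[i].confidence or 0.0)
    )
    matched = [False] * len(gts)
    flags = [False] * len(dets)
    for i in order:
        det = dets[i]
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if matched[j] or gt.class_id != det.class_id:
                continue
            overlap = iou(det, gt)
            if overlap > best_iou:
                best_j, best_iou = j, overlap
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            flags[i] = True
    return flags


def average_precision(
    flags: Sequence[bool], confidences: Sequence[float], n_gt: int
) -> float:
    """Area under the monotone-envelope precision-recall curve, in [0,1]."""
    if n_gt == 0:
        return 0.0
    if not flags:
        return 0.0
    order = np.argsort(-np.asarray(confidences, dtype=float), kind="stable")
    tp = np.asarray(flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    return float(np.sum(np.diff(mrec) * mpre[1:]))


@dataclass
class EvalReport:
    per_class_ap: dict  # class name -> AP percent
    map_percent: float
    precision_percent: float
    recall_percent: float
    f1: float
    fps: float | None = None
    iou_threshold: float = 0.5
    conf_threshold: float = 0.5
    counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "per_class_ap": self.per_class_ap,
                    "mAP": self.map_percent,
                    "precision": self.precision_percent,
                    "recall": self.recall_percent,
                    "f1": self.f1,
                    "fps": self.fps,
                    "iou_threshold": self.iou_threshold,
                    "conf_threshold": self.conf_threshold,
                    "counts": self.counts,
                },
                fh,
                indent=2,
            )


def evaluate(
    dets_by_image: Mapping[str, Sequence[DetectionBox]],
    gts_by_image: Mapping[str, Sequence[DetectionBox]],
    iou_threshold: float = 0.5,
    conf_threshold: float = 0.5,
    class_names: Sequence[str] = CLASS_NAMES,
) -> EvalReport:
    """Score detections against ground truth over a set of images."""
    image_ids = sorted(gts_by_image)
    n_classes = len(class_names)
    for img_id, dets in dets_by_image.items():
        for d in dets:
            if d.class_id >= n_classes:
                raise ValueError(
                    f"unknown class id {d.class_id} in detections for {img_id!r}"
                )

    # per-class AP over all confidences
    per_class_ap: dict[str, float] = {}
    ap_values = []
    for cls in range(n_classes):
        flags_all: list[bool] = []
        confs_all: list[float] = []
        n_gt = 0
        for img_id in image_ids:
            gts = [g for g in gts_by_image[img_id] if g.class_id == cls]
            dets = [d for d in dets_by_image.get(img_id, []) if d.class_id == cls]
            n_gt += len(gts)
            flags = match_detections(dets, gts, iou_threshold)
            for d, f in zip(dets, flags):
                flags_all.append(f)
                confs_all.append(d.confidence or 0.0)
        if n_gt == 0 and not flags_all:
            continue  # class absent entirely
        ap = average_precision(flags_all, confs_all, n_gt)
        per_class_ap[class_names[cls]] = 100.0 * ap
        ap_values.append(ap)
    map_percent = 100.0 * float(np.mean(ap_values)) if ap_values else 0.0

    # micro P/R/F1 at the confidence threshold
    tp = fp = n_gt_total = 0
    for img_id in image_ids:
        gts = list(gts_by_image[img_id])
        n_gt_total += len(gts)
        dets = [
            d
            for d in dets_by_image.get(img_id, [])
            if (d.confidence or 0.0) >= conf_threshold
        ]
        flags = match_detections(dets, gts, iou_threshold)
        tp += sum(flags)
        fp += len(flags) - sum(flags)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / n_gt_total if n_gt_total > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalReport(
        per_class_ap=per_class_ap,
        map_percent=map_percent,
        precision_percent=100.0 * precision,
        recall_percent=100.0 * recall,
        f1=f1,
        iou_threshold=iou_threshold,
        conf_threshold=conf_threshold,
        counts={"tp": tp, "fp": fp, "n_gt": n_gt_total},
    )


def measure_fps(fn, image: np.ndarray, n_runs: int = 10) -> float:
    """Wall-clock frames per second of a single-image callable (informational)."""
    start = time.perf_counter()
    for _ in range(n_runs):
        fn(image)
    return n_runs / (time.perf_counter() - start)
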
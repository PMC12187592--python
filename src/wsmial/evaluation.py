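"""Image-level classification metrics and instance-level overlays.

Accuracy, precision, recall and F1 from the confusion counts, with the
tooth-marked class as the positive class (clinically, missed positives
matter most, so recall is the headline secondary metric). Ratios with a
zero denominator are reported as 0 and flagged rather than NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "undefined": list(self.undefined),
        }


def confusion_and_metrics(predictions, truths,
                          positive_class: int = 1) -> MetricsReport:
    """Confusion counts and the four derived metrics."""
    preds = np.asarray(predictions)
    truth = np.asarray(truths)
    if preds.shape != truth.shape or preds.ndim != 1 or preds.size == 0:
        raise ValueError("predictions and truths must be equal-length, "
                         "non-empty 1-D sequences")
    p_pos = preds == positive_class
    t_pos = truth == positive_class
    tp = int(np.sum(p_pos & t_pos))
    tn = int(np.sum(~p_pos & ~t_pos))
    fp = int(np.sum(p_pos & ~t_pos))
    fn = int(np.sum(~p_pos & t_pos))

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f1")
        f1 = 0.0
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                         precision=precision, recall=recall, f1=f1,
                         undefined=undefined)


def top_detections(bundle, top_n: int) -> list[int]:
    """Indices of the top-n proposals by the MIL-detection product for the
    predicted class, ties broken by proposal index."""
    pred = int(np.argmax(bundle.image_score))
    score = bundle.y_mil[:, pred] * bundle.y_det[pred, :]
    R = score.shape[0]
    order = np.lexsort((np.arange(R), -score))
    return [int(i) for i in order[:max(0, top_n)]]


def export_detections(sample, bundle, grid, top_n: int,
                      out_png: str | None = None,
                      out_json: str | None = None):
    """Overlay the top-n scoring proposal boxes on the image and emit a
    COCO-style detection dictionary. Returns (PIL image, coco dict)."""
    pred = int(np.argmax(bundle.image_score))
    idx = top_detections(bundle, top_n)
    img = Image.fromarray(sample.pixels).convert("RGB")
    draw = ImageDraw.Draw(img)
    annotations = []
    for rank, r in enumerate(idx):
        x0, y0, x1, y1 = (int(v) for v in grid.proposals[r])
        draw.rectangle([x0, y0, x1 - 1, y1 - 1], outline=(255, 0, 0))
        annotations.append({
            "id": rank,
            "image_id": sample.id,
            "category_id": pred,
            "bbox": [x0, y0, x1 - x0, y1 - y0],
            "score": float(bundle.y_mil[r, pred] * bundle.y_det[pred, r]),
        })
    coco = {
        "images": [{"id": sample.id, "width": sample.pixels.shape[1],
                    "height": sample.pixels.shape[0]}],
        "categories": [{"id": 0, "name": "non-tooth-marked"},
                       {"id": 1, "name": "tooth-marked"}],
        "annotations": annotations,
    }
    if out_png:
        img.save(out_png)
    if out_json:
        with open(out_json, "w") as fh:
            json.dump(coco, fh, indent=2)
    return img, coco


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    ix = max(0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0
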
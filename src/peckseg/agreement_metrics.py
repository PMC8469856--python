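"""Agreement and detection metrics.

Two levels of comparison are used throughout the pipeline:

* **pixel-exact agreement** — intersection over union of pixel sets, the
  strict measure used for inter- and intra-observer reliability, with the
  conventional Landis–Koch qualitative bands;
* **detection-level agreement** — each annotated or predicted injury is
  outlined with its tight bounding box, boxes are matched one-to-one at a
  box-IoU threshold (default 0.5), and precision / recall / F1 are derived
  from the TP/FP/FN counts.  Corpus-level scores are micro-aggregated
  (counts pooled over images, then P/R/F1 recomputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Iterable, List, Sequence, Set, Tuple

from .annotation_store import AnnotationSet, InjuryMask, Pixel


class AgreementBand(str, Enum):
    poor = "poor"
    slight = "slight"
    fair = "fair"
    moderate = "moderate"
    substantial = "substantial"
    almost_perfect = "almost_perfect"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, inclusive min / exclusive max."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("bounding box must have positive extent")

    @property
    def area(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)

    def iou(self, other: "BoundingBox") -> float:
        ri = max(self.row_min, other.row_min)
        ci = max(self.col_min, other.col_min)
        ra = min(self.row_max, other.row_max)
        ca = min(self.col_max, other.col_max)
        inter = max(0, ra - ri) * max(0, ca - ci)
        if inter == 0:
            return 0.0
        return inter / (self.area + other.area - inter)


@dataclass
class DetectionReport:
    """Outcome of one-to-one detection matching at a box-IoU threshold."""

    true_positives: int
    false_positives: int
    false_negatives: int
    matched_pairs: List[Tuple[str, str, float]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d > 0 else 0.0

    @property
    def recall(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    @property
    def mean_detection_iou(self) -> float:
        if not self.matched_pairs:
            return 0.0
        return sum(i for _, _, i in self.matched_pairs) / len(self.matched_pairs)

    def as_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mean_detection_iou": self.mean_detection_iou,
        }


def pixel_iou(a: Iterable[Pixel], b: Iterable[Pixel]) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 when both are empty, 0.0 when exactly one is."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    union = len(sa | sb)
    return len(sa & sb) / union


def whole_image_iou(a: AnnotationSet, b: AnnotationSet) -> float:
    """Pixel IoU of the unions of all masks in each set (same image)."""
    if a.image_id != b.image_id:
        raise ValueError(f"image_id mismatch: {a.image_id!r} vs {b.image_id!r}")
    return pixel_iou(a.union_pixels(), b.union_pixels())


# Landis & Koch qualitative bands.  The printed two-decimal band edges are
# treated as partition points: slight [0, 0.21), fair [0.21, 0.41),
# moderate [0.41, 0.61), substantial [0.61, 0.81), almost perfect [0.81, 1].
_BAND_EDGES = [
    (0.0, AgreementBand.poor),
    (0.21, AgreementBand.slight),
    (0.41, AgreementBand.fair),
    (0.61, AgreementBand.moderate),
    (0.81, AgreementBand.substantial),
]


def landis_koch_band(value: float) -> AgreementBand:
    if value > 1.0:
        raise ValueError(f"agreement value {value} exceeds 1.0")
    if value < 0.0:
        return AgreementBand.poor
    if value >= 0.81:
        return AgreementBand.almost_perfect
    if value >= 0.61:
        return AgreementBand.substantial
    if value >= 0.41:
        return AgreementBand.moderate
    if value >= 0.21:
        return AgreementBand.fair
    return AgreementBand.slight


def mask_to_bbox(mask: InjuryMask) -> BoundingBox:
    """Tightest axis-aligned box containing every mask pixel."""
    rows = [p[0] for p in mask.pixels]
    cols = [p[1] for p in mask.pixels]
    return BoundingBox(min(rows), min(cols), max(rows) + 1, max(cols) + 1)


def match_detections(
    pred: AnnotationSet, ref: AnnotationSet, iou_threshold: float = 0.5
) -> DetectionReport:
    """Match predicted to reference injuries one-to-one by bounding-box IoU.

    Matching is greedy in descending box IoU (ties broken by smaller pred
    index, then smaller ref index); a pair is eligible when its box IoU is
    at least ``iou_threshold``.  Unmatched predictions are false positives,
    unmatched references false negatives.  ``matched_pairs`` records the
    pixel-mask IoU of each matched pair, which is what the mean detection
    IoU averages.
    """
    if pred.image_id != ref.image_id:
        raise ValueError(f"image_id mismatch: {pred.image_id!r} vs {ref.image_id!r}")
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError("iou_threshold must be in (0, 1]")
    pboxes = [mask_to_bbox(m) for m in pred.masks]
    rboxes = [mask_to_bbox(m) for m in ref.masks]
    candidates = []
    for i, pb in enumerate(pboxes):
        for j, rb in enumerate(rboxes):
            iou = pb.iou(rb)
            if iou >= iou_threshold:
                candidates.append((-iou, i, j))
    candidates.sort()
    used_p: Set[int] = set()
    used_r: Set[int] = set()
    pairs: List[Tuple[str, str, float]] = []
    for neg_iou, i, j in candidates:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        pairs.append(
            (
                pred.masks[i].mask_id,
                ref.masks[j].mask_id,
                pixel_iou(pred.masks[i].pixels, ref.masks[j].pixels),
            )
        )
    tp = len(pairs)
    return DetectionReport(
        true_positives=tp,
        false_positives=len(pred.masks) - tp,
        false_negatives=len(ref.masks) - tp,
        matched_pairs=pairs,
    )


def aggregate_reports(reports: Sequence[DetectionReport]) -> DetectionReport:
    """Micro-aggregate per-image reports: pool TP/FP/FN, recompute P/R/F1."""
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    pairs: List[Tuple[str, str, float]] = []
    for r in reports:
        pairs.extend(r.matched_pairs)
    return DetectionReport(
        true_positives=sum(r.true_positives for r in reports),
        false_positives=sum(r.false_positives for r in reports),
        false_negatives=sum(r.false_negatives for r in reports),
        matched_pairs=pairs,
    )
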
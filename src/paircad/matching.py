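"""Assign detections to reference lesions per exam and class.

The matching rule is the one used throughout box-based CAD evaluation: a
detection is a true positive when its intersection-over-union with a
reference lesion exceeds a threshold (default strictly > 0.5). Detections
below the confidence cutoff are discarded before matching; survivors are
assigned greedily in descending confidence, each taking the unmatched
lesion of greatest IOU, one-to-one. Extra detections over an already
matched lesion count as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .types import BoundingBox, DetectionBox, LesionROI, Undefined


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over union area of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    # clamp: corner-difference rounding can push the ratio past 1 by an ulp
    return min(1.0, inter / (a.area + b.area - inter))


@dataclass(frozen=True)
class MatchSet:
    """Per-exam, per-class TP/FP/FN assignment at one confidence cutoff."""

    exam_id: str
    class_label: str
    cutoff: float
    matches: tuple[tuple[DetectionBox, LesionROI], ...]
    false_positives: tuple[DetectionBox, ...]
    missed_lesions: tuple[LesionROI, ...]

    @property
    def n_lesions(self) -> int:
        return len(self.matches) + len(self.missed_lesions)


def match_exam(
    detections: Sequence[DetectionBox],
    lesions: Sequence[LesionROI],
    cutoff: float,
    iou_threshold: float = 0.5,
    strict: bool = True,
) -> MatchSet:
    """Greedy one-to-one assignment of detections to lesions on one exam.

    Parameters
    ----------
    detections, lesions
        Boxes of a single exam and class; mixed exam or class ids raise.
    cutoff
        Confidence screen in [0, 1]; detections below it are dropped
        before matching (they are neither TP nor FP).
    iou_threshold
        Minimum overlap for a match. With ``strict`` (default) the
        comparison is ``iou > threshold``, otherwise ``>=``.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    ids = {d.exam_id for d in detections} | {l.exam_id for l in lesions}
    if len(ids) > 1:
        raise ValueError(f"mixed exam_ids in match_exam: {sorted(ids)}")
    labels = {d.class_label for d in detections} | {l.class_label for l in lesions}
    if len(labels) > 1:
        raise ValueError(f"mixed class labels in match_exam: {sorted(labels)}")
    exam_id = next(iter(ids), "")
    class_label = next(iter(labels), "")

    surviving = [d for d in detections if d.confidence >= cutoff]
    # descending confidence; ties by descending best-IOU, then input order
    best_iou = {
        id(d): max((iou(d.box, l.box) for l in lesions), default=0.0)
        for d in surviving
    }
    order = sorted(
        range(len(surviving)),
        key=lambda i: (-surviving[i].confidence, -best_iou[id(surviving[i])], i),
    )

    accepts = (lambda v: v > iou_threshold) if strict else (lambda v: v >= iou_threshold)
    unmatched = list(lesions)
    matches: list[tuple[DetectionBox, LesionROI]] = []
    false_positives: list[DetectionBox] = []
    for i in order:
        det = surviving[i]
        best, best_v = None, -1.0
        for les in unmatched:
            v = iou(det.box, les.box)
            if accepts(v) and v > best_v:
                best, best_v = les, v
        if best is None:
            false_positives.append(det)
        else:
            matches.append((det, best))
            unmatched.remove(best)

    return MatchSet(
        exam_id=exam_id,
        class_label=class_label,
        cutoff=cutoff,
        matches=tuple(matches),
        false_positives=tuple(false_positives),
        missed_lesions=tuple(unmatched),
    )


ExamOutcome = Literal["detected", "missed"]


def exam_outcome(match_set: MatchSet) -> ExamOutcome:
    """Exam-level positivity: detected iff at least one true-positive match.

    False positives alone never make an exam "detected" — an exam whose
    only boxes are false alarms has still missed its lesions.
    """
    return "detected" if len(match_set.matches) >= 1 else "missed"


def recall(match_sets: Iterable[MatchSet]) -> float | Undefined:
    """Lesion-level sensitivity over a collection of exams, in percent."""
    matched = total = 0
    for ms in match_sets:
        matched += len(ms.matches)
        total += ms.n_lesions
    if total == 0:
        return Undefined("recall undefined: no reference lesions")
    return 100.0 * matched / total
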
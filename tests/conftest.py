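"""Shared helpers: record builders and independent brute-force oracles."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from paircad import BoundingBox, DetectionBox, LesionROI
from paircad.matching import iou


def box(x, y, w, h) -> BoundingBox:
    return BoundingBox(x, y, w, h)


def lesion(lesion_id, exam_id, b, label="N") -> LesionROI:
    return LesionROI(lesion_id=lesion_id, exam_id=exam_id, class_label=label, box=b)


def det(exam_id, b, conf, label="N") -> DetectionBox:
    return DetectionBox(exam_id=exam_id, class_label=label, box=b, confidence=conf)


def brute_force_max_matches(detections, lesions, iou_threshold=0.5, strict=True):
    """Maximum number of one-to-one (detection, lesion) matches above the
    IOU threshold, by exhaustive enumeration over injective assignments.

    Independent of the greedy matcher: tries every way of assigning each
    detection to a distinct lesion (or none) and returns the best count.
    """
    accepts = (lambda v: v > iou_threshold) if strict else (lambda v: v >= iou_threshold)
    n_d, n_l = len(detections), len(lesions)
    best = 0
    slots = list(range(n_l)) + [None] * n_d  # None = unassigned
    for assign in set(permutations(slots, n_d)):
        used = [a for a in assign if a is not None]
        if len(used) != len(set(used)):
            continue
        count = sum(
            1 for d_idx, l_idx in enumerate(assign)
            if l_idx is not None
            and accepts(iou(detections[d_idx].box, lesions[l_idx].box))
        )
        best = max(best, count)
    return best


def separated_lesion_instance(rng: np.random.Generator, n_det_max=4, n_les_max=4,
                              exam_id="E", label="N"):
    """Random matching instance whose lesions are mutually disjoint.

    With disjoint reference lesions no detection can exceed IOU 0.5 with
    two of them, which is the regime the greedy matcher is designed for.
    Detections are jittered copies of lesions plus pure-noise boxes, with
    distinct confidences.
    """
    n_les = int(rng.integers(1, n_les_max + 1))
    lesions = []
    for i in range(n_les):
        w, h = rng.uniform(20, 40, size=2)
        x = 100.0 * i + rng.uniform(0, 30)  # 100-px lanes: disjoint by construction
        y = rng.uniform(0, 50)
        lesions.append(lesion(f"L{i}", exam_id, box(x, y, w, h), label))
    n_det = int(rng.integers(0, n_det_max + 1))
    confs = rng.permutation(np.linspace(0.2, 0.95, n_det_max))[:n_det]
    dets = []
    for j in range(n_det):
        if rng.random() < 0.7 and n_les > 0:  # near-copy of a random lesion
            src = lesions[int(rng.integers(n_les))].box
            dx, dy = rng.uniform(-10, 10, size=2)
            b = box(max(0.0, src.x_min + dx), max(0.0, src.y_min + dy),
                    src.width, src.height)
        else:  # noise box
            b = box(rng.uniform(0, 400), rng.uniform(100, 300),
                    rng.uniform(10, 40), rng.uniform(10, 40))
        dets.append(det(exam_id, b, float(confs[j]), label))
    return dets, lesions


def jafroc_fom_bruteforce(lesion_ratings, normal_fp_ratings):
    """Plain double-loop figure of merit with the 0.5 tie kernel."""
    ys = [y for ratings in lesion_ratings.values() for y in ratings]
    xs = list(normal_fp_ratings.values())
    total = 0.0
    for y in ys:
        for x in xs:
            total += 1.0 if y > x else (0.5 if y == x else 0.0)
    return total / (len(ys) * len(xs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
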
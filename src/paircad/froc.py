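"""Free-response operating characteristics and the jackknife figure of merit.

The FROC curve traces lesion-level sensitivity against average false
positives per image as the confidence cutoff sweeps a grid. Operating
points are picked by an average-FP budget. The JAFROC figure of merit is
the probability, with half credit for ties, that a lesion's rating (its
highest matched detection confidence) exceeds the highest false-positive
rating on a normal image; its 95% CI comes from leave-one-case-out
jackknife pseudovalues with a normal approximation, the case being the
exam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .matching import match_exam
from .types import DetectionBox, LesionROI, Undefined

#: Ratings for unmatched lesions / normal exams without false positives.
NO_RATING = float("-inf")

DEFAULT_CUTOFF_GRID: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 101), 10))


@dataclass(frozen=True)
class FROCPoint:
    cutoff: float
    avg_fp_per_image: float
    lesion_sensitivity: float


@dataclass(frozen=True)
class FROCCurve:
    class_label: str
    points: tuple[FROCPoint, ...]  # sorted by cutoff ascending
    n_images: int
    n_lesions: int


@dataclass(frozen=True)
class CutoffSelection:
    cutoff: float
    avg_fp_per_image: float
    lesion_sensitivity: float
    target_avg_fp: float
    #: set when no grid cutoff attains the FP budget and the largest
    #: cutoff was returned instead
    unattainable: bool = False


@dataclass(frozen=True)
class FOMResult:
    class_label: str
    fom: float
    ci_low: float
    ci_high: float
    n_jackknife: int


def froc_curve(
    detections_by_exam: Mapping[str, Sequence[DetectionBox]],
    lesions_by_exam: Mapping[str, Sequence[LesionROI]],
    exam_ids: Sequence[str],
    class_label: str,
    cutoff_grid: Sequence[float] = DEFAULT_CUTOFF_GRID,
    iou_threshold: float = 0.5,
) -> FROCCurve:
    """Sweep the cutoff grid, matching every scored exam at each cutoff.

    ``exam_ids`` lists every exam that is scored — lesion-bearing and
    normal alike — so exams with no detections still enter the FP
    denominator.
    """
    if len(cutoff_grid) == 0:
        raise ValueError("cutoff_grid must be nonempty")
    if len(exam_ids) == 0:
        raise ValueError("no exams to score")
    n_lesions = sum(len(lesions_by_exam.get(e, ())) for e in exam_ids)
    if n_lesions == 0:
        raise ValueError("FROC needs at least one reference lesion")

    points = []
    for cutoff in sorted(cutoff_grid):
        matched = fps = 0
        for e in exam_ids:
            ms = match_exam(
                detections_by_exam.get(e, ()),
                lesions_by_exam.get(e, ()),
                cutoff=cutoff,
                iou_threshold=iou_threshold,
            )
            matched += len(ms.matches)
            fps += len(ms.false_positives)
        points.append(
            FROCPoint(
                cutoff=float(cutoff),
                avg_fp_per_image=fps / len(exam_ids),
                lesion_sensitivity=matched / n_lesions,
            )
        )
    return FROCCurve(
        class_label=class_label,
        points=tuple(points),
        n_images=len(exam_ids),
        n_lesions=n_lesions,
    )


def select_cutoff(curve: FROCCurve, target_avg_fp: float) -> CutoffSelection:
    """Operating point at an average-FP budget.

    Returns the smallest grid cutoff whose average FP per image is within
    the budget — i.e. maximum sensitivity subject to the FP constraint;
    between grid points this lands on the conservative (higher-cutoff)
    side. If even the largest cutoff exceeds the budget, that cutoff is
    returned with ``unattainable`` set.
    """
    if target_avg_fp < 0:
        raise ValueError("target_avg_fp must be >= 0")
    for p in curve.points:  # ascending cutoff, non-increasing avg FP
        if p.avg_fp_per_image <= target_avg_fp:
            return CutoffSelection(
                cutoff=p.cutoff,
                avg_fp_per_image=p.avg_fp_per_image,
                lesion_sensitivity=p.lesion_sensitivity,
                target_avg_fp=target_avg_fp,
            )
    top = curve.points[-1]
    return CutoffSelection(
        cutoff=top.cutoff,
        avg_fp_per_image=top.avg_fp_per_image,
        lesion_sensitivity=top.lesion_sensitivity,
        target_avg_fp=target_avg_fp,
        unattainable=True,
    )


def collect_ratings(
    detections_by_exam: Mapping[str, Sequence[DetectionBox]],
    lesions_by_exam: Mapping[str, Sequence[LesionROI]],
    exam_ids: Sequence[str],
    iou_threshold: float = 0.5,
) -> tuple[dict[str, list[float]], dict[str, float]]:
    """Build the JAFROC rating sets from raw boxes.

    Matches every exam at cutoff 0 and returns (a) per lesion-bearing
    exam, the list of per-lesion ratings — the confidence of the matched
    detection, ``-inf`` if unmatched; and (b) per normal exam (zero
    lesions of the class), the highest false-positive confidence, ``-inf``
    when the exam has no detections at all.
    """
    lesion_ratings: dict[str, list[float]] = {}
    normal_ratings: dict[str, float] = {}
    for e in exam_ids:
        lesions = lesions_by_exam.get(e, ())
        ms = match_exam(
            detections_by_exam.get(e, ()), lesions, cutoff=0.0,
            iou_threshold=iou_threshold,
        )
        if len(lesions) > 0:
            rated = {id(l): NO_RATING for l in lesions}
            for det, les in ms.matches:
                rated[id(les)] = det.confidence
            lesion_ratings[e] = [rated[id(l)] for l in lesions]
        else:
            normal_ratings[e] = max(
                (d.confidence for d in ms.false_positives), default=NO_RATING
            )
    return lesion_ratings, normal_ratings


def _psi(fp_rating: float, lesion_rating: float) -> float:
    """Wilcoxon kernel with half credit for ties (including -inf vs -inf)."""
    if lesion_rating > fp_rating:
        return 1.0
    if lesion_rating == fp_rating:
        return 0.5
    return 0.0


def jafroc_fom(
    lesion_ratings: Mapping[str, Sequence[float]],
    normal_fp_ratings: Mapping[str, float],
    class_label: str = "",
) -> FOMResult | Undefined:
    """Figure of merit over all (lesion, normal exam) pairs, jackknifed by exam.

    FOM = mean of psi(x_fp, y_lesion) over every lesion and every normal
    exam. The 95% CI uses leave-one-case-out pseudovalues
    ``n*theta - (n-1)*theta_(-i)`` over all cases (lesion-bearing and
    normal exams), a normal approximation, and clipping to [0, 1].
    """
    lesion_cases = {k: list(v) for k, v in lesion_ratings.items() if len(v) > 0}
    n_lesions = sum(len(v) for v in lesion_cases.values())
    n_normals = len(normal_fp_ratings)
    if n_lesions == 0:
        return Undefined("JAFROC FOM undefined: no reference lesions")
    if n_normals == 0:
        return Undefined("JAFROC FOM undefined: no normal exams (no noise set)")

    # kernel sums, organised so that leave-one-out totals are cheap
    case_lesion_sum = {
        c: sum(_psi(x, y) for y in ys for x in normal_fp_ratings.values())
        for c, ys in lesion_cases.items()
    }
    case_normal_sum = {
        c: sum(_psi(x, y) for ys in lesion_cases.values() for y in ys)
        for c, x in normal_fp_ratings.items()
    }
    total = sum(case_lesion_sum.values())
    theta = total / (n_lesions * n_normals)

    cases = list(lesion_cases) + list(normal_fp_ratings)
    n = len(cases)
    pseudo = []
    for c in cases:
        if c in lesion_cases:
            rem_lesions = n_lesions - len(lesion_cases[c])
            if rem_lesions == 0:
                theta_i = theta  # removing the only lesion case: no information
            else:
                theta_i = (total - case_lesion_sum[c]) / (rem_lesions * n_normals)
        else:
            if n_normals == 1:
                theta_i = theta
            else:
                theta_i = (total - case_normal_sum[c]) / (n_lesions * (n_normals - 1))
        pseudo.append(n * theta - (n - 1) * theta_i)

    pseudo_arr = np.asarray(pseudo)
    se = float(pseudo_arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    mean_pseudo = float(pseudo_arr.mean())
    half = 1.959963984540054 * se
    return FOMResult(
        class_label=class_label,
        fom=theta,
        ci_low=max(0.0, min(theta, mean_pseudo - half)),
        ci_high=min(1.0, max(theta, mean_pseudo + half)),
        n_jackknife=n,
    )
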
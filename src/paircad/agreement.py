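"""Paired-exam agreement: the a/b/c/d cells, PPA and Chamberlain's CPPA.

Each initial/follow-up pair is classified by whether the detector found at
least one true lesion on each exam:

    a — detected on both exams        b — detected only on the initial
    c — detected only on the follow-up  d — detected on neither

Positive agreement deliberately ignores d (pairs where nothing was found),
since the question is how consistently the detector finds disease it is
capable of finding:

    PPA  = 100 * 2a / (2a + b + c)
    CPPA = 100 * a / (a + b + c)

CPPA <= PPA always, with equality iff there are no discordant pairs or no
concordant ones. The two are linked by PPA = 100 * 2p / (1 + p) with
p = CPPA / 100, exact whenever both come from the same counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .matching import exam_outcome, match_exam
from .types import DetectionBox, LesionROI, PairManifestEntry, Undefined

logger = logging.getLogger(__name__)

_CELL = {
    ("detected", "detected"): "a",
    ("detected", "missed"): "b",
    ("missed", "detected"): "c",
    ("missed", "missed"): "d",
}


@dataclass(frozen=True)
class AgreementCounts:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("agreement counts must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AgreementResult:
    class_label: str
    cutoff: float
    counts: AgreementCounts
    ppa: float | Undefined
    cppa: float | Undefined


def classify_pair(initial: str, followup: str) -> str:
    """Map the (initial, follow-up) exam outcomes to one of the cells a-d."""
    try:
        return _CELL[(initial, followup)]
    except KeyError:
        raise ValueError(
            f"outcomes must be 'detected' or 'missed', got ({initial!r}, {followup!r})"
        ) from None


def ppa(counts: AgreementCounts) -> float | Undefined:
    """Percent positive agreement, 100*2a/(2a+b+c); d is excluded."""
    denom = 2 * counts.a + counts.b + counts.c
    if denom == 0:
        return Undefined("PPA undefined: no positively detected pairs (a=b=c=0)")
    return 100.0 * 2 * counts.a / denom


def cppa(counts: AgreementCounts) -> float | Undefined:
    """Chamberlain's percent positive agreement, 100*a/(a+b+c)."""
    denom = counts.a + counts.b + counts.c
    if denom == 0:
        return Undefined("CPPA undefined: no positively detected pairs (a=b=c=0)")
    return 100.0 * counts.a / denom


def ppa_from_cppa(cppa_value: float) -> float:
    """Recover PPA from CPPA via the identity PPA = 100*2p/(1+p), p=CPPA/100."""
    if not 0.0 <= cppa_value <= 100.0:
        raise ValueError(f"CPPA must lie in [0, 100], got {cppa_value}")
    p = cppa_value / 100.0
    return 100.0 * 2 * p / (1 + p)


def evaluate_reproducibility(
    pairs: Sequence[PairManifestEntry],
    lesions_by_exam: Mapping[str, Sequence[LesionROI]],
    detections_by_exam: Mapping[str, Sequence[DetectionBox]],
    cutoff: float,
    iou_threshold: float = 0.5,
) -> dict[str, AgreementResult]:
    """Per-class agreement over all pairs at one confidence cutoff.

    For each pair, both exams are matched at the cutoff and reduced to an
    exam-level outcome; the pair lands in one cell and the per-class cell
    tallies feed PPA and CPPA. Classes with zero pairs are omitted.
    """
    tallies: dict[str, dict[str, int]] = {}
    for pair in pairs:
        outcomes = []
        for exam_id in (pair.initial_exam_id, pair.followup_exam_id):
            dets = [
                d for d in detections_by_exam.get(exam_id, ())
                if d.class_label == pair.class_label
            ]
            les = [
                l for l in lesions_by_exam.get(exam_id, ())
                if l.class_label == pair.class_label
            ]
            ms = match_exam(dets, les, cutoff=cutoff, iou_threshold=iou_threshold)
            outcomes.append(exam_outcome(ms))
        cell = classify_pair(*outcomes)
        tallies.setdefault(pair.class_label, {"a": 0, "b": 0, "c": 0, "d": 0})
        tallies[pair.class_label][cell] += 1

    results = {}
    for label, t in sorted(tallies.items()):
        counts = AgreementCounts(**t)
        results[label] = AgreementResult(
            class_label=label,
            cutoff=cutoff,
            counts=counts,
            ppa=ppa(counts),
            cppa=cppa(counts),
        )
    return results


def aggregate_over_operating_points(
    results: Iterable[AgreementResult],
) -> dict[str, float | Undefined | int]:
    """Mean and sample SD (n-1) of PPA and CPPA across operating points.

    Undefined points are excluded and counted. With a single defined
    point the SD is reported as 0.0.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("aggregation needs at least two operating points")
    ppas = [r.ppa for r in results if not isinstance(r.ppa, Undefined)]
    cppas = [r.cppa for r in results if not isinstance(r.cppa, Undefined)]
    n_excluded = len(results) - len(ppas)

    def _mean_sd(vals: list[float]) -> tuple[float | Undefined, float | Undefined]:
        if not vals:
            u = Undefined("all operating points undefined")
            return u, u
        m = sum(vals) / len(vals)
        if len(vals) == 1:
            return m, 0.0
        sd = math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
        return m, sd

    ppa_mean, ppa_sd = _mean_sd(ppas)
    cppa_mean, cppa_sd = _mean_sd(cppas)
    if n_excluded:
        logger.info("aggregation excluded %d undefined operating points", n_excluded)
    return {
        "ppa_mean": ppa_mean,
        "ppa_sd": ppa_sd,
        "cppa_mean": cppa_mean,
        "cppa_sd": cppa_sd,
        "n_points": len(results),
        "n_excluded": n_excluded,
    }
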
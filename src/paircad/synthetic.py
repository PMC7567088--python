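"""Synthetic paired-exam cohorts with a simulated lesion detector.

The generator emulates the structure of a paired chest-radiograph
reproducibility study: five disease classes with fixed per-class pair
counts, one or more lesion boxes per positive exam, a pool of normal
exams, and a detector characterised by per-class sensitivity, a Poisson
false-alarm process and Beta-distributed confidence scores.

Within-pair dependence uses a Gaussian copula: each lesion carries a
latent detectability ``u`` shared by the two exams of its pair, and the
exam-specific score is ``z_e = sqrt(rho)*u + sqrt(1-rho)*eps_e`` with
``eps_e`` independent standard normals. The lesion is detected on exam
``e`` iff ``z_e < Phi^{-1}(s)``, so the marginal per-exam detection
probability is exactly the configured sensitivity ``s`` while ``rho``
tunes test-retest correlation from independent (0) to identical (1).

Detected lesions emit a box displaced to a target IOU drawn uniformly
from (0.55, 0.95) — above the 0.5 matching threshold but stressing it —
and false positives are placed away from every lesion (IOU <= 0.1), so
the generator's recorded per-pair outcomes are exactly what the matching
pipeline recomputes at cutoff 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .types import (
    DEFAULT_CLASSES,
    BoundingBox,
    DetectionBox,
    ExamRecord,
    LesionROI,
    PairManifestEntry,
)

#: Per-class pair counts of the emulated paired test set.
DEFAULT_PAIR_COUNTS = {"N": 121, "C": 28, "IO": 12, "PLE": 67, "PN": 20}

#: Per-class detector sensitivity at the emulated operating behaviour.
DEFAULT_SENSITIVITY = {"N": 0.78, "C": 0.71, "IO": 0.93, "PLE": 0.97, "PN": 0.88}

#: Mean extra lesions per positive exam (lesion count = 1 + Poisson(mu)),
#: matching per-class ROI-per-image ratios of roughly 1.06-1.92.
DEFAULT_EXTRA_LESIONS = {"N": 0.16, "C": 0.31, "IO": 0.92, "PLE": 0.22, "PN": 0.06}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate the target design."""

    pair_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_COUNTS))
    n_normal_exams: int = 200
    sensitivity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    extra_lesions_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXTRA_LESIONS))
    #: raw false-alarm candidates per exam (Poisson), before confidence
    #: screening; labels drawn uniformly over the classes
    fp_rate: float = 3.0
    #: within-pair latent detectability correlation (Gaussian copula)
    pair_correlation: float = 0.7
    tp_conf_alpha: float = 4.0  # Beta(4, 1): mean 0.8
    tp_conf_beta: float = 1.0
    fp_conf_alpha: float = 2.0  # Beta(2, 3): mean 0.4
    fp_conf_beta: float = 3.0
    image_width: int = 1000
    image_height: int = 1000
    #: follow-up lesion displacement, pixels (uniform in [-j, j] per axis)
    jitter_px: float = 15.0
    box_size_range: tuple[float, float] = (50.0, 250.0)
    seed: int = 0

    def validate(self) -> None:
        for label, s in self.sensitivity.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sensitivity[{label}] out of [0,1]: {s}")
        if not 0.0 <= self.pair_correlation <= 1.0:
            raise ValueError(f"pair_correlation out of [0,1]: {self.pair_correlation}")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if any(n < 0 for n in self.pair_counts.values()) or self.n_normal_exams < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.box_size_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid box_size_range {self.box_size_range}")
        if hi >= min(self.image_width, self.image_height):
            raise ValueError("boxes of the configured size cannot fit the image")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated study: exams, lesions, pairs, detections and truth."""

    exams: list[ExamRecord]
    lesions: list[LesionROI]
    pairs: list[PairManifestEntry]
    detections_initial: list[DetectionBox]
    detections_followup: list[DetectionBox]
    #: pair_id -> (detected_on_initial, detected_on_follow_up); recorded by
    #: the detector simulation, before any confidence cutoff
    pair_outcomes: dict[str, tuple[bool, bool]]

    def lesions_by_exam(self) -> dict[str, list[LesionROI]]:
        out: dict[str, list[LesionROI]] = {}
        for l in self.lesions:
            out.setdefault(l.exam_id, []).append(l)
        return out

    def detections_by_exam(self) -> dict[str, list[DetectionBox]]:
        out: dict[str, list[DetectionBox]] = {}
        for d in self.detections_initial + self.detections_followup:
            out.setdefault(d.exam_id, []).append(d)
        return out


def _random_box(rng: np.random.Generator, cfg: SimulationConfig) -> BoundingBox:
    lo, hi = cfg.box_size_range
    w = rng.uniform(lo, hi)
    h = rng.uniform(lo, hi)
    x = rng.uniform(0, cfg.image_width - w)
    y = rng.uniform(0, cfg.image_height - h)
    return BoundingBox(x, y, w, h)


def _jitter_box(box: BoundingBox, rng: np.random.Generator,
                cfg: SimulationConfig) -> BoundingBox:
    if cfg.jitter_px == 0:
        return box
    dx = rng.uniform(-cfg.jitter_px, cfg.jitter_px)
    dy = rng.uniform(-cfg.jitter_px, cfg.jitter_px)
    x = min(max(box.x_min + dx, 0.0), cfg.image_width - box.width)
    y = min(max(box.y_min + dy, 0.0), cfg.image_height - box.height)
    return BoundingBox(x, y, box.width, box.height)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Lay out exams, pairs and lesion boxes; detections come later.

    Deterministic given ``config.seed``. Follow-up lesions are the initial
    lesions displaced by the jitter, clipped to the image.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])

    exams: list[ExamRecord] = []
    lesions: list[LesionROI] = []
    pairs: list[PairManifestEntry] = []
    for label, n_pairs in config.pair_counts.items():
        mu = config.extra_lesions_mean.get(label, 0.0)
        for i in range(n_pairs):
            pid = f"{label}{i:03d}"
            e0, e1 = f"{pid}_init", f"{pid}_fu"
            exams.append(ExamRecord(e0, pid, "initial",
                                    config.image_width, config.image_height))
            exams.append(ExamRecord(e1, pid, "follow_up",
                                    config.image_width, config.image_height))
            pairs.append(PairManifestEntry(
                pair_id=pid, patient_id=pid, class_label=label,
                initial_exam_id=e0, followup_exam_id=e1,
                interval_days=float(rng.integers(1, 8)),
            ))
            n_lesions = 1 + int(rng.poisson(mu))
            for k in range(n_lesions):
                box0 = _random_box(rng, config)
                lesions.append(LesionROI(f"{pid}_L{k}", e0, label, box0))
                lesions.append(
                    LesionROI(f"{pid}_L{k}", e1, label,
                              _jitter_box(box0, rng, config)))
    for i in range(config.n_normal_exams):
        exams.append(ExamRecord(f"NORM{i:04d}", f"NORM{i:04d}", "unpaired",
                                config.image_width, config.image_height))

    return SyntheticCohort(
        exams=exams, lesions=lesions, pairs=pairs,
        detections_initial=[], detections_followup=[], pair_outcomes={},
    )


def _target_iou_shift(box: BoundingBox, target: float, rng: np.random.Generator,
                      cfg: SimulationConfig) -> BoundingBox:
    """Translate a box along x so that IOU with the original equals target.

    For a pure x-shift dx of a w-by-h box, IOU = (w-dx)/(w+dx), so
    dx = w*(1-t)/(1+t). The direction is chosen to stay inside the image.
    """
    dx = box.width * (1.0 - target) / (1.0 + target)
    left_ok = box.x_min - dx >= 0
    right_ok = box.x_min + dx + box.width <= cfg.image_width
    if left_ok and right_ok:
        sign = -1.0 if rng.random() < 0.5 else 1.0
    else:
        sign = -1.0 if left_ok else 1.0
    return BoundingBox(box.x_min + sign * dx, box.y_min, box.width, box.height)


def simulate_detector(cohort: SyntheticCohort, config: SimulationConfig) -> SyntheticCohort:
    """Emit detections for every exam and record ground-truth pair outcomes.

    Mutates and returns the cohort: fills ``detections_initial``,
    ``detections_followup`` and ``pair_outcomes``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    from .matching import iou  # local import avoids a cycle at module load

    labels = sorted(set(config.pair_counts) | set(config.sensitivity))
    rho = config.pair_correlation
    lesions_by_exam = cohort.lesions_by_exam()
    by_pair_exam: dict[str, list[LesionROI]] = lesions_by_exam

    dets_init: list[DetectionBox] = []
    dets_fu: list[DetectionBox] = []
    outcomes: dict[str, tuple[bool, bool]] = {}

    for pair in cohort.pairs:
        s = config.sensitivity.get(pair.class_label, 0.8)
        thresh = norm.ppf(s)
        exam_ids = (pair.initial_exam_id, pair.followup_exam_id)
        initial_lesions = by_pair_exam.get(exam_ids[0], [])
        followup_lesions = {l.lesion_id: l for l in by_pair_exam.get(exam_ids[1], [])}
        detected = [False, False]
        for les0 in initial_lesions:
            u = rng.standard_normal()
            eps = rng.standard_normal(2)
            z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps
            for e, exam_id in enumerate(exam_ids):
                if z[e] >= thresh:
                    continue
                detected[e] = True
                les = les0 if e == 0 else followup_lesions[les0.lesion_id]
                target = rng.uniform(0.55, 0.95)
                box = _target_iou_shift(les.box, target, rng, config)
                det = DetectionBox(
                    exam_id=exam_id, class_label=pair.class_label, box=box,
                    confidence=float(rng.beta(config.tp_conf_alpha,
                                              config.tp_conf_beta)),
                )
                (dets_init if e == 0 else dets_fu).append(det)
        outcomes[pair.pair_id] = (detected[0], detected[1])

    # false alarms on every exam, away from every lesion
    for exam in cohort.exams:
        exam_lesions = lesions_by_exam.get(exam.exam_id, [])
        n_fp = int(rng.poisson(config.fp_rate))
        for _ in range(n_fp):
            for _attempt in range(50):
                box = _random_box(rng, config)
                if all(iou(box, l.box) <= 0.1 for l in exam_lesions):
                    break
            else:
                continue  # crowded exam: drop this false alarm
            det = DetectionBox(
                exam_id=exam.exam_id,
                class_label=labels[int(rng.integers(len(labels)))],
                box=box,
                confidence=float(rng.beta(config.fp_conf_alpha,
                                          config.fp_conf_beta)),
            )
            if exam.role == "follow_up":
                dets_fu.append(det)
            else:
                dets_init.append(det)

    cohort.detections_initial = dets_init
    cohort.detections_followup = dets_fu
    cohort.pair_outcomes = outcomes
    return cohort


def end_to_end_fixture(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate a cohort, run the simulated detector and write all CSVs.

    Emits the full file set the command-line pipeline consumes, plus a
    manifest recording the seed and generator, and the ground-truth
    per-pair outcomes for self-consistency checks.
    """
    from . import io_formats as iof

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_detector(generate_cohort(config), config)

    paths = {
        "exams": out / "exams.csv",
        "lesions": out / "lesions.csv",
        "pairs": out / "pairs.csv",
        "detections_initial": out / "detections_initial.csv",
        "detections_followup": out / "detections_followup.csv",
        "outcomes": out / "outcomes.csv",
        "manifest": out / "manifest.json",
    }
    iof.write_exams(cohort.exams, paths["exams"])
    iof.write_lesions(cohort.lesions, paths["lesions"])
    iof.write_pairs(cohort.pairs, paths["pairs"])
    iof.write_detections(cohort.detections_initial, paths["detections_initial"])
    iof.write_detections(cohort.detections_followup, paths["detections_followup"])
    with open(paths["outcomes"], "w", encoding="utf-8") as fh:
        fh.write("pair_id,initial_detected,followup_detected\n")
        for pid in sorted(cohort.pair_outcomes):
            a, b = cohort.pair_outcomes[pid]
            fh.write(f"{pid},{int(a)},{int(b)}\n")
    manifest = {
        "generator": "numpy.random.Generator(PCG64) via SeedSequence",
        "seed": config.seed,
        "n_pairs": len(cohort.pairs),
        "n_normal_exams": config.n_normal_exams,
        "pair_counts": config.pair_counts,
        "fixture_version": "1",
    }
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return paths
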
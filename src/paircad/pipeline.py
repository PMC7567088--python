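"""End-to-end orchestration: simulate/load -> FROC -> agree -> correlate.

`run_pipeline` executes the whole reproducibility analysis and writes one
consolidated ``report.json``. Per disease class it builds the FROC curve
over the initial and normal exams, computes the JAFROC figure of merit
with its jackknife CI, selects a confidence cutoff for each requested
average-FP budget (or uses a fixed cutoff), classifies every exam pair
into the agreement cells at each operating point, and aggregates PPA and
CPPA across operating points. Finally the per-class detector recall is
rank-correlated with the per-class agreement using the exact small-sample
permutation test.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path


import yaml

from . import io_formats as iof
from .agreement import aggregate_over_operating_points, evaluate_reproducibility
from .froc import DEFAULT_CUTOFF_GRID, collect_ratings, froc_curve, jafroc_fom, select_cutoff
from .matching import match_exam, recall
from .stats import spearman_exact
from .synthetic import SimulationConfig, generate_cohort, simulate_detector
from .types import Undefined

logger = logging.getLogger(__name__)

DEFAULT_FP_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one cutoff policy is active: a list of average-FP budgets
    (``fp_levels``, FROC-derived cutoffs, the default) or one
    ``fixed_cutoff``.
    """

    # inputs: either a simulation config (synthetic run) ...
    simulation: SimulationConfig | None = None
    # ... or paths to the four CSV tables plus per-exam detections
    lesions_path: str | None = None
    detections_initial_path: str | None = None
    detections_followup_path: str | None = None
    pairs_path: str | None = None
    exams_path: str | None = None

    fp_levels: tuple[float, ...] = DEFAULT_FP_LEVELS
    fixed_cutoff: float | None = None
    headline_fp_level: float = 0.6
    iou_threshold: float = 0.5
    classes: tuple[str, ...] | None = None  # None = all classes present
    seed: int = 0
    out_dir: str = "paircad_out"

    def validate(self) -> None:
        if self.fixed_cutoff is not None and self.fp_levels != ():
            if tuple(self.fp_levels) != DEFAULT_FP_LEVELS:
                raise ValueError("set either fixed_cutoff or fp_levels, not both")
        if self.fixed_cutoff is None and len(self.fp_levels) == 0:
            raise ValueError("one cutoff policy required: fp_levels or fixed_cutoff")
        synthetic = self.simulation is not None
        files = all(p is not None for p in (
            self.lesions_path, self.detections_initial_path,
            self.detections_followup_path, self.pairs_path, self.exams_path))
        if not synthetic and not files:
            raise ValueError("inputs missing: provide a simulation config or all file paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {
            f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if isinstance(cfg.fp_levels, list):
            cfg.fp_levels = tuple(cfg.fp_levels)
        if isinstance(cfg.classes, list):
            cfg.classes = tuple(cfg.classes)
        return cfg


def _num(v):
    return None if isinstance(v, Undefined) else v


def _reason(v):
    return v.reason if isinstance(v, Undefined) else None


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_detector(generate_cohort(sim), sim)
        return (cohort.exams, cohort.lesions, cohort.pairs,
                cohort.detections_initial + cohort.detections_followup)
    exams = iof.read_exams(config.exams_path)
    lesions = iof.read_lesions(config.lesions_path, allow_extra_labels=True)
    pairs = iof.read_pair_manifest(config.pairs_path, exams)
    detections = (iof.read_detections(config.detections_initial_path,
                                      allow_extra_labels=True)
                  + iof.read_detections(config.detections_followup_path,
                                        allow_extra_labels=True))
    return exams, lesions, pairs, detections


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the consolidated report document.

    Deterministic given (config, seed); the report is also written to
    ``<out_dir>/report.json``.
    """
    config.validate()
    exams, lesions, pairs, detections = _load_inputs(config)

    lesions_by_exam: dict[str, list] = {}
    for l in lesions:
        lesions_by_exam.setdefault(l.exam_id, []).append(l)
    detections_by_exam: dict[str, list] = {}
    for d in detections:
        detections_by_exam.setdefault(d.exam_id, []).append(d)

    class_labels = sorted({p.class_label for p in pairs})
    if config.classes is not None:
        class_labels = [c for c in class_labels if c in config.classes]
    if not class_labels:
        raise ValueError("no classes to analyse after subsetting")

    # FROC/JAFROC are scored on the initial exams plus the normal pool
    scored_exams = [e.exam_id for e in exams if e.role in ("initial", "unpaired")]

    class_blocks: dict[str, dict] = {}
    recall_by_class: dict[str, float | Undefined] = {}
    for label in class_labels:
        logger.info("stage froc: class %s", label)
        class_pairs = [p for p in pairs if p.class_label == label]
        dets_c = {e: [d for d in detections_by_exam.get(e, ())
                      if d.class_label == label] for e in scored_exams}
        les_c = {e: [l for l in lesions_by_exam.get(e, ())
                     if l.class_label == label] for e in scored_exams}
        curve = froc_curve(dets_c, les_c, scored_exams, label,
                           DEFAULT_CUTOFF_GRID, config.iou_threshold)
        lesion_ratings, normal_ratings = collect_ratings(
            dets_c, les_c, scored_exams, config.iou_threshold)
        fom = jafroc_fom(lesion_ratings, normal_ratings, label)

        if config.fixed_cutoff is not None:
            selections = [(None, config.fixed_cutoff, False)]
            headline_cutoff = config.fixed_cutoff
        else:
            selections = []
            headline_cutoff = None
            for level in config.fp_levels:
                sel = select_cutoff(curve, level)
                selections.append((level, sel.cutoff, sel.unattainable))
                if level == config.headline_fp_level:
                    headline_cutoff = sel.cutoff
            if headline_cutoff is None:
                headline_cutoff = selections[-1][1]

        logger.info("stage agree: class %s (%d pairs)", label, len(class_pairs))
        op_blocks = []
        agreement_results = []
        for level, cutoff, unattainable in selections:
            per_class = evaluate_reproducibility(
                class_pairs, lesions_by_exam, detections_by_exam,
                cutoff=cutoff, iou_threshold=config.iou_threshold)
            res = per_class[label]
            agreement_results.append(res)
            op_blocks.append({
                "fp_level": float(level) if level is not None else -1.0,
                "cutoff": float(cutoff),
                "fp_budget_unattainable": bool(unattainable),
                "a": res.counts.a, "b": res.counts.b,
                "c": res.counts.c, "d": res.counts.d,
                "ppa": _num(res.ppa), "ppa_reason": _reason(res.ppa),
                "cppa": _num(res.cppa), "cppa_reason": _reason(res.cppa),
            })

        if len(agreement_results) >= 2:
            agg = aggregate_over_operating_points(agreement_results)
        else:
            r = agreement_results[0]
            agg = {"ppa_mean": r.ppa, "ppa_sd": Undefined("single operating point"),
                   "cppa_mean": r.cppa, "cppa_sd": Undefined("single operating point"),
                   "n_points": 1, "n_excluded": 0}

        # detector recall at the headline operating point, initial exams only
        initial_sets = [
            match_exam(
                [d for d in detections_by_exam.get(p.initial_exam_id, ())
                 if d.class_label == label],
                [l for l in lesions_by_exam.get(p.initial_exam_id, ())
                 if l.class_label == label],
                cutoff=headline_cutoff, iou_threshold=config.iou_threshold)
            for p in class_pairs
        ]
        rec = recall(initial_sets)
        recall_by_class[label] = rec

        class_blocks[label] = {
            "n_pairs": len(class_pairs),
            "n_lesions": curve.n_lesions,
            "fom": None if isinstance(fom, Undefined) else fom.fom,
            "fom_ci_low": None if isinstance(fom, Undefined) else fom.ci_low,
            "fom_ci_high": None if isinstance(fom, Undefined) else fom.ci_high,
            "fom_reason": _reason(fom),
            "n_jackknife": 0 if isinstance(fom, Undefined) else fom.n_jackknife,
            "recall_at_headline": _num(rec),
            "recall_reason": _reason(rec),
            "headline_cutoff": float(headline_cutoff),
            "operating_points": op_blocks,
            "ppa_mean": _num(agg["ppa_mean"]), "ppa_sd": _num(agg["ppa_sd"]),
            "cppa_mean": _num(agg["cppa_mean"]), "cppa_sd": _num(agg["cppa_sd"]),
            "n_points_excluded": agg["n_excluded"],
        }

    correlation: dict[str, dict | None] = {"ppa": None, "cppa": None}
    recs = {c: recall_by_class[c] for c in class_labels
            if not isinstance(recall_by_class[c], Undefined)}
    for metric in ("ppa", "cppa"):
        usable = [c for c in recs
                  if class_blocks[c][f"{metric}_mean"] is not None]
        if len(usable) >= 3:
            try:
                res = spearman_exact(
                    [recs[c] for c in usable],
                    [class_blocks[c][f"{metric}_mean"] for c in usable])
                correlation[metric] = {
                    "rho": res.rho, "p_two_sided": res.p_two_sided,
                    "n": res.n, "method": res.method,
                }
            except ValueError as exc:
                logger.warning("stage correlate (%s): %s", metric, exc)

    report = {
        "iou_threshold": float(config.iou_threshold),
        "fp_levels": [float(v) for v in config.fp_levels]
                     if config.fixed_cutoff is None else [],
        "fixed_cutoff": config.fixed_cutoff,
        "headline_fp_level": float(config.headline_fp_level),
        "seed": config.seed,
        "classes": class_blocks,
        "correlation": correlation,
    }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iof.write_report(report, out_dir / "report.json")
    report["schema_version"] = iof.REPORT_SCHEMA_VERSION
    return report


def _fmt(v, reason=None, digits=2) -> str:
    if v is None:
        return f"NA({reason})" if reason else "NA"
    return f"{v:.{digits}f}"


def render_summary(report: dict) -> str:
    """Fixed-width per-class summary table of FOM, PPA and CPPA."""
    header = (f"{'Class':<7}{'FOM (95% CI)':<24}{'PPA (%)':<18}{'CPPA (%)':<18}"
              f"{'Recall (%)':<12}{'Pairs':>6}")
    lines = [header, "-" * len(header)]
    for label, blk in sorted(report["classes"].items()):
        if blk["fom"] is None:
            fom = f"NA({blk.get('fom_reason')})"
        else:
            fom = (f"{blk['fom']:.2f} "
                   f"[{blk['fom_ci_low']:.2f}-{blk['fom_ci_high']:.2f}]")
        ppa = _fmt(blk["ppa_mean"])
        if blk["ppa_sd"] is not None and blk["ppa_mean"] is not None:
            ppa += f" ± {blk['ppa_sd']:.2f}"
        cppa = _fmt(blk["cppa_mean"])
        if blk["cppa_sd"] is not None and blk["cppa_mean"] is not None:
            cppa += f" ± {blk['cppa_sd']:.2f}"
        rec = _fmt(blk["recall_at_headline"], blk.get("recall_reason"))
        lines.append(f"{label:<7}{fom:<24}{ppa:<18}{cppa:<18}{rec:<12}"
                     f"{blk['n_pairs']:>6}")
    corr = report.get("correlation", {})
    for metric in ("ppa", "cppa"):
        c = corr.get(metric)
        if c:
            lines.append(
                f"Spearman recall vs {metric.upper()}: rho={c['rho']:.3f}, "
                f"p={c['p_two_sided']:.3f} (n={c['n']}, {c['method']})")
    return "\n".join(lines)
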
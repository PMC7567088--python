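"""Readers and writers for the package's stable text formats.

Four CSV tables (UTF-8, comma-separated, header required, ``.`` decimal)
carry the data: ``lesions.csv``, ``detections.csv``, ``exams.csv`` and
``pairs.csv``; COCO-style JSON is accepted as an alternative dialect for
lesions and detections (bbox = [x, y, w, h], origin top-left, pixel
units — the same convention the matcher uses). Analysis results go to a
versioned ``report.json`` with deterministic key ordering, validated
against the shipped structural schema.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    DEFAULT_CLASSES,
    BoundingBox,
    DetectionBox,
    ExamRecord,
    LesionROI,
    PairManifestEntry,
    Undefined,
    ValidationError,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"

LESION_COLUMNS = ["exam_id", "lesion_id", "label", "x_min", "y_min", "width", "height"]
DETECTION_COLUMNS = ["exam_id", "label", "x_min", "y_min", "width", "height", "confidence"]
EXAM_COLUMNS = ["exam_id", "patient_id", "role", "image_width", "image_height"]
PAIR_COLUMNS = ["pair_id", "patient_id", "label", "initial_exam_id",
                "followup_exam_id", "interval_days"]


class ParseError(ValueError):
    """A file failed to parse under the named dialect."""


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 — surface as a parse error
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _check_label(label: str, classes: Sequence[str], allow_extra: bool, where: str) -> None:
    if not allow_extra and label not in classes:
        raise ValidationError(
            f"{where}: unknown class label {label!r} (expected one of {list(classes)})"
        )


def _float(df_value: str, path, line: int, column: str) -> float:
    try:
        return float(df_value)
    except ValueError:
        raise ParseError(
            f"{path}, line {line}: column {column!r} is not a number: {df_value!r}"
        ) from None


def read_lesions(
    path,
    dialect: str = "csv",
    classes: Sequence[str] = DEFAULT_CLASSES,
    allow_extra_labels: bool = False,
) -> list[LesionROI]:
    """Read reference lesion boxes from CSV or COCO-style JSON."""
    if dialect == "coco_json":
        records = _read_coco(path, want_score=False, classes=classes,
                             allow_extra_labels=allow_extra_labels)
        lesions = [
            LesionROI(lesion_id=r["id"], exam_id=r["exam_id"],
                      class_label=r["label"], box=r["box"])
            for r in records
        ]
    elif dialect == "csv":
        df = _read_csv(path, LESION_COLUMNS)
        lesions = []
        for i, row in enumerate(df.itertuples(index=False)):
            line = i + 2  # header is line 1
            _check_label(row.label, classes, allow_extra_labels, f"{path}, line {line}")
            try:
                box = BoundingBox(
                    _float(row.x_min, path, line, "x_min"),
                    _float(row.y_min, path, line, "y_min"),
                    _float(row.width, path, line, "width"),
                    _float(row.height, path, line, "height"),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}, line {line}: {exc}") from None
            lesions.append(
                LesionROI(lesion_id=row.lesion_id, exam_id=row.exam_id,
                          class_label=row.label, box=box)
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    seen: set[tuple[str, str]] = set()
    for l in lesions:
        key = (l.exam_id, l.lesion_id)
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate lesion_id {l.lesion_id!r} in exam {l.exam_id!r}"
            )
        seen.add(key)
    return lesions


def read_detections(
    path,
    dialect: str = "csv",
    classes: Sequence[str] = DEFAULT_CLASSES,
    allow_extra_labels: bool = False,
) -> list[DetectionBox]:
    """Read detector output boxes (with confidences) from CSV or COCO JSON."""
    if dialect == "coco_json":
        records = _read_coco(path, want_score=True, classes=classes,
                             allow_extra_labels=allow_extra_labels)
        return [
            DetectionBox(exam_id=r["exam_id"], class_label=r["label"],
                         box=r["box"], confidence=r["score"])
            for r in records
        ]
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_csv(path, DETECTION_COLUMNS)
    detections = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        _check_label(row.label, classes, allow_extra_labels, f"{path}, line {line}")
        try:
            box = BoundingBox(
                _float(row.x_min, path, line, "x_min"),
                _float(row.y_min, path, line, "y_min"),
                _float(row.width, path, line, "width"),
                _float(row.height, path, line, "height"),
            )
            det = DetectionBox(
                exam_id=row.exam_id, class_label=row.label, box=box,
                confidence=_float(row.confidence, path, line, "confidence"),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {line}: {exc}") from None
        detections.append(det)
    return detections


def _read_coco(path, want_score: bool, classes, allow_extra_labels):
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    images = {img["id"]: img for img in doc.get("images", [])}
    categories = {c["id"]: c["name"] for c in doc.get("categories", [])}
    annotations = doc.get("annotations", doc.get("detections", []))
    records = []
    for k, ann in enumerate(annotations):
        where = f"{path}, annotation {k}"
        img_id = ann.get("image_id")
        exam_id = str(images.get(img_id, {}).get("file_name", img_id))
        label = categories.get(ann.get("category_id"), str(ann.get("category_id")))
        _check_label(label, classes, allow_extra_labels, where)
        bbox = ann.get("bbox")
        if not isinstance(bbox, (list, tuple)) or len(bbox) != 4:
            raise ParseError(f"{where}: bbox must be [x, y, w, h]")
        try:
            box = BoundingBox(*map(float, bbox))
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{where}: {exc}") from None
        rec = {"id": str(ann.get("id", k)), "exam_id": exam_id,
               "label": label, "box": box}
        if want_score:
            if "score" not in ann:
                raise ParseError(f"{where}: missing 'score'")
            rec["score"] = float(ann["score"])
        records.append(rec)
    return records


def read_exams(path) -> list[ExamRecord]:
    df = _read_csv(path, EXAM_COLUMNS)
    exams = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        if row.exam_id in seen:
            raise ValidationError(f"{path}, line {line}: duplicate exam_id {row.exam_id!r}")
        seen.add(row.exam_id)
        exams.append(
            ExamRecord(
                exam_id=row.exam_id, patient_id=row.patient_id, role=row.role,
                image_width=int(_float(row.image_width, path, line, "image_width")),
                image_height=int(_float(row.image_height, path, line, "image_height")),
            )
        )
    return exams


def read_pair_manifest(path, cohort: Iterable[ExamRecord]) -> list[PairManifestEntry]:
    """Read the pair manifest and validate every exam reference against the cohort."""
    known = {e.exam_id for e in cohort}
    df = _read_csv(path, PAIR_COLUMNS)
    pairs = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        for ref in (row.initial_exam_id, row.followup_exam_id):
            if ref not in known:
                raise ValidationError(
                    f"{path}, line {line}: pair {row.pair_id!r} references "
                    f"unknown exam {ref!r}"
                )
        pairs.append(
            PairManifestEntry(
                pair_id=row.pair_id, patient_id=row.patient_id,
                class_label=row.label,
                initial_exam_id=row.initial_exam_id,
                followup_exam_id=row.followup_exam_id,
                interval_days=_float(row.interval_days, path, line, "interval_days"),
            )
        )
    tally = Counter(p.class_label for p in pairs)
    logger.info("pair manifest %s: %d pairs, per class %s", path, len(pairs), dict(tally))
    return pairs


# --- writers ---------------------------------------------------------------

def write_lesions(lesions: Iterable[LesionROI], path) -> None:
    rows = [
        {"exam_id": l.exam_id, "lesion_id": l.lesion_id, "label": l.class_label,
         "x_min": l.box.x_min, "y_min": l.box.y_min,
         "width": l.box.width, "height": l.box.height}
        for l in lesions
    ]
    pd.DataFrame(rows, columns=LESION_COLUMNS).to_csv(path, index=False)


def write_detections(detections: Iterable[DetectionBox], path) -> None:
    rows = [
        {"exam_id": d.exam_id, "label": d.class_label,
         "x_min": d.box.x_min, "y_min": d.box.y_min,
         "width": d.box.width, "height": d.box.height,
         "confidence": d.confidence}
        for d in detections
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def write_exams(exams: Iterable[ExamRecord], path) -> None:
    rows = [
        {"exam_id": e.exam_id, "patient_id": e.patient_id, "role": e.role,
         "image_width": e.image_width, "image_height": e.image_height}
        for e in exams
    ]
    pd.DataFrame(rows, columns=EXAM_COLUMNS).to_csv(path, index=False)


def write_pairs(pairs: Iterable[PairManifestEntry], path) -> None:
    rows = [
        {"pair_id": p.pair_id, "patient_id": p.patient_id, "label": p.class_label,
         "initial_exam_id": p.initial_exam_id,
         "followup_exam_id": p.followup_exam_id,
         "interval_days": p.interval_days}
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, index=False)


# --- report ----------------------------------------------------------------

#: Structural schema of report.json: required key -> type (or nested dict).
#: ``float | None`` fields encode undefined statistics as null with a
#: companion "<key>_reason" string.
REPORT_SCHEMA = {
    "schema_version": str,
    "iou_threshold": float,
    "fp_levels": list,
    "headline_fp_level": float,
    "classes": dict,  # label -> class block, see CLASS_BLOCK_SCHEMA
    "correlation": dict,
}

CLASS_BLOCK_SCHEMA = {
    "n_pairs": int,
    "operating_points": list,
    "ppa_mean": (float, type(None)),
    "ppa_sd": (float, type(None)),
    "cppa_mean": (float, type(None)),
    "cppa_sd": (float, type(None)),
}

OPERATING_POINT_SCHEMA = {
    "fp_level": float,
    "cutoff": float,
    "a": int,
    "b": int,
    "c": int,
    "d": int,
    "ppa": (float, type(None)),
    "cppa": (float, type(None)),
}


def encode_value(v):
    """JSON encoding for statistic values: Undefined -> None."""
    if isinstance(v, Undefined):
        return None
    return v


def undefined_reason(v):
    return v.reason if isinstance(v, Undefined) else None


def write_report(results: dict, path) -> None:
    """Write a report dict as schema-versioned, byte-deterministic JSON."""
    if not results.get("classes"):
        raise ValueError("report must contain at least one class block")
    doc = dict(results)
    doc["schema_version"] = REPORT_SCHEMA_VERSION
    validate_report(doc)
    text = json.dumps(doc, indent=2, sort_keys=True, allow_nan=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    validate_report(doc)
    return doc


def _check_block(block: dict, schema: dict, where: str) -> None:
    for key, typ in schema.items():
        if key not in block:
            raise ValidationError(f"report {where}: missing key {key!r}")
        val = block[key]
        ok_types = typ if isinstance(typ, tuple) else (typ,)
        # ints are acceptable where floats are expected
        if float in ok_types and isinstance(val, int) and not isinstance(val, bool):
            continue
        if not isinstance(val, ok_types):
            raise ValidationError(
                f"report {where}.{key}: expected {typ}, got {type(val).__name__}"
            )


def validate_report(doc: dict) -> None:
    """Structural validation of a report document; raises on violation."""
    _check_block(doc, REPORT_SCHEMA, "$")
    if doc["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported report schema version {doc['schema_version']!r}"
        )
    if not doc["classes"]:
        raise ValidationError("report $.classes: must contain at least one class")
    for label, block in doc["classes"].items():
        _check_block(block, CLASS_BLOCK_SCHEMA, f"$.classes.{label}")
        for k, op in enumerate(block["operating_points"]):
            _check_block(op, OPERATING_POINT_SCHEMA, f"$.classes.{label}.op[{k}]")
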
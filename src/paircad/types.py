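"""Core record types for paired-exam lesion-detection evaluation.

All geometry is in pixel units with a top-left origin and the COCO box
convention ``(x_min, y_min, width, height)``, 0-based. Records are frozen
dataclasses validated on construction; invalid geometry or confidences are
rejected at the type level so downstream arithmetic never sees them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Default lesion classes: nodule/mass, consolidation, interstitial opacity,
#: pleural effusion, pneumothorax.
DEFAULT_CLASSES: tuple[str, ...] = ("N", "C", "IO", "PLE", "PN")


class ValidationError(ValueError):
    """An input record violates a type invariant."""


@dataclass(frozen=True)
class Undefined:
    """Typed marker for a statistic that is undefined on the given input.

    Used instead of NaN/0/100 so that callers must handle the degenerate
    case explicitly (e.g. agreement with no positive pairs, recall with no
    reference lesions).
    """

    reason: str

    def __bool__(self) -> bool:  # an undefined value is never truthy
        return False


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left corner plus positive width and height."""

    x_min: float
    y_min: float
    width: float
    height: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.width, self.height)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite box coordinates: {vals}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValidationError(f"negative box origin: {vals}")
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(f"degenerate box (width/height must be > 0): {vals}")

    @property
    def x_max(self) -> float:
        return self.x_min + self.width

    @property
    def y_max(self) -> float:
        return self.y_min + self.height

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class LesionROI:
    """A reference lesion: radiologist ROI reduced to its bounding box."""

    lesion_id: str
    exam_id: str
    class_label: str
    box: BoundingBox


@dataclass(frozen=True)
class DetectionBox:
    """A detector output box with a class label and confidence score."""

    exam_id: str
    class_label: str
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0) or not math.isfinite(self.confidence):
            raise ValidationError(
                f"confidence must lie in [0, 1], got {self.confidence!r}"
            )


@dataclass(frozen=True)
class ExamRecord:
    """One radiograph: identity, patient, pairing role and image size."""

    exam_id: str
    patient_id: str
    role: str  # initial | follow_up | unpaired
    image_width: int = 1000
    image_height: int = 1000

    _ROLES = ("initial", "follow_up", "unpaired")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValidationError(
                f"exam {self.exam_id}: role {self.role!r} not in {self._ROLES}"
            )
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValidationError(f"exam {self.exam_id}: non-positive image size")


@dataclass(frozen=True)
class PairManifestEntry:
    """Links a patient's initial and follow-up exam for one disease class."""

    pair_id: str
    patient_id: str
    class_label: str
    initial_exam_id: str
    followup_exam_id: str
    interval_days: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_exam_id == self.followup_exam_id:
            raise ValidationError(
                f"pair {self.pair_id}: initial and follow-up exam must differ"
            )
        if self.interval_days < 0:
            raise ValidationError(f"pair {self.pair_id}: negative interval")
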
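"""Hierarchical quantification of lesion masks into ordinal clinical features.

Each lesion type is reduced to a small feature triple:

* ``grade`` — a quartile bin (1-4) of the lesion's extent relative to the
  cornea, 0 when the lesion is absent;
* ``occludes_pupil`` — whether the lesion overlaps the pupil (scar,
  blue-light ulcer, and neovascularization only);
* ``quadrants`` — how many corneal quadrants the lesion touches (same three
  types).

Descemetocele and anterior-chamber abscess carry a grade only.  The abscess
grade defaults to a depth measure (fraction of the cornea's vertical extent
the fluid level spans), with the plain area-fraction variant selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .regions import (
    LESION_TAGS,
    EmptyRegionError,
    EyeRegionSet,
    area_ratio,
    overlap_indicator,
    quadrant_count,
    quadrant_partition,
    vertical_extent_ratio,
)

#: Lesion types whose policy rules include pupil occlusion and quadrant count.
FULL_FEATURE_TAGS = ("scar", "blue_ulcer", "neovascularization")

#: Lesion types graded by extent only.
GRADE_ONLY_TAGS = ("descemetocele", "abscess")

ABSCESS_MODES = ("depth", "area")
OCCLUSION_TARGETS = ("pupil", "cornea")


@dataclass(frozen=True)
class LesionFeatures:
    """Quantified features of a single lesion type in one eye.

    ``occludes_pupil`` and ``quadrants`` are ``None`` for the grade-only
    lesion types (descemetocele, abscess).
    """

    grade: int
    occludes_pupil: int | None = None
    quadrants: int | None = None

    def __post_init__(self):
        if self.grade not in (0, 1, 2, 3, 4):
            raise ValueError(f"grade must be in 0..4, got {self.grade}")
        if self.occludes_pupil not in (None, 0, 1):
            raise ValueError("occludes_pupil must be 0, 1 or None")
        if self.quadrants is not None and self.quadrants not in range(5):
            raise ValueError("quadrants must be in 0..4 or None")


@dataclass(frozen=True)
class QuantifiedFeatures:
    """Per-lesion features for one eye; all five lesion tags are present."""

    eye_id: str | None
    lesions: Mapping[str, LesionFeatures]

    def __post_init__(self):
        missing = set(LESION_TAGS) - set(self.lesions)
        if missing:
            raise ValueError(f"missing lesion tags: {sorted(missing)}")
        object.__setattr__(self, "lesions", MappingProxyType(dict(self.lesions)))

    def to_row(self) -> dict:
        """Flatten to a numeric feature row (CSV / DataFrame friendly)."""
        row: dict = {"eye_id": self.eye_id}
        for tag in LESION_TAGS:
            f = self.lesions[tag]
            row[f"{tag}_grade"] = f.grade
            if tag in FULL_FEATURE_TAGS:
                row[f"{tag}_occludes"] = f.occludes_pupil
                row[f"{tag}_quadrants"] = f.quadrants
        return row


def feature_columns() -> list[str]:
    """Deterministic order of the numeric feature columns of ``to_row``."""
    cols = []
    for tag in LESION_TAGS:
        cols.append(f"{tag}_grade")
        if tag in FULL_FEATURE_TAGS:
            cols.append(f"{tag}_occludes")
            cols.append(f"{tag}_quadrants")
    return cols


def grade_fraction(r: float) -> int:
    """Quartile grade of a fraction in [0, 1].

    Bins follow the published policy rules with upper edges inclusive:
    [0, 0.25] -> 1, (0.25, 0.50] -> 2, (0.50, 0.75] -> 3, (0.75, 1.00] -> 4.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {r}")
    if r <= 0.25:
        return 1
    if r <= 0.50:
        return 2
    if r <= 0.75:
        return 3
    return 4


def _occlusion_target_mask(eye: EyeRegionSet, occlusion_target: str):
    if occlusion_target not in OCCLUSION_TARGETS:
        raise ValueError(f"unknown occlusion target {occlusion_target!r}")
    return eye.pupil if occlusion_target == "pupil" else eye.cornea


def _quantify_full(eye: EyeRegionSet, tag: str, occlusion_target: str) -> LesionFeatures:
    if not eye.has_lesion(tag):
        return LesionFeatures(grade=0, occludes_pupil=0, quadrants=0)
    lesion = eye.lesion(tag)
    grade = grade_fraction(area_ratio(lesion, eye.cornea))
    occludes = overlap_indicator(lesion, _occlusion_target_mask(eye, occlusion_target))
    quadrants = quadrant_count(lesion, quadrant_partition(eye.cornea))
    return LesionFeatures(grade=grade, occludes_pupil=occludes, quadrants=quadrants)


def quantify_scar(eye: EyeRegionSet, occlusion_target: str = "pupil") -> LesionFeatures:
    """Grade, pupil occlusion and quadrant occupancy of the corneal scar."""
    return _quantify_full(eye, "scar", occlusion_target)


def quantify_blue_ulcer(eye: EyeRegionSet, occlusion_target: str = "pupil") -> LesionFeatures:
    """Grade, pupil occlusion and quadrant occupancy of the fluorescein-stained ulcer."""
    return _quantify_full(eye, "blue_ulcer", occlusion_target)


def quantify_neovascularization(
    eye: EyeRegionSet, occlusion_target: str = "pupil"
) -> LesionFeatures:
    """Vessel ingrowth features; disconnected tufts are pooled as one region."""
    return _quantify_full(eye, "neovascularization", occlusion_target)


def quantify_descemetocele(eye: EyeRegionSet) -> LesionFeatures:
    """Area-fraction grade of the descemetocele (no occlusion/quadrant rules)."""
    if not eye.has_lesion("descemetocele"):
        return LesionFeatures(grade=0)
    return LesionFeatures(grade=grade_fraction(area_ratio(eye.lesion("descemetocele"), eye.cornea)))


def quantify_abscess(eye: EyeRegionSet, mode: str = "depth") -> LesionFeatures:
    """Grade of the anterior-chamber abscess.

    ``mode="depth"`` (default) grades the fraction of the cornea's vertical
    extent spanned by the fluid level; ``mode="area"`` grades the plain
    lesion-to-cornea area fraction.
    """
    if mode not in ABSCESS_MODES:
        raise ValueError(f"unknown abscess mode {mode!r}")
    if not eye.has_lesion("abscess"):
        return LesionFeatures(grade=0)
    lesion = eye.lesion("abscess")
    if mode == "depth":
        r = vertical_extent_ratio(lesion, eye.cornea)
    else:
        r = area_ratio(lesion, eye.cornea)
    return LesionFeatures(grade=grade_fraction(r))


def quantify_eye(
    eye: EyeRegionSet,
    abscess_mode: str = "depth",
    occlusion_target: str = "pupil",
) -> QuantifiedFeatures:
    """Quantify all five lesion types of one eye.

    Absent lesions (missing tag or empty mask) yield grade 0 and zero
    indicators.  Raises on an empty cornea: such an eye is unquantifiable.
    """
    if not eye.cornea.any():
        raise EmptyRegionError("cannot quantify an eye with an empty cornea mask")
    return QuantifiedFeatures(
        eye_id=eye.eye_id,
        lesions={
            "scar": quantify_scar(eye, occlusion_target),
            "descemetocele": quantify_descemetocele(eye),
            "abscess": quantify_abscess(eye, abscess_mode),
            "blue_ulcer": quantify_blue_ulcer(eye, occlusion_target),
            "neovascularization": quantify_neovascularization(eye, occlusion_target),
        },
    )
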
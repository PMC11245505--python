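"""Binary-mask geometry for anterior-eye region annotations.

The data model is an :class:`EyeRegionSet`: a corneal disc mask (interior of
the limbus), a pupil mask, and zero or more lesion masks of five types, all
rasterized on one pixel grid.  Coordinates are 0-based ``(row, col)`` with
row 0 at the top of the image; masks are boolean arrays of shape
``(height, width)``.

Everything downstream (grading, occlusion, quadrant occupancy) reduces to a
handful of exact pixel-counting operations defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: The five lesion types that can be annotated on a slit-lamp image.
LESION_TAGS = ("scar", "descemetocele", "abscess", "blue_ulcer", "neovascularization")

#: Quadrant order.  Image-frame quadrants about the corneal centroid; with
#: temporal taken as the left half of the image frame the indices read
#: superior-temporal, superior-nasal, inferior-nasal, inferior-temporal.
QUADRANT_NAMES = (
    "superior_temporal",
    "superior_nasal",
    "inferior_nasal",
    "inferior_temporal",
)


class MaskShapeError(ValueError):
    """Masks in one eye do not share a single grid shape."""


class EmptyRegionError(ValueError):
    """An operation that needs a non-empty region received an empty mask."""


class AnnotationError(ValueError):
    """Region masks violate an anatomical containment constraint."""


def as_mask(a) -> np.ndarray:
    """Coerce input to a 2-D boolean array (non-zero means inside)."""
    m = np.asarray(a)
    if m.ndim != 2:
        raise MaskShapeError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool, copy=False)


def _check_same_shape(*masks: np.ndarray) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise MaskShapeError(f"masks have mismatched shapes: {sorted(shapes)}")


@dataclass(frozen=True)
class EyeRegionSet:
    """All region masks of one eye on a common grid.

    Parameters
    ----------
    cornea
        Boolean mask of the corneal disc (interior of the limbus).
    pupil
        Boolean mask of the pupil.  Must be a subset of the cornea; use
        :meth:`from_masks` with ``pupil_policy="clip"`` to repair annotations
        that spill over the limbus.
    lesions
        Mapping from lesion tag (one of :data:`LESION_TAGS`) to boolean mask.
        A missing tag means the lesion is not present in this eye.
    eye_id
        Optional source-image identifier.
    """

    cornea: np.ndarray
    pupil: np.ndarray
    lesions: Mapping[str, np.ndarray] = field(default_factory=dict)
    eye_id: str | None = None

    def __post_init__(self):
        cornea = as_mask(self.cornea)
        pupil = as_mask(self.pupil)
        lesions = {tag: as_mask(m) for tag, m in dict(self.lesions).items()}
        unknown = set(lesions) - set(LESION_TAGS)
        if unknown:
            raise ValueError(f"unknown lesion tags: {sorted(unknown)}")
        _check_same_shape(cornea, pupil, *lesions.values())
        if np.any(pupil & ~cornea):
            raise AnnotationError(
                "pupil mask is not contained in the cornea mask; re-load with "
                "pupil_policy='clip' to clip it to the corneal disc"
            )
        object.__setattr__(self, "cornea", cornea)
        object.__setattr__(self, "pupil", pupil)
        object.__setattr__(self, "lesions", lesions)

    @classmethod
    def from_masks(
        cls,
        cornea,
        pupil,
        lesions: Mapping[str, np.ndarray] | None = None,
        eye_id: str | None = None,
        pupil_policy: str = "strict",
    ) -> "EyeRegionSet":
        """Build an eye, optionally clipping the pupil to the cornea.

        ``pupil_policy`` is ``"strict"`` (default; out-of-cornea pupil pixels
        raise :class:`AnnotationError`) or ``"clip"`` (pupil is intersected
        with the cornea before validation).
        """
        if pupil_policy not in ("strict", "clip"):
            raise ValueError(f"unknown pupil_policy {pupil_policy!r}")
        cornea = as_mask(cornea)
        pupil = as_mask(pupil)
        if pupil_policy == "clip":
            _check_same_shape(cornea, pupil)
            pupil = pupil & cornea
        return cls(cornea, pupil, dict(lesions or {}), eye_id)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cornea.shape

    def lesion(self, tag: str) -> np.ndarray:
        """Lesion mask for ``tag``; an all-false mask when absent."""
        if tag not in LESION_TAGS:
            raise ValueError(f"unknown lesion tag {tag!r}")
        m = self.lesions.get(tag)
        if m is None:
            return np.zeros(self.shape, dtype=bool)
        return m

    def has_lesion(self, tag: str) -> bool:
        """True when the tag is annotated with at least one pixel."""
        m = self.lesions.get(tag)
        return m is not None and bool(m.any())


@dataclass(frozen=True)
class QuadrantPartition:
    """Exact four-way partition of a cornea mask about its centroid.

    ``masks[i]`` follows :data:`QUADRANT_NAMES`; the four masks are pairwise
    disjoint and their union is the cornea mask.
    """

    masks: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    origin: tuple[float, float]

    def __iter__(self):
        return iter(self.masks)


def region_area(mask) -> int:
    """Number of pixels inside the region."""
    return int(np.count_nonzero(as_mask(mask)))


def centroid(mask) -> tuple[float, float]:
    """Arithmetic-mean ``(row, col)`` of the region's pixels."""
    m = as_mask(mask)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise EmptyRegionError("centroid of an empty mask is undefined")
    return float(rows.mean()), float(cols.mean())


def area_ratio(lesion, cornea) -> float:
    """Lesion-to-cornea area fraction, |lesion ∩ cornea| / |cornea|.

    The lesion is intersected with the cornea first, so annotations that
    spill past the limbus cannot push the ratio above 1.
    """
    lesion = as_mask(lesion)
    cornea = as_mask(cornea)
    _check_same_shape(lesion, cornea)
    denom = np.count_nonzero(cornea)
    if denom == 0:
        raise EmptyRegionError("area ratio undefined for an empty cornea")
    return float(np.count_nonzero(lesion & cornea) / denom)


def overlap_indicator(lesion, target) -> int:
    """1 iff the two regions share at least one pixel, else 0."""
    lesion = as_mask(lesion)
    target = as_mask(target)
    _check_same_shape(lesion, target)
    return int(np.any(lesion & target))


def quadrant_partition(cornea) -> QuadrantPartition:
    """Split the cornea into four image-frame quadrants about its centroid.

    A pixel's quadrant is decided by the sign of ``row - origin_row`` and
    ``col - origin_col``; a coordinate exactly on an axis breaks toward the
    lower-index quadrant of the eligible pair, so the assignment is
    deterministic and every cornea pixel lands in exactly one quadrant.
    """
    cornea = as_mask(cornea)
    orow, ocol = centroid(cornea)  # raises on empty cornea
    rows, cols = np.indices(cornea.shape)
    superior = rows <= orow
    masks = (
        cornea & superior & (cols <= ocol),  # superior-temporal
        cornea & superior & (cols > ocol),  # superior-nasal
        cornea & ~superior & (cols > ocol),  # inferior-nasal
        cornea & ~superior & (cols <= ocol),  # inferior-temporal
    )
    return QuadrantPartition(masks, (orow, ocol))


def quadrant_count(lesion, partition: QuadrantPartition) -> int:
    """Number of corneal quadrants the lesion touches (0-4)."""
    lesion = as_mask(lesion)
    _check_same_shape(lesion, *partition.masks)
    return sum(int(np.any(lesion & q)) for q in partition.masks)


def occupied_quadrants(lesion, partition: QuadrantPartition) -> tuple[int, ...]:
    """Indices (per :data:`QUADRANT_NAMES`) of quadrants the lesion touches."""
    lesion = as_mask(lesion)
    _check_same_shape(lesion, *partition.masks)
    return tuple(i for i, q in enumerate(partition.masks) if np.any(lesion & q))


def vertical_extent_ratio(lesion, cornea) -> float:
    """Fraction of the cornea's vertical (row) extent the lesion spans.

    Counts the distinct rows that contain lesion pixels lying within the
    cornea's column span, divided by the number of distinct rows containing
    cornea pixels, capped at 1.  This is the depth-style measure for layered
    collections such as a hypopyon: a fluid level filling the inferior fifth
    of the cornea scores 0.2 regardless of its area.
    """
    lesion = as_mask(lesion)
    cornea = as_mask(cornea)
    _check_same_shape(lesion, cornea)
    crows, ccols = np.nonzero(cornea)
    if crows.size == 0:
        raise EmptyRegionError("vertical extent undefined for an empty cornea")
    in_span = np.zeros_like(lesion)
    in_span[:, ccols.min() : ccols.max() + 1] = True
    lrows = np.nonzero(lesion & in_span)[0]
    n_cornea_rows = np.unique(crows).size
    n_lesion_rows = np.unique(lrows).size
    return float(min(n_lesion_rows / n_cornea_rows, 1.0))
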
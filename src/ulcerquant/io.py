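"""Readers and writers: PNG masks and label maps, CSV tables, JSON reports.

Mask files are 8-bit grayscale PNGs with 0 = background and 255 = region,
one file per region, named ``<eye_id>_<region>.png``.  A combined label map
is an 8-bit PNG with exclusive codes 0 = background, 1 = cornea, 2 = pupil,
3 = lesion (precedence lesion > pupil > cornea when flattening).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .quantify import feature_columns
from .regions import LESION_TAGS, EyeRegionSet

LABEL_CODES = {"background": 0, "cornea": 1, "pupil": 2, "lesions": 3}


class FileFormatError(ValueError):
    """A file's content does not match the expected schema."""


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit grayscale PNG (0/255)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG; any non-zero pixel counts as inside."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_label_map(path, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 255:
        raise FileFormatError("label codes must fit in 8 bits")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(Path(path), format="PNG")


def read_label_map(path, n_classes: int = 4) -> np.ndarray:
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L")).astype(np.int64)
    if arr.max() >= n_classes:
        raise FileFormatError(
            f"{path}: label code {arr.max()} outside [0, {n_classes})"
        )
    return arr


def flatten_eye(eye: EyeRegionSet) -> np.ndarray:
    """Flatten an eye to the combined label map (lesion > pupil > cornea)."""
    labels = np.zeros(eye.shape, dtype=np.int64)
    labels[eye.cornea] = LABEL_CODES["cornea"]
    labels[eye.pupil] = LABEL_CODES["pupil"]
    for tag in LESION_TAGS:
        labels[eye.lesion(tag)] = LABEL_CODES["lesions"]
    return labels


def write_eye_masks(directory, eye: EyeRegionSet, eye_id: str | None = None) -> dict[str, str]:
    """Write one PNG per region; returns region -> filename for the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    eid = eye_id or eye.eye_id
    if not eid:
        raise ValueError("an eye_id is required to name mask files")
    names = {}
    for region, mask in (("cornea", eye.cornea), ("pupil", eye.pupil)):
        fname = f"{eid}_{region}.png"
        write_mask(directory / fname, mask)
        names[region] = fname
    for tag in LESION_TAGS:
        if eye.has_lesion(tag):
            fname = f"{eid}_{tag}.png"
            write_mask(directory / fname, eye.lesions[tag])
            names[tag] = fname
    return names


def read_eye_masks(
    directory, manifest_row: Mapping[str, str], pupil_policy: str = "strict"
) -> EyeRegionSet:
    """Load one eye from a manifest row of region filenames.

    The row must name ``eye_id``, ``cornea`` and ``pupil`` files; lesion
    columns are optional and an empty cell means the lesion is absent.
    """
    directory = Path(directory)
    eye_id = manifest_row.get("eye_id")
    for region in ("cornea", "pupil"):
        if not manifest_row.get(region):
            raise FileFormatError(f"eye {eye_id!r}: missing {region} mask filename")
    cornea = read_mask(directory / manifest_row["cornea"])
    pupil = read_mask(directory / manifest_row["pupil"])
    lesions = {}
    for tag in LESION_TAGS:
        fname = manifest_row.get(tag)
        if fname and not (isinstance(fname, float) and np.isnan(fname)):
            lesions[tag] = read_mask(directory / fname)
    return EyeRegionSet.from_masks(cornea, pupil, lesions, eye_id, pupil_policy=pupil_policy)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if "eye_id" not in df.columns:
        raise FileFormatError(f"{path}: manifest must have an eye_id column")
    return df


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_features_csv(path) -> pd.DataFrame:
    """Read a quantified-features CSV, validating every feature cell is numeric."""
    df = pd.read_csv(path)
    missing = [c for c in feature_columns() if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing feature columns {missing}")
    for col in feature_columns():
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise FileFormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        df[col] = coerced
    return df


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["patient_id", "age", "sex", "bcva", "ulcer_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing clinical columns {missing}")
    return df


def read_outcomes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise FileFormatError(f"{path}: outcomes table must have a patient_id column")
    return df


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_REPORT_REQUIRED = (
    "accuracy",
    "auc",
    "ci_low",
    "ci_high",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "precision",
    "recall",
    "f1",
)


def write_report_json(path, report: Mapping) -> None:
    """Write a prognosis metric panel, validating the schema first."""
    missing = [k for k in _REPORT_REQUIRED if k not in report]
    if missing:
        raise FileFormatError(f"report missing keys: {missing}")
    for k in _REPORT_REQUIRED:
        v = report[k]
        if v is not None and not isinstance(v, (int, float)):
            raise FileFormatError(f"report key {k!r} is not numeric: {v!r}")
    Path(path).write_text(json.dumps(dict(report), indent=2, sort_keys=True) + "\n")


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
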
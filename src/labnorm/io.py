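"""Readers and writers: NIfTI volumes/masks, landmark tables, transforms, ratings.

NIfTI I/O goes through SimpleITK, so header geometry (spacing, origin,
direction) round-trips exactly.  Landmarks and ratings are plain delimited
text; transforms are a 12-number text file (row-major rotation, then
translation, then center, all documented in-file).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import (
    LANDMARK_NAMES,
    METHODS,
    BinaryMask,
    LandmarkTriplet,
    RatingRecord,
    RigidTransform,
    Volume,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "read_ratings",
    "write_ratings",
]


def read_volume(path) -> Volume:
    """Read a 3D NIfTI image; header spacing/origin/direction are preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path} is {img.GetDimension()}D; expected a 3D volume")
    return Volume.from_sitk(img)


def write_volume(volume: Volume, path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    sitk.WriteImage(volume.to_sitk(), str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask.from_volume(vol, threshold=0.5)


def write_mask(mask: BinaryMask, path) -> None:
    write_volume(mask.to_volume(np.uint8), path)


def read_landmarks(path) -> LandmarkTriplet:
    """Read the three canonical fiducials from a CSV (name, x_mm, y_mm, z_mm).

    Names are matched case-insensitively; exactly the three canonical rows
    must be present, and the points must be non-collinear.
    """
    path = Path(path)
    found: dict[str, np.ndarray] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().startswith("#"):
                continue
            name = row[0].strip().lower()
            if name in ("name", ""):  # header row
                continue
            if name not in LANDMARK_NAMES:
                raise ValueError(f"unknown landmark name {row[0]!r} in {path}")
            if name in found:
                raise ValueError(f"duplicate landmark {name!r} in {path}")
            if len(row) < 4:
                raise ValueError(f"landmark row for {name!r} needs name,x,y,z")
            found[name] = np.array([float(v) for v in row[1:4]])
    missing = [n for n in LANDMARK_NAMES if n not in found]
    if missing:
        raise ValueError(f"missing landmark(s) {missing} in {path}")
    return LandmarkTriplet(*(found[n] for n in LANDMARK_NAMES))


def write_landmarks(landmarks: LandmarkTriplet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x_mm", "y_mm", "z_mm"])
        for name, pt in zip(LANDMARK_NAMES, landmarks.as_array()):
            writer.writerow([name, repr(float(pt[0])), repr(float(pt[1])), repr(float(pt[2]))])


_TFM_HEADER = """\
# rigid transform: p_fixed = R (p_moving - c) + c + t
# 12 numbers: rows 1-3 rotation R (row-major), row 4 translation t (mm), row 5 center c (mm)
"""


def write_transform(transform: RigidTransform, path) -> None:
    rows = np.vstack(
        [transform.rotation, transform.translation[None, :], transform.center[None, :]]
    )
    with open(path, "w") as fh:
        fh.write(_TFM_HEADER)
        for row in rows:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_transform(path) -> RigidTransform:
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.extend(float(v) for v in line.split())
    if len(values) != 15:
        raise ValueError(f"transform file {path} must contain 15 numbers (9 + 3 + 3), got {len(values)}")
    arr = np.asarray(values)
    return RigidTransform(arr[:9].reshape(3, 3), arr[9:12], arr[12:15])


def read_ratings(path) -> list[RatingRecord]:
    """Read a rating table CSV with columns dataset_id, method, rater_id, grade."""
    df = pd.read_csv(path)
    required = ["dataset_id", "method", "rater_id", "grade"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"rating table {path} is missing column(s) {missing}")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (str(row.dataset_id), str(row.method), str(row.rater_id))
        if key in seen:
            raise ValueError(f"duplicate rating for (dataset, method, rater) = {key}")
        seen.add(key)
        records.append(
            RatingRecord(str(row.dataset_id), str(row.method), str(row.rater_id), float(row.grade))
        )
    return records


def write_ratings(records: Iterable[RatingRecord], path) -> None:
    df = pd.DataFrame(
        [(r.dataset_id, r.method, r.rater_id, r.grade) for r in records],
        columns=["dataset_id", "method", "rater_id", "grade"],
    )
    df.to_csv(path, index=False)
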
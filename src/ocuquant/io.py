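"""Readers and writers for the pipeline's on-disk formats.

Images are grayscale PNG/TIFF; integer files are rescaled to floating
intensities in [0, 1] on read (value / dtype max) and written back as
16-bit.  Landmarks travel as CSV with header
``point_id,fixed_row,fixed_col,moving_row,moving_col``; transforms, ground
truth and results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .registration import LandmarkPairs, SimilarityTransform

__all__ = [
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "write_json",
]

LANDMARK_COLUMNS = ["point_id", "fixed_row", "fixed_col", "moving_row", "moving_col"]


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF into float intensities in [0, 1].

    Integer images are divided by their dtype maximum; floating images are
    passed through unchanged.  Multi-channel input is rejected: convert to
    single-channel grayscale upstream.
    """
    img = iio.imread(Path(path))
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel grayscale image, got shape "
            f"{img.shape}; convert RGB(A) input to grayscale first"
        )
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / np.iinfo(img.dtype).max
    img = img.astype(float)
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{path}: image contains non-finite values")
    return img


def write_image(path, image: np.ndarray) -> None:
    """Write float intensities in [0, 1] as 16-bit grayscale PNG/TIFF."""
    image = np.asarray(image, dtype=float)
    scaled = np.clip(image, 0.0, 1.0) * np.iinfo(np.uint16).max
    iio.imwrite(Path(path), np.round(scaled).astype(np.uint16))


def read_landmarks(path) -> LandmarkPairs:
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: landmark CSV missing columns {missing}")
    return LandmarkPairs(
        fixed_points=df[["fixed_row", "fixed_col"]].to_numpy(float),
        moving_points=df[["moving_row", "moving_col"]].to_numpy(float),
    )


def write_landmarks(path, landmarks: LandmarkPairs) -> None:
    df = pd.DataFrame(
        {
            "point_id": np.arange(len(landmarks)),
            "fixed_row": landmarks.fixed_points[:, 0],
            "fixed_col": landmarks.fixed_points[:, 1],
            "moving_row": landmarks.moving_points[:, 0],
            "moving_col": landmarks.moving_points[:, 1],
        }
    )
    df.to_csv(path, index=False)


def write_transform(path, transform: SimilarityTransform, rms_residual=None) -> None:
    payload = transform.to_dict()
    if rms_residual is not None:
        payload["rms_residual"] = float(rms_residual)
    write_json(path, payload)


def read_transform(path) -> SimilarityTransform:
    with open(path) as fh:
        return SimilarityTransform.from_dict(json.load(fh))


def write_json(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
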
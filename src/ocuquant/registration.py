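"""Landmark-based co-registration of paired retinal angiogram channels.

The vessel-reference (intravascular dextran) and fluorescein channels of one
eye are acquired sequentially, so they differ by a small pose/zoom change.
Given matched landmark pairs (typically vessel bifurcations picked in both
channels), a least-squares similarity transform — scale, rotation,
translation — is estimated mapping moving-channel coordinates onto the fixed
channel, and the moving image is resampled onto the fixed grid with bilinear
interpolation.  Pixels that map from outside the source frame are carried as
an explicit invalidity mask rather than a fill value, so downstream per-area
statistics stay unbiased.

Coordinates are 0-based ``(row, col)`` with pixel centers at integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform
from sklearn.base import BaseEstimator

__all__ = [
    "LandmarkPairs",
    "SimilarityTransform",
    "SimilarityRegistrator",
    "estimate_similarity",
    "apply_transform",
    "registration_residual",
]


@dataclass(frozen=True)
class LandmarkPairs:
    """Matched control points in the fixed and moving channels.

    Both arrays have shape ``(n, 2)`` in (row, col) pixels.  ``fixed_points[i]``
    and ``moving_points[i]`` mark the same anatomical feature.
    """

    fixed_points: np.ndarray
    moving_points: np.ndarray

    def __post_init__(self) -> None:
        fixed = np.asarray(self.fixed_points, dtype=float)
        moving = np.asarray(self.moving_points, dtype=float)
        if fixed.ndim != 2 or fixed.shape[1] != 2 or moving.shape != fixed.shape:
            raise ValueError(
                "landmarks must be two equal-length (n, 2) arrays of (row, col)"
            )
        if len(fixed) < 2:
            raise ValueError("insufficient landmarks: need at least 2 pairs")
        for name, pts in (("fixed", fixed), ("moving", moving)):
            if not np.isfinite(pts).all():
                raise ValueError(f"non-finite {name} landmark coordinates")
            if len(np.unique(pts, axis=0)) != len(pts):
                raise ValueError(f"degenerate configuration: duplicated {name} points")
        object.__setattr__(self, "fixed_points", fixed)
        object.__setattr__(self, "moving_points", moving)

    def __len__(self) -> int:
        return len(self.fixed_points)


@dataclass(frozen=True)
class SimilarityTransform:
    """Scale + rotation + translation in (row, col) pixel coordinates.

    Maps a moving-channel point ``m`` to the fixed frame:
    ``f = s·R(θ)·m + t``.
    """

    scale: float = 1.0
    rotation: float = 0.0  # radians, counter-clockwise in (row, col)
    translation: tuple[float, float] = (0.0, 0.0)  # (t_row, t_col)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("scale must be positive and finite")
        if not np.isfinite(self.rotation):
            raise ValueError("non-finite rotation")
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("non-finite translation")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (row, col, 1) column vectors."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.translation[0]],
                [self.scale * s, self.scale * c, self.translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "SimilarityTransform":
        matrix = np.asarray(matrix, dtype=float)
        scale = float(np.hypot(matrix[0, 0], matrix[1, 0]))
        rotation = float(np.arctan2(matrix[1, 0], matrix[0, 0]))
        return cls(
            scale=scale,
            rotation=rotation,
            translation=(float(matrix[0, 2]), float(matrix[1, 2])),
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) moving-frame (row, col) points into the fixed frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))])
        return (self.matrix @ homo.T).T[:, :2]

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform.from_matrix(np.linalg.inv(self.matrix))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return SimilarityTransform.from_matrix(self.matrix @ other.matrix)

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(self.rotation))

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation_deg": self.rotation_deg,
            "t_row": self.translation[0],
            "t_col": self.translation[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            scale=float(d["scale"]),
            rotation=float(np.radians(d["rotation_deg"])),
            translation=(float(d["t_row"]), float(d["t_col"])),
        )


def _as_xy(points_rc: np.ndarray) -> np.ndarray:
    # scikit-image transforms act on (x, y) = (col, row)
    return np.asarray(points_rc, dtype=float)[:, ::-1]


class SimilarityRegistrator(BaseEstimator):
    """Least-squares landmark registration, scikit-learn style.

    Estimates the transform ``f ≈ T(m)`` mapping moving-channel landmark
    coordinates onto the fixed channel by minimising the mean squared
    distance between transformed moving points and fixed points (Umeyama
    closed form for the similarity family).

    Parameters
    ----------
    transform_family : {"similarity", "affine", "euclidean"}
        Geometric model.  "similarity" (scale + rotation + translation) is
        the default: paired angiogram channels come from the same camera and
        session, so only pose and zoom differ.

    Attributes
    ----------
    transform_ : SimilarityTransform
        Estimated transform (similarity/euclidean families only).
    matrix_ : ndarray, shape (3, 3)
        Homogeneous matrix on (row, col, 1) vectors, any family.
    rms_residual_ : float
        Root-mean-square landmark distance after alignment, pixels.
    condition_ : float
        Condition number of the centred landmark configuration; large values
        flag near-collinear landmark sets.
    """

    def __init__(self, transform_family: str = "similarity"):
        self.transform_family = transform_family

    def fit(self, moving_points, fixed_points=None):
        """Estimate the transform from matched points.

        Accepts either ``fit(LandmarkPairs)`` or
        ``fit(moving_points, fixed_points)``.
        """
        if isinstance(moving_points, LandmarkPairs):
            pairs = moving_points
        else:
            pairs = LandmarkPairs(
                fixed_points=np.asarray(fixed_points, dtype=float),
                moving_points=np.asarray(moving_points, dtype=float),
            )
        if self.transform_family not in ("similarity", "affine", "euclidean"):
            raise ValueError(f"unknown transform family {self.transform_family!r}")
        if self.transform_family == "affine" and len(pairs) < 3:
            raise ValueError("insufficient landmarks: affine needs at least 3 pairs")

        tf = sktransform.estimate_transform(
            self.transform_family,
            _as_xy(pairs.moving_points),
            _as_xy(pairs.fixed_points),
        )
        if not np.all(np.isfinite(tf.params)):
            raise ValueError("degenerate configuration: transform estimation failed")

        # convert the (x, y) matrix to (row, col) convention: P M P with
        # P the axis-swap permutation
        p = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        self.matrix_ = p @ tf.params @ p
        if self.transform_family in ("similarity", "euclidean"):
            self.transform_ = SimilarityTransform.from_matrix(self.matrix_)
        else:
            self.transform_ = None
        centred = pairs.moving_points - pairs.moving_points.mean(axis=0)
        sv = np.linalg.svd(centred, compute_uv=False)
        self.condition_ = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
        self.rms_residual_ = registration_residual(pairs, self._as_transform())
        self.n_landmarks_ = len(pairs)
        return self

    def _as_transform(self):
        if getattr(self, "transform_", None) is not None:
            return self.transform_
        return self.matrix_

    def transform_points(self, points_rc) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))])
        return (self.matrix_ @ homo.T).T[:, :2]

    def transform_image(self, image: np.ndarray):
        """Resample ``image`` (moving channel) onto the fixed grid.

        Returns ``(aligned, valid)`` where ``valid`` is False wherever the
        output pixel sampled outside the source frame.
        """
        return apply_transform(image, self._as_transform())


def estimate_similarity(landmarks: LandmarkPairs) -> SimilarityTransform:
    """Least-squares similarity transform mapping moving onto fixed points."""
    return SimilarityRegistrator().fit(landmarks).transform_


def _matrix_of(transform) -> np.ndarray:
    if isinstance(transform, SimilarityTransform):
        return transform.matrix
    matrix = np.asarray(transform, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError("transform must be a SimilarityTransform or 3x3 matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite transform parameters")
    return matrix


def apply_transform(image: np.ndarray, transform) -> tuple[np.ndarray, np.ndarray]:
    """Warp the moving image into the fixed frame under ``transform``.

    The output pixel at fixed-frame location ``p`` is sampled bilinearly from
    the moving image at ``T⁻¹(p)``.  Returns ``(warped, valid)``; ``valid``
    marks pixels whose source location fell inside the moving frame.  Invalid
    pixels hold 0.0 in ``warped`` and must be excluded via the mask.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    matrix_rc = _matrix_of(transform)
    p = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    # skimage warp wants the output->input map in (x, y) convention
    inv_xy = sktransform.AffineTransform(matrix=p @ np.linalg.inv(matrix_rc) @ p)
    warped = sktransform.warp(
        image, inv_xy, order=1, mode="constant", cval=np.nan, preserve_range=True
    )
    valid = np.isfinite(warped)
    warped = np.where(valid, warped, 0.0)
    return warped, valid


def registration_residual(landmarks: LandmarkPairs, transform) -> float:
    """RMS distance (pixels) between transformed moving and fixed landmarks."""
    matrix = _matrix_of(transform)
    homo = np.column_stack(
        [landmarks.moving_points, np.ones(len(landmarks))]
    )
    mapped = (matrix @ homo.T).T[:, :2]
    d2 = np.sum((mapped - landmarks.fixed_points) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))
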
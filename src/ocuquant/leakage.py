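"""Fluorescein-leakage quantification from a co-registered channel pair.

After registration the two channels show the same vessels, but only the
fluorescein channel carries extravasated dye.  The pipeline is:

1. crop non-analyzable regions (optic nerve, outside the medullary band,
   artifacts, registration-invalid pixels) into an ``RoiMask``;
2. photometrically normalize the pair by fitting
   ``fluorescein ≈ gain·reference + offset`` with a robust linear regression
   restricted to vessel pixels — the only structures present in both
   channels — so acquisition gain/offset differences cancel;
3. subtract pixel-by-pixel, clipping negative residuals to zero (dye cannot
   be negative), leaving an image of extravasated fluorescein only;
4. report mean extravasated intensity per analyzable pixel ("fluorescein
   leakage") and percent inhibition relative to the control-group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "RoiMask",
    "LeakageResult",
    "InhibitionResult",
    "build_roi_mask",
    "VesselGainNormalizer",
    "normalize_pair",
    "subtract_extravasation",
    "leakage_score",
    "inhibition",
    "group_summary",
]


@dataclass(frozen=True)
class RoiMask:
    """Analyzable-pixel mask with per-category exclusion accounting.

    ``excluded_px`` attributes each excluded pixel to exactly one category,
    in priority order registration_invalid > optic_nerve >
    outside_medullary_band > artifact, so the categories are disjoint and
    ``analyzable_px + sum(excluded_px.values()) == total_px``.
    """

    analyzable: np.ndarray
    excluded_px: dict = field(default_factory=dict)

    @property
    def analyzable_px(self) -> int:
        return int(self.analyzable.sum())

    @property
    def total_px(self) -> int:
        return int(self.analyzable.size)


@dataclass(frozen=True)
class LeakageResult:
    """Mean extravasated intensity per analyzable pixel for one eye."""

    leakage: float  # intensity per pixel
    analyzable_area: int  # pixels
    eye_id: str = ""

    def __post_init__(self) -> None:
        if self.analyzable_area <= 0:
            raise ValueError("analyzable_area must be positive")
        if self.leakage < 0:
            raise ValueError("leakage must be nonnegative")


@dataclass(frozen=True)
class InhibitionResult:
    inhibition_pct: float  # may be negative (worse than control)
    control_mean_leakage: float
    n_controls: int


def build_roi_mask(
    image_shape: tuple[int, int],
    optic_nerve_region: tuple[tuple[float, float], float] | None = None,
    medullary_band: tuple[float, float] | None = None,
    artifact_regions: list[np.ndarray] | None = None,
    registration_validity: np.ndarray | None = None,
) -> RoiMask:
    """Compose the analyzable-pixel mask from the stated exclusions.

    Parameters
    ----------
    optic_nerve_region : ((row, col), radius) or None
        Disk to crop out.
    medullary_band : (row_lo, row_hi) or None
        Inclusive row range kept; everything outside is cropped.
    artifact_regions : list of boolean masks
        Manually flagged regions of insufficient image quality.
    registration_validity : boolean mask
        False where the registered moving channel sampled outside its frame.
    """
    h, w = image_shape
    if h <= 0 or w <= 0:
        raise ValueError("image shape must be positive")
    rows, cols = np.mgrid[0:h, 0:w]

    in_band = np.ones((h, w), dtype=bool)
    if medullary_band is not None:
        lo, hi = medullary_band
        if not (0 <= lo and hi < h):
            raise ValueError("medullary band outside image bounds")
        in_band = (rows >= lo) & (rows <= hi)

    in_nerve = np.zeros((h, w), dtype=bool)
    if optic_nerve_region is not None:
        (r0, c0), radius = optic_nerve_region
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise ValueError("optic nerve center outside image bounds")
        in_nerve = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2

    in_artifact = np.zeros((h, w), dtype=bool)
    for region in artifact_regions or []:
        region = np.asarray(region, dtype=bool)
        if region.shape != (h, w):
            raise ValueError("artifact region shape mismatch")
        in_artifact |= region

    reg_valid = (
        np.ones((h, w), dtype=bool)
        if registration_validity is None
        else np.asarray(registration_validity, dtype=bool)
    )
    if reg_valid.shape != (h, w):
        raise ValueError("registration validity shape mismatch")

    analyzable = in_band & ~in_nerve & ~in_artifact & reg_valid
    if not analyzable.any():
        raise ValueError("no analyzable pixels")

    # disjoint accounting, priority order
    excluded = ~analyzable
    reg_bad = excluded & ~reg_valid
    nerve = excluded & ~reg_bad & in_nerve
    outside = excluded & ~reg_bad & ~nerve & ~in_band
    artifact = excluded & ~reg_bad & ~nerve & ~outside
    return RoiMask(
        analyzable=analyzable,
        excluded_px={
            "registration_invalid": int(reg_bad.sum()),
            "optic_nerve": int(nerve.sum()),
            "outside_medullary_band": int(outside.sum()),
            "artifact": int(artifact.sum()),
        },
    )


class VesselGainNormalizer(BaseEstimator):
    """Photometric normalization of a co-registered channel pair.

    Fits ``fluorescein ≈ gain·reference + offset`` on vessel pixels inside
    the analyzable region.  Vessels carry intravascular dye in both
    channels, so the relation there is purely the acquisition gain/offset;
    extravascular leak pixels are excluded and do not bias the fit.  A Huber
    M-estimator (default) downweights stray pixels; on exactly linear data
    the fit is exact.

    With ``include_offset=False`` a pure gain is fitted through the origin.
    Vessel interiors are bright and nearly uniform, so the gain/offset
    split is poorly conditioned there; when the channels share a zero dark
    level (the usual case after acquisition dark-subtraction) the gain-only
    model is far more stable and is what the batch pipeline uses.

    Attributes
    ----------
    gain_ : float
        Fitted multiplicative gain; must be positive.
    offset_ : float
        Fitted additive offset (0 when ``include_offset=False``).
    n_pixels_ : int
        Vessel pixels used in the fit.
    """

    def __init__(
        self, robust: bool = True, min_pixels: int = 10, include_offset: bool = True
    ):
        self.robust = robust
        self.min_pixels = min_pixels
        self.include_offset = include_offset

    def fit(self, reference, fluorescein, vessel_mask, analyzable=None):
        reference = np.asarray(reference, dtype=float)
        fluorescein = np.asarray(fluorescein, dtype=float)
        sel = np.asarray(vessel_mask, dtype=bool)
        if analyzable is not None:
            sel = sel & np.asarray(analyzable, dtype=bool)
        x = reference[sel]
        y = fluorescein[sel]
        if x.size < self.min_pixels:
            raise ValueError(
                f"normalization failed: only {x.size} usable vessel pixels "
                f"(need >= {self.min_pixels})"
            )
        design = sm.add_constant(x) if self.include_offset else x[:, None]
        if self.robust and np.ptp(y - y.mean()) > 0:
            fit = sm.RLM(y, design, M=sm.robust.norms.HuberT()).fit()
        else:
            fit = sm.OLS(y, design).fit()
        if self.include_offset:
            offset, gain = fit.params
        else:
            offset, gain = 0.0, fit.params[0]
        if gain <= 0:
            raise ValueError(f"normalization failed: fitted gain {gain:.4g} <= 0")
        self.gain_ = float(gain)
        self.offset_ = float(offset)
        self.n_pixels_ = int(x.size)
        return self

    def transform(self, reference) -> np.ndarray:
        """Rescale the reference channel onto the fluorescein intensity scale."""
        return self.gain_ * np.asarray(reference, dtype=float) + self.offset_


def normalize_pair(
    reference_img: np.ndarray,
    fluorescein_img: np.ndarray,
    vessel_mask: np.ndarray,
    mask: RoiMask,
    robust: bool = True,
    include_offset: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(reference_scaled, fluorescein_img)`` on a common scale."""
    norm = VesselGainNormalizer(robust=robust, include_offset=include_offset).fit(
        reference_img, fluorescein_img, vessel_mask, mask.analyzable
    )
    return norm.transform(reference_img), np.asarray(fluorescein_img, dtype=float)


def subtract_extravasation(
    fluorescein_img: np.ndarray, reference_scaled: np.ndarray, mask: RoiMask
) -> np.ndarray:
    """Pixel-wise ``max(fluorescein − reference, 0)`` on analyzable pixels.

    The result contains only extravasated fluorescein: on vessels both
    channels agree after normalization, so residuals there are ≈ 0, and
    negative residuals (reference brighter than fluorescein, i.e. noise) are
    clipped to zero.  Non-analyzable pixels are set to 0 and must be
    excluded via the mask.
    """
    fluorescein_img = np.asarray(fluorescein_img, dtype=float)
    reference_scaled = np.asarray(reference_scaled, dtype=float)
    if fluorescein_img.shape != reference_scaled.shape:
        raise ValueError("channel shape mismatch")
    leak = np.clip(fluorescein_img - reference_scaled, 0.0, None)
    leak[~mask.analyzable] = 0.0
    return leak


def leakage_score(
    leak_image: np.ndarray, mask: RoiMask, eye_id: str = ""
) -> LeakageResult:
    """Mean extravasated intensity per analyzable pixel."""
    area = mask.analyzable_px
    if area == 0:
        raise ValueError("no analyzable pixels")
    total = float(np.asarray(leak_image, dtype=float)[mask.analyzable].sum())
    return LeakageResult(leakage=total / area, analyzable_area=area, eye_id=eye_id)


def inhibition(
    leakage_eye: LeakageResult | float, control_leakages: list
) -> InhibitionResult:
    """Percent inhibition of leakage relative to the control-group mean.

    ``100·(1 − leakage/mean(controls))``: an eye leaking exactly the control
    mean scores 0%, no leak scores 100%, and leak above the control mean is
    negative.
    """
    if len(control_leakages) == 0:
        raise ValueError("at least one control eye required")
    controls = [
        c.leakage if isinstance(c, LeakageResult) else float(c)
        for c in control_leakages
    ]
    control_mean = float(np.mean(controls))
    if control_mean <= 0:
        raise ValueError("uninformative control group: control mean leakage <= 0")
    value = (
        leakage_eye.leakage
        if isinstance(leakage_eye, LeakageResult)
        else float(leakage_eye)
    )
    return InhibitionResult(
        inhibition_pct=100.0 * (1.0 - value / control_mean),
        control_mean_leakage=control_mean,
        n_controls=len(controls),
    )


def group_summary(inhibitions: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean/sd of inhibition with exclusion bookkeeping.

    Parameters
    ----------
    inhibitions : DataFrame
        Columns ``group, eye_id, inhibition_pct`` and optionally
        ``excluded`` (boolean) with ``exclusion_reason``.  Excluded eyes are
        tallied but never enter the statistics.
    """
    df = inhibitions.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    rows = []
    for group, sub in df.groupby("group", sort=True):
        kept = sub.loc[~sub["excluded"], "inhibition_pct"].astype(float)
        if kept.empty:
            rows.append(
                {
                    "group": group,
                    "mean_inhibition": np.nan,
                    "sd": np.nan,
                    "n": 0,
                    "excluded_n": int(sub["excluded"].sum()),
                }
            )
            continue
        rows.append(
            {
                "group": group,
                "mean_inhibition": float(kept.mean()),
                "sd": float(kept.std(ddof=1)) if len(kept) > 1 else 0.0,
                "n": int(len(kept)),
                "excluded_n": int(sub["excluded"].sum()),
            }
        )
    if not rows:
        raise ValueError("empty group table")
    return pd.DataFrame(rows)
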
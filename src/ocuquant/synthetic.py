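"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The rabbit retina is merangiotic: its vessels run in a narrow horizontal
band (the medullary ray) adjacent to the optic nerve, and that band is the
analyzable region of an angiogram.  ``generate_vessel_scene`` emulates a
co-acquired channel pair of such a retina:

* a vessel-reference channel (intravascular high-MW dextran: vessels only),
* a fluorescein channel containing the same vessels at a different camera
  gain plus extravasated dye rendered as a blur halo around the vessels,
  mis-registered from the reference by a known similarity transform.

Everything the downstream stages estimate — the true transform, the true
extravasation field, the channel gain — is returned as ground truth, so
recovery can be asserted exactly.  Two further generators produce
mono-exponential intravitreal decay series with multiplicative noise and
ordinal four-rater lesion score tables.

All generators are pure functions of their config (seed included): the same
config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology

from .registration import LandmarkPairs, SimilarityTransform

__all__ = [
    "SceneConfig",
    "AngiogramPair",
    "GroundTruth",
    "PkSeriesConfig",
    "ScorerTableConfig",
    "generate_vessel_scene",
    "generate_pk_series",
    "generate_scorer_table",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic angiogram pair.

    Intensities are dimensionless floats with a nominal range of [0, 1];
    ``leak_intensity`` scales the expected extravascular dye signal and
    ``channel_gain`` is the fluorescein-channel acquisition gain relative to
    the reference channel.
    """

    image_height: int = 256
    image_width: int = 256
    vessel_branch_count: int = 6
    vessel_width_px: int = 7
    optic_nerve_center: tuple[int, int] = (128, 36)
    optic_nerve_radius: int = 18
    medullary_band_halfwidth: int = 48
    leak_intensity: float = 0.5
    leak_blur_sigma: float = 6.0
    channel_gain: float = 1.0
    transform_true: SimilarityTransform = field(default_factory=SimilarityTransform)
    noise_sigma: float = 0.01
    landmark_jitter_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "image_height",
            "image_width",
            "vessel_width_px",
            "optic_nerve_radius",
            "medullary_band_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vessel_branch_count < 1:
            raise ValueError("vessel_branch_count must be at least 1")
        if self.leak_intensity < 0:
            raise ValueError("leak_intensity must be nonnegative")
        if self.channel_gain <= 0:
            raise ValueError("channel_gain must be positive")
        if self.noise_sigma < 0 or self.landmark_jitter_sigma < 0:
            raise ValueError("noise scales must be nonnegative")
        r0, c0 = self.optic_nerve_center
        r = self.optic_nerve_radius
        if not (r <= r0 < self.image_height - r and r <= c0 < self.image_width - r):
            raise ValueError("optic nerve disk must lie fully inside the image")
        if (
            r0 - self.medullary_band_halfwidth < 0
            or r0 + self.medullary_band_halfwidth >= self.image_height
        ):
            raise ValueError("medullary band must lie inside the image")


@dataclass(frozen=True)
class AngiogramPair:
    """One eye's co-acquired channel pair plus its picked landmarks."""

    reference: np.ndarray  # vessel-reference (fixed) channel
    fluorescein: np.ndarray  # fluorescein (moving) channel
    landmarks: LandmarkPairs
    eye_id: str = "synthetic"


@dataclass(frozen=True)
class GroundTruth:
    vessel_mask: np.ndarray  # binary, fixed frame
    leak_field: np.ndarray  # extravasated dye only, fixed frame
    transform_true: SimilarityTransform  # moving -> fixed
    leak_intensity: float
    channel_gain: float
    landmarks_true: LandmarkPairs  # noiseless landmark correspondence


def _grow_vessel_tree(config: SceneConfig, rng: np.random.Generator):
    """Random binary branching tree from the optic-nerve disk along the band.

    Returns the centreline mask and the bifurcation/terminal node list used
    as landmark candidates.
    """
    h, w = config.image_height, config.image_width
    r0, c0 = config.optic_nerve_center
    band_lo = r0 - config.medullary_band_halfwidth
    band_hi = r0 + config.medullary_band_halfwidth
    centreline = np.zeros((h, w), dtype=bool)
    nodes: list[tuple[float, float]] = []

    # trunks leave the nerve rim fanning toward the far side of the image
    stack = []
    for i in range(config.vessel_branch_count):
        ang = (i / max(config.vessel_branch_count - 1, 1) - 0.5) * np.deg2rad(70)
        ang += rng.normal(0.0, 0.05)
        start = (
            r0 + config.optic_nerve_radius * np.sin(ang),
            c0 + config.optic_nerve_radius * np.cos(ang),
        )
        stack.append((start, ang, 0))

    max_depth = 4
    while stack:
        (row, col), ang, depth = stack.pop()
        n_steps = int(rng.integers(3, 6))
        for _ in range(n_steps):
            step = rng.uniform(14.0, 22.0)
            # wander, pulled back toward horizontal and into the band
            ang = 0.8 * ang + rng.normal(0.0, 0.12)
            mid = 0.5 * (band_lo + band_hi)
            ang -= 0.002 * (row - mid)
            nr = row + step * np.sin(ang)
            nc = col + step * np.cos(ang)
            nr = float(np.clip(nr, band_lo + 1, band_hi - 1))
            if nc >= w - 2 or nc <= 1:
                nc = float(np.clip(nc, 1, w - 2))
                rr, cc = skdraw.line(round(row), round(col), round(nr), round(nc))
                centreline[rr, cc] = True
                nodes.append((nr, nc))
                break
            rr, cc = skdraw.line(round(row), round(col), round(nr), round(nc))
            centreline[rr, cc] = True
            row, col = nr, nc
        else:
            nodes.append((row, col))
            if depth < max_depth:
                spread = rng.uniform(0.25, 0.5)
                stack.append(((row, col), ang + spread, depth + 1))
                stack.append(((row, col), ang - spread, depth + 1))
            continue
    return centreline, nodes


def generate_vessel_scene(config: SceneConfig) -> tuple[AngiogramPair, GroundTruth]:
    """Render one synthetic angiogram pair with full ground truth.

    The clean scene is built in the fixed frame: a smoothed vessel image
    ``v``, a leak field ``λ·blur(vessel_mask)`` restricted to extravascular
    pixels, and the clean fluorescein scene ``a·v + leak``.  The moving
    channel is that scene resampled under ``transform_true⁻¹`` (so the true
    transform maps moving coordinates back onto the fixed frame), after
    which per-channel Gaussian noise is added.  Landmarks are vessel
    bifurcations; the moving copies carry Gaussian jitter of
    ``landmark_jitter_sigma`` pixels emulating imperfect manual picking.
    """
    rng = np.random.default_rng(config.seed)
    centreline, nodes = _grow_vessel_tree(config, rng)
    radius = max(1, config.vessel_width_px // 2)
    vessel_mask = morphology.dilation(centreline, morphology.disk(radius))

    # smooth rendering: avoids aliased single-pixel edges that resample badly
    vessel_img = ndimage.gaussian_filter(vessel_mask.astype(float), 1.0)

    leak_field = config.leak_intensity * ndimage.gaussian_filter(
        vessel_mask.astype(float), config.leak_blur_sigma
    )
    leak_field[vessel_mask] = 0.0

    scene_fluo = config.channel_gain * vessel_img + leak_field

    t = config.transform_true
    # moving image M satisfies M(T⁻¹(p)) = scene(p): features at fixed
    # location p appear in the moving frame at T⁻¹(p)
    from .registration import apply_transform

    moving, _ = apply_transform(scene_fluo, t.inverse())

    # landmarks: bifurcation/terminal nodes, at least 4, away from borders
    h, w = config.image_height, config.image_width
    pts = [
        (r, c) for (r, c) in nodes if 4 <= r < h - 4 and 4 <= c < w - 4
    ]
    # deduplicate (rounded) while preserving generation order
    seen, fixed_pts = set(), []
    for r, c in pts:
        key = (round(r, 1), round(c, 1))
        if key not in seen:
            seen.add(key)
            fixed_pts.append((r, c))
    if len(fixed_pts) < 4:
        raise RuntimeError(
            "vessel tree produced fewer than 4 landmark nodes; "
            "increase vessel_branch_count"
        )
    fixed_pts = np.asarray(fixed_pts, dtype=float)
    moving_true = t.inverse().apply(fixed_pts)
    landmarks_true = LandmarkPairs(fixed_pts, moving_true)
    jitter = rng.normal(0.0, config.landmark_jitter_sigma, moving_true.shape)
    moving_jittered = moving_true + jitter
    landmarks = LandmarkPairs(fixed_pts, moving_jittered)

    reference = vessel_img + rng.normal(0.0, config.noise_sigma, vessel_img.shape)
    fluorescein = moving + rng.normal(0.0, config.noise_sigma, moving.shape)
    reference = np.clip(reference, 0.0, None)
    fluorescein = np.clip(fluorescein, 0.0, None)

    pair = AngiogramPair(
        reference=reference,
        fluorescein=fluorescein,
        landmarks=landmarks,
        eye_id=f"synthetic-{config.seed}",
    )
    truth = GroundTruth(
        vessel_mask=vessel_mask,
        leak_field=leak_field,
        transform_true=t,
        leak_intensity=config.leak_intensity,
        channel_gain=config.channel_gain,
        landmarks_true=landmarks_true,
    )
    return pair, truth


@dataclass(frozen=True)
class PkSeriesConfig:
    """Mono-exponential intravitreal decay with multiplicative noise.

    ``amount(day) = A0·exp(−k·day)·ε`` with ε mean-one lognormal of the
    stated coefficient of variation.
    """

    A0: float = 100.0  # pmol per eye at day 0
    k: float = 0.1137  # per-day elimination rate (t1/2 ≈ 6.1 d)
    sample_days: tuple[float, ...] = (21.0, 24.0, 26.0, 30.0, 31.0)
    cv: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")
        if self.k <= 0:
            raise ValueError("elimination rate k must be positive")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        days = np.asarray(self.sample_days, dtype=float)
        if len(days) == 0 or np.any(np.diff(days) <= 0):
            raise ValueError("sample_days must be nonempty and strictly increasing")


def generate_pk_series(config: PkSeriesConfig) -> pd.DataFrame:
    """Sample terminal drug amounts; columns ``day, replicate, amount_pmol``."""
    rng = np.random.default_rng(config.seed)
    days = np.repeat(np.asarray(config.sample_days, float), config.n_replicates)
    reps = np.tile(np.arange(config.n_replicates), len(config.sample_days))
    clean = config.A0 * np.exp(-config.k * days)
    if config.cv > 0:
        sigma = np.sqrt(np.log1p(config.cv**2))
        eps = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=days.shape)
    else:
        eps = np.ones_like(days)
    return pd.DataFrame(
        {"day": days, "replicate": reps, "amount_pmol": clean * eps}
    )


@dataclass(frozen=True)
class ScorerTableConfig:
    """Ordinal lesion-score tables from several masked raters.

    Each rater reports ``clip(round(true_severity + noise), 1, 4)`` — the
    1–4 angiographic severity scale with additive rater noise, rounded
    half-up to an integer score.
    """

    true_severity: tuple[float, ...] = (4.0,) * 6 + (1.0,) * 18
    rater_noise_sd: float = 0.0
    n_raters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        sev = np.asarray(self.true_severity, dtype=float)
        if sev.size == 0:
            raise ValueError("true_severity must be nonempty")
        if np.any(sev < 1) or np.any(sev > 4):
            raise ValueError("true severities must lie in [1, 4]")
        if self.n_raters < 1:
            raise ValueError("n_raters must be at least 1")
        if self.rater_noise_sd < 0:
            raise ValueError("rater_noise_sd must be nonnegative")

    @property
    def n_lesions(self) -> int:
        return len(self.true_severity)


def generate_scorer_table(config: ScorerTableConfig) -> pd.DataFrame:
    """Simulate the rater table: ``lesion_id, score_1..score_n``."""
    rng = np.random.default_rng(config.seed)
    sev = np.asarray(config.true_severity, dtype=float)[:, None]
    noise = rng.normal(0.0, config.rater_noise_sd, (config.n_lesions, config.n_raters))
    scores = np.clip(np.floor(sev + noise + 0.5), 1, 4).astype(int)
    out = pd.DataFrame(
        scores, columns=[f"score_{j + 1}" for j in range(config.n_raters)]
    )
    out.insert(0, "lesion_id", [f"lesion-{i:03d}" for i in range(config.n_lesions)])
    return out
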
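"""ROI masking, photometric normalization, subtraction and leakage scoring."""

import numpy as np
import pandas as pd
import pytest

from conftest import BAND, ON_CENTER, ON_RADIUS
from ocuquant.leakage import (
    VesselGainNormalizer,
    build_roi_mask,
    group_summary,
    inhibition,
    leakage_score,
    normalize_pair,
    subtract_extravasation,
)
from ocuquant.pipeline import QuantifyConfig, quantify_pair
from ocuquant.synthetic import SceneConfig, generate_vessel_scene

SHAPE = (256, 256)


def _roi(**kwargs):
    return build_roi_mask(SHAPE, **kwargs)


class TestRoiMask:
    def test_no_exclusions_full_frame(self):
        roi = _roi()
        assert roi.analyzable.all()
        assert sum(roi.excluded_px.values()) == 0

    def test_disk_exclusion_matches_brute_force_count(self):
        (r0, c0), radius = (60.5, 70.0), 12.0
        roi = _roi(optic_nerve_region=((r0, c0), radius))
        brute = sum(
            (r - r0) ** 2 + (c - c0) ** 2 <= radius**2
            for r in range(SHAPE[0])
            for c in range(SHAPE[1])
        )
        assert roi.excluded_px["optic_nerve"] == brute

    def test_area_conservation(self):
        roi = _roi(
            optic_nerve_region=(ON_CENTER, ON_RADIUS),
            medullary_band=BAND,
            artifact_regions=[np.pad(np.ones((20, 20), bool), ((0, 236), (0, 236)))],
        )
        assert roi.analyzable_px + sum(roi.excluded_px.values()) == roi.total_px

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError, match="no analyzable pixels"):
            _roi(artifact_regions=[np.ones(SHAPE, bool)])


class TestNormalization:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        ref = rng.random(SHAPE)
        vessels = np.zeros(SHAPE, bool)
        vessels[40:60, 40:200] = True
        fluo = 2.0 * ref + 0.1
        norm = VesselGainNormalizer().fit(ref, fluo, vessels)
        assert norm.gain_ == pytest.approx(2.0, abs=1e-9)
        assert norm.offset_ == pytest.approx(0.1, abs=1e-9)
        scaled, _ = normalize_pair(ref, fluo, vessels, _roi())
        assert np.abs(fluo - scaled)[vessels].max() < 1e-9

    def test_identical_images_unit_gain(self):
        rng = np.random.default_rng(1)
        img = rng.random(SHAPE)
        vessels = img > 0.7
        norm = VesselGainNormalizer().fit(img, img, vessels)
        assert norm.gain_ == pytest.approx(1.0, abs=1e-9)
        assert norm.offset_ == pytest.approx(0.0, abs=1e-9)

    def test_gain_recovered_despite_leak(self, clean_scene):
        # leak lives off-vessel, so the vessel-restricted fit sees pure gain
        pair, truth = clean_scene
        roi = _roi(medullary_band=BAND)
        norm = VesselGainNormalizer().fit(
            pair.reference, pair.fluorescein, truth.vessel_mask, roi.analyzable
        )
        assert norm.gain_ == pytest.approx(truth.channel_gain, rel=0.05)

    def test_too_few_vessel_pixels_rejected(self):
        ref = np.random.default_rng(2).random(SHAPE)
        vessels = np.zeros(SHAPE, bool)
        vessels[0, :5] = True
        with pytest.raises(ValueError, match="normalization failed"):
            VesselGainNormalizer().fit(ref, ref, vessels)


class TestSubtraction:
    def test_equal_images_zero_leak(self):
        img = np.random.default_rng(3).random(SHAPE)
        leak = subtract_extravasation(img, img, _roi())
        assert np.all(leak == 0)

    def test_negative_residuals_clipped(self):
        fluo = np.zeros(SHAPE)
        ref = np.ones(SHAPE)
        leak = subtract_extravasation(fluo, ref, _roi())
        assert leak.min() == 0.0

    def test_noiseless_scene_recovers_ground_truth_leak(self, clean_scene):
        pair, truth = clean_scene
        roi = _roi(medullary_band=BAND)
        scaled, fluo = normalize_pair(
            pair.reference, pair.fluorescein, truth.vessel_mask, roi
        )
        leak = subtract_extravasation(fluo, scaled, roi)
        off_vessel = roi.analyzable & ~truth.vessel_mask
        assert np.abs(leak - truth.leak_field)[off_vessel].max() < 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_extravasation(np.zeros((4, 4)), np.zeros((5, 5)), _roi())


class TestLeakageScore:
    def test_zero_and_constant_leak(self):
        roi = _roi(medullary_band=BAND)
        assert leakage_score(np.zeros(SHAPE), roi).leakage == 0.0
        const = np.full(SHAPE, 0.37)
        assert leakage_score(const, roi).leakage == pytest.approx(0.37)

    def test_score_proportional_to_leak_intensity(self):
        # λ ∈ {0.2, 0.4, 0.8}: strictly increasing, proportional within 2%
        scores = []
        for lam in (0.2, 0.4, 0.8):
            pair, truth = generate_vessel_scene(
                SceneConfig(leak_intensity=lam, noise_sigma=0.0,
                            landmark_jitter_sigma=0.0, seed=3)
            )
            roi = _roi(medullary_band=BAND)
            scaled, fluo = normalize_pair(
                pair.reference, pair.fluorescein, truth.vessel_mask, roi
            )
            leak = subtract_extravasation(fluo, scaled, roi)
            scores.append(leakage_score(leak, roi).leakage)
        assert scores[0] < scores[1] < scores[2]
        assert scores[1] / scores[0] == pytest.approx(2.0, rel=0.02)
        assert scores[2] / scores[0] == pytest.approx(4.0, rel=0.02)


class TestInhibition:
    def test_control_mean_leakage_is_zero_percent(self):
        res = inhibition(2.0, [1.0, 2.0, 3.0])
        assert res.inhibition_pct == pytest.approx(0.0)
        assert res.n_controls == 3

    def test_no_leak_is_full_inhibition(self):
        assert inhibition(0.0, [1.5]).inhibition_pct == pytest.approx(100.0)

    def test_double_control_leak_is_minus_hundred(self):
        assert inhibition(4.0, [2.0]).inhibition_pct == pytest.approx(-100.0)

    def test_uninformative_controls_rejected(self):
        with pytest.raises(ValueError, match="uninformative control group"):
            inhibition(1.0, [0.0, 0.0])
        with pytest.raises(ValueError):
            inhibition(1.0, [])


class TestGroupSummary:
    def test_identical_values_zero_sd(self):
        df = pd.DataFrame(
            {"group": ["a"] * 3, "eye_id": list("xyz"), "inhibition_pct": [40.0] * 3}
        )
        row = group_summary(df).iloc[0]
        assert (row["mean_inhibition"], row["sd"], row["n"]) == (40.0, 0.0, 3)

    def test_excluded_eye_bookkeeping(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 3,
                "eye_id": list("xyz"),
                "inhibition_pct": [40.0, 50.0, 999.0],
                "excluded": [False, False, True],
            }
        )
        row = group_summary(df).iloc[0]
        assert row["n"] == 2 and row["excluded_n"] == 1
        assert row["mean_inhibition"] == pytest.approx(45.0)


class TestScaleInvariance:
    def test_global_gain_cancels_in_inhibition(self, misregistered_scene):
        # multiplying both channels by c > 0 leaves relative leakage intact
        pair, _ = misregistered_scene
        config = QuantifyConfig(
            optic_nerve_region=(ON_CENTER, ON_RADIUS), medullary_band=BAND
        )
        base = quantify_pair(
            pair.reference, pair.fluorescein, pair.landmarks, config
        ).result.leakage
        scaled = quantify_pair(
            3.0 * pair.reference, 3.0 * pair.fluorescein, pair.landmarks, config
        ).result.leakage
        assert scaled / base == pytest.approx(3.0, rel=1e-6)
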
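import math

import numpy as np
import pytest

from cemap import (
    RoiMask,
    ctcf,
    max_project,
    occupancy,
    partition_center_periphery,
    sum_project,
)
from cemap.morphometry import ContactMeasure, fit_contact_outline
from cemap.partition import (
    center_periphery_analysis,
    channel_comparison,
    default_background_roi,
)
from test_morphometry import ellipse_image


def fitted_ellipse(a_um, b_um, pixel=0.02, angle=0.0):
    img, _ = ellipse_image(a_um, b_um, pixel, angle=angle)
    return fit_contact_outline(img, pixel_size=pixel, threshold=50.0)


class TestPartition:
    def test_continuous_scaling_gives_three_quarters(self):
        # a similar ellipse with both semi-axes scaled by sqrt(0.75) has
        # exactly 3/4 of the area
        assert math.sqrt(0.75) ** 2 == pytest.approx(0.75)

    @pytest.mark.parametrize("a,b,angle", [(2.0, 3.0, 0.0), (2.5, 1.5, 0.6)])
    def test_rasterized_center_fraction(self, a, b, angle):
        roi, meas = fitted_ellipse(a, b, angle=angle)
        part = partition_center_periphery(roi, meas)
        frac = part.center.size / roi.size
        assert frac == pytest.approx(0.75, abs=0.01)

    def test_circle_center_radius(self):
        roi, meas = fitted_ellipse(2.0, 2.0)
        part = partition_center_periphery(roi, meas)
        # max radial extent of the center mask ≈ R*sqrt(0.75)
        ys, xs = np.nonzero(part.center.mask)
        cy, cx = ys.mean(), xs.mean()
        rmax = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2).max() * 0.02
        assert rmax == pytest.approx(2.0 * math.sqrt(0.75), abs=0.05)

    def test_masks_partition_contact_exactly(self):
        roi, meas = fitted_ellipse(2.0, 1.2, angle=0.3)
        part = partition_center_periphery(roi, meas)
        assert not (part.center.mask & part.periphery.mask).any()
        np.testing.assert_array_equal(
            part.center.mask | part.periphery.mask, roi.mask
        )

    def test_lateral_view_rejected(self):
        roi, meas = fitted_ellipse(2.0, 1.2)
        lateral = ContactMeasure(
            long_diameter=meas.long_diameter,
            short_diameter=meas.short_diameter,
            area=meas.area,
            view="lateral",
        )
        with pytest.raises(ValueError, match="en-face"):
            partition_center_periphery(roi, lateral)


class TestCtcf:
    def test_arithmetic_identity(self):
        img = np.zeros((20, 20))
        roi = np.zeros((20, 20), bool)
        roi[:5, :10] = True  # 50 px
        img[roi] = 20.0      # integrated density 1000
        bg = np.zeros((20, 20), bool)
        bg[15:, :] = True
        img[bg] = 2.0
        val = ctcf(img, roi, bg)
        assert val.integrated_density == pytest.approx(1000.0)
        assert val.ctcf == pytest.approx(1000.0 - 50 * 2.0)

    def test_zero_background(self):
        img = np.zeros((10, 10))
        roi = np.zeros((10, 10), bool)
        roi[:3] = True
        img[roi] = 5.0
        bg = np.zeros((10, 10), bool)
        bg[8:] = True
        val = ctcf(img, roi, bg)
        assert val.ctcf == pytest.approx(val.integrated_density)

    def test_uniform_image_gives_zero(self):
        img = np.full((12, 12), 7.3)
        roi = np.zeros((12, 12), bool)
        roi[2:6, 2:6] = True
        bg = np.zeros((12, 12), bool)
        bg[8:, 8:] = True
        assert ctcf(img, roi, bg).ctcf == pytest.approx(0.0, abs=1e-9)

    def test_linearity_in_image(self, rng):
        img1 = rng.random((16, 16)) * 10
        img2 = rng.random((16, 16)) * 10
        roi = np.zeros((16, 16), bool)
        roi[2:8, 2:8] = True
        bg = np.zeros((16, 16), bool)
        bg[12:, 12:] = True
        total = ctcf(img1 + img2, roi, bg).ctcf
        assert total == pytest.approx(
            ctcf(img1, roi, bg).ctcf + ctcf(img2, roi, bg).ctcf
        )

    def test_empty_or_overlapping_rois_rejected(self):
        img = np.ones((8, 8))
        roi = np.zeros((8, 8), bool)
        roi[:2] = True
        with pytest.raises(ValueError):
            ctcf(img, roi, np.zeros((8, 8), bool))
        with pytest.raises(ValueError):
            ctcf(img, roi, roi)


class TestCenterPeriphery:
    def test_factor_two_channels_normalize_to_half(self):
        roi, meas = fitted_ellipse(2.0, 1.4)
        part = partition_center_periphery(roi, meas)
        base = np.zeros(roi.mask.shape)
        base[roi.mask] = 10.0
        bg = np.zeros(roi.mask.shape, bool)
        bg[:5, :5] = True
        table = center_periphery_analysis(
            {"A": 2 * base, "B": base}, part, bg
        )
        df = table.data
        for roi_name in ("center", "periphery"):
            sub = df[df["roi"] == roi_name].set_index("channel")["normalized"]
            assert sub["A"] == pytest.approx(1.0)
            assert sub["B"] == pytest.approx(0.5)

    def test_glur2_dominates_periphery_only(self, noiseless_pairs):
        # receptor labeling confined to the rim: normalized GluR2 beats the
        # connexin channel in the periphery and loses in the center
        for stack, gt in noiseless_pairs:
            proj = max_project(stack)
            roi = RoiMask(gt.masks["contact"], provenance="contact-outline")
            _, meas = fit_contact_outline(
                gt.masks["contact"].astype(float),
                pixel_size=gt.mask_pixel_size,
                threshold=0.5,
            )
            part = partition_center_periphery(roi, meas)
            bg = default_background_roi(proj.channel("Cx35.5"), roi.mask)
            table = center_periphery_analysis(
                {
                    "Cx35.5": proj.channel("Cx35.5"),
                    "GluR2": proj.channel("GluR2"),
                },
                part,
                bg,
            )
            df = table.data.set_index(["roi", "channel"])["normalized"]
            assert df[("center", "Cx35.5")] > df[("center", "GluR2")]
            assert df[("periphery", "GluR2")] == pytest.approx(1.0)

    def test_identical_channels_not_distinguishable(self, rng):
        vals_a = rng.normal(1.0, 0.1, 8)
        t, p = channel_comparison(vals_a, vals_a)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)


class TestOccupancy:
    def test_half_roi_coverage(self):
        roi = np.zeros((20, 20), bool)
        roi[:, :10] = True
        img = np.zeros((20, 20))
        img[:10, :10] = 100.0  # covers half the ROI
        res = occupancy({"A": img}, roi, thresholds={"A": 50.0})
        assert res.fractions["A"] == pytest.approx(0.5)
        assert res.unlabeled == pytest.approx(0.5)

    def test_two_disjoint_channels_additive(self):
        roi = np.zeros((20, 20), bool)
        roi[:, :] = True
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[:8] = 10.0          # 0.40
        b[8:15] = 10.0        # 0.35
        res = occupancy({"A": a, "B": b}, roi,
                        thresholds={"A": 5.0, "B": 5.0})
        assert res.fractions["A"] == pytest.approx(0.40)
        assert res.fractions["B"] == pytest.approx(0.35)
        assert res.unlabeled == pytest.approx(0.25)

    def test_exclusive_fractions_sum_to_one(self, rng):
        roi = np.ones((30, 30), bool)
        a = rng.random((30, 30)) * 10
        b = rng.random((30, 30)) * 10
        res = occupancy({"A": a, "B": b}, roi,
                        thresholds={"A": 5.0, "B": 5.0}, exclusive=True)
        total = sum(res.fractions.values()) + res.unlabeled
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_scene_recovers_ground_truth(self, noiseless_pairs):
        key_map = {"Cx35.5": "gj", "N-cadherin": "aj", "GluR2": "glur2"}
        for stack, gt in noiseless_pairs:
            # sum projection: column intensity is invariant to surface tilt
            proj = sum_project(stack)
            contact = RoiMask(gt.masks["contact"], provenance="contact-outline")
            res = occupancy(
                {n: proj.channel(n) for n in stack.channel_names}, contact
            )
            for ch, key in key_map.items():
                assert res.fractions[ch] == pytest.approx(
                    gt.occupancy[key], abs=0.03
                )
            assert res.unlabeled == pytest.approx(
                gt.occupancy["unlabeled"], abs=0.03
            )

    def test_occupancy_ordering_matches_contact_composition(self, noiseless_pairs):
        # adherens-junction ≈ gap-junction coverage, both far above the
        # receptor patches, which in turn exceed the unlabeled guard zones
        fr = {"Cx35.5": [], "N-cadherin": [], "GluR2": [], "unlabeled": []}
        for stack, gt in noiseless_pairs:
            proj = sum_project(stack)
            contact = RoiMask(gt.masks["contact"], provenance="contact-outline")
            res = occupancy(
                {n: proj.channel(n) for n in stack.channel_names}, contact
            )
            for ch in ("Cx35.5", "N-cadherin", "GluR2"):
                fr[ch].append(res.fractions[ch])
            fr["unlabeled"].append(res.unlabeled)
        gj = np.mean(fr["Cx35.5"])
        aj = np.mean(fr["N-cadherin"])
        glur2 = np.mean(fr["GluR2"])
        unl = np.mean(fr["unlabeled"])
        assert abs(aj - gj) < 0.15
        assert glur2 < min(aj, gj) - 0.05
        assert unl < glur2
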
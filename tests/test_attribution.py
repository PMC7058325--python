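"""Grad-CAM mechanics, branch-point detection, enrichment arithmetic."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.draw import line

from retinavasc._nn.layers import Conv2d, Dense, GlobalMaxPool, ReLU
from retinavasc._nn.network import Sequential
from retinavasc.attribution import (
    HeatMap,
    default_radius,
    detect_bifurcations,
    grad_cam,
    localization_enrichment,
    mean_vessel_diameter,
)
from retinavasc.exceptions import ModelError


def _toy_net():
    """Conv box-filter -> ReLU -> GMP -> dense; class 1 reads channel 0."""
    net = Sequential([
        Conv2d(1, 2, 3, rng=np.random.default_rng(0)),
        ReLU(),
        GlobalMaxPool(),
        Dense(2, 2, rng=np.random.default_rng(0)),
    ])
    conv = net.layers[0]
    conv.W[...] = 0.0
    conv.W[0, :] = 1.0 / 9.0  # channel 0: local brightness detector
    conv.W[1, :] = -1.0 / 9.0
    conv.b[...] = 0.0
    dense = net.layers[3]
    dense.W[...] = np.array([[0.0, 1.0], [0.0, 0.0]], dtype=np.float32)
    dense.b[...] = 0.0
    net.gradcam_index = 1
    return net


class TestGradCam:
    def test_heat_is_nonnegative_and_max_normalized(self):
        net = _toy_net()
        img = np.zeros((16, 16))
        img[2:6, 2:6] = 1.0
        heat = grad_cam(net, img, 1)
        assert (heat.values >= 0).all()
        assert heat.values.max() == pytest.approx(1.0)

    def test_argmax_falls_in_the_responsive_quadrant(self):
        """Class 1 of the hand-built network responds to local brightness;
        with the only bright blob in the top-left quadrant, the heat map
        must peak there."""
        net = _toy_net()
        img = np.zeros((16, 16))
        img[1:5, 1:5] = 1.0
        heat = grad_cam(net, img, 1)
        r, c = np.unravel_index(np.argmax(heat.values), heat.values.shape)
        assert r < 8 and c < 8

    def test_positive_logit_scaling_leaves_map_unchanged(self):
        net = _toy_net()
        img = np.random.default_rng(1).random((16, 16))
        before = grad_cam(net, img, 1).values
        net.layers[3].W[...] *= 7.0
        net.layers[3].b[...] *= 7.0
        after = grad_cam(net, img, 1).values
        np.testing.assert_allclose(before, after, atol=1e-5)

    def test_heat_map_is_deterministic_for_fixed_weights(self):
        net = _toy_net()
        img = np.random.default_rng(2).random((16, 16))
        a = grad_cam(net, img, 1).values
        b = grad_cam(net, img, 1).values
        np.testing.assert_array_equal(a, b)

    def test_overlay_serialization_writes_png_and_raw_grid(self, tmp_path):
        from retinavasc.attribution import save_heatmap

        net = _toy_net()
        img = np.random.default_rng(3).random((16, 16))
        heat = grad_cam(net, img, 1)
        out = tmp_path / "map.png"
        save_heatmap(heat, img, out)
        assert out.exists()
        raw = np.load(str(out) + ".npy")
        np.testing.assert_array_equal(raw, heat.values)

    def test_model_without_conv_stage_rejected(self):
        net = Sequential([Dense(4, 2, rng=np.random.default_rng(0))])
        with pytest.raises(ModelError):
            grad_cam(net, np.zeros((2, 2)), 0)


class TestDetectBifurcations:
    def test_straight_bar_has_no_branch_points(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[15:18, 4:28] = 1
        assert detect_bifurcations(mask) == []

    def test_rasterized_y_has_exactly_one(self):
        mask = np.zeros((48, 48), dtype=np.uint8)
        for end in ((4, 10), (4, 38), (44, 24)):
            rr, cc = line(24, 24, *end)
            mask[rr, cc] = 1
        points = detect_bifurcations(mask)
        assert len(points) == 1
        x, y = points[0]
        assert np.hypot(x - 24, y - 24) <= 3.0

    def test_empty_mask_yields_empty_list(self):
        assert detect_bifurcations(np.zeros((16, 16), dtype=np.uint8)) == []

    def test_recovers_ground_truth_bifurcations_on_rendered_trees(self, small_cohort):
        """Bipartite check against the simulator annotations: at least 90%
        of true bifurcations have a detected branch point within 5 pixels."""
        matched = total = 0
        for rec in small_cohort.records[:6]:
            truth = [(b.x, b.y) for b in rec.bifurcations]
            if not truth:
                continue
            detected = detect_bifurcations(rec.mask)
            total += len(truth)
            if not detected:
                continue
            tree = cKDTree(np.asarray(detected))
            dists, _ = tree.query(np.asarray(truth))
            matched += int((dists <= 5.0).sum())
        assert total > 20
        assert matched / total >= 0.90


class TestEnrichment:
    def _bar_mask(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[19:22, 5:35] = 1
        return mask

    def test_uniform_heat_over_reference_region_gives_ratio_one(self):
        from scipy.ndimage import binary_dilation

        mask = self._bar_mask()
        points = [(10.0, 20.0), (30.0, 20.0)]
        radius = 3.0
        heat = np.zeros((40, 40))
        ref = binary_dilation(mask.astype(bool), np.ones((7, 7)))
        # uniform over a superset of the reference region
        heat[:] = 0.5
        result = localization_enrichment(heat, points, mask, radius)
        assert result.enrichment_ratio == pytest.approx(1.0)

    def test_heat_entirely_inside_disks_gives_area_ratio(self):
        """Closed form: density ratio equals (reference area) / (near area)
        when all mass sits inside the bifurcation disks."""
        mask = self._bar_mask()
        points = [(10.0, 20.0)]
        radius = 3.0
        result_ref = localization_enrichment(np.ones((40, 40)), points, mask, radius)
        heat = np.zeros((40, 40))
        heat[20, 10] = 1.0  # a single pixel inside the disk, on the vessel
        result = localization_enrichment(heat, points, mask, radius)
        expected = result.area_reference / result.area_near
        assert result.enrichment_ratio == pytest.approx(expected)
        assert result.mass_near_bifurcations <= result.total_mass

    def test_zero_mass_near_bifurcations_gives_zero(self):
        mask = self._bar_mask()
        heat = np.zeros((40, 40))
        heat[20, 30] = 1.0  # far from the single bifurcation at x=10
        result = localization_enrichment(heat, [(10.0, 20.0)], mask, 3.0)
        assert result.enrichment_ratio == 0.0

    def test_no_bifurcations_is_flagged_undefined(self):
        result = localization_enrichment(np.ones((40, 40)), [], self._bar_mask(), 3.0)
        assert result.undefined and result.enrichment_ratio is None

    def test_ratio_invariant_to_positive_scaling(self):
        mask = self._bar_mask()
        gen = np.random.default_rng(3)
        heat = gen.random((40, 40))
        points = [(10.0, 20.0), (28.0, 20.0)]
        a = localization_enrichment(heat, points, mask, 4.0).enrichment_ratio
        b = localization_enrichment(heat * 11.0, points, mask, 4.0).enrichment_ratio
        assert a == pytest.approx(b)

    def test_default_radius_tracks_vessel_caliber(self):
        thin = np.zeros((40, 40), dtype=np.uint8)
        thin[20, 5:35] = 1
        thick = np.zeros((40, 40), dtype=np.uint8)
        thick[16:25, 5:35] = 1
        assert default_radius(thick) > default_radius(thin)
        assert mean_vessel_diameter(thick) > mean_vessel_diameter(thin)


class TestCohortReport:
    def test_report_contains_only_correctly_classified_images(self, small_cohort):
        """Train a tiny classifier on the cohort masks, then check that the
        attribution table rows are exactly the correctly classified test
        images (scores recomputed independently)."""
        import dataclasses as dc

        from retinavasc.attribution import cohort_attribution_report
        from retinavasc.classify import CNNClassifier
        from retinavasc.synthetic import FundusImage
        from tests.test_classifier import TINY

        records = []
        for r in small_cohort.records:
            img = FundusImage(pixels=r.mask.pixels.astype(float), label=r.label,
                              subject_id=r.subject_id, provenance="segmented")
            records.append(dc.replace(r, image=img))
        config = dc.replace(TINY, epochs=4)
        model = CNNClassifier.from_config(config).fit(
            [r.image for r in records], [r.label for r in records]
        )
        frame, summary = cohort_attribution_report(model, records)
        scores = model.decision_scores([r.image for r in records])
        correct = {
            i
            for i, (r, s) in enumerate(zip(records, scores))
            if (r.label == "hypertension") == (s >= 0.5)
        }
        assert set(frame["image_id"]) == correct
        assert summary["n_maps"] == len(correct)
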
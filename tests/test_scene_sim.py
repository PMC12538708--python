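"""Scene generation: point processes, rendering, detector simulation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import seedspread as sp
from seedspread.scene_sim import BackgroundModel, layout_mask


def _positions(layout):
    return np.array([xy for _, xy, _, _ in layout.placements])


class TestSampleLayout:
    def test_zero_intensity_gives_empty_layout(self):
        params = sp.ProcessParams(process="poisson", intensity_per_mm2=0.0)
        layout = sp.sample_layout(params, seed=0)
        assert len(layout) == 0

    def test_poisson_mean_count_matches_intensity(self):
        lam = 0.003
        params = sp.ProcessParams(process="poisson", intensity_per_mm2=lam)
        counts = [len(sp.sample_layout(params, seed=s)) for s in range(200)]
        # interior box is the belt inset by the largest semi-major axis
        inset = max(s.length_mm for s in sp.DEFAULT_PALETTE) / 2
        area = (384 - 2 * inset) * (216 - 2 * inset)
        expect = lam * area
        assert abs(np.mean(counts) - expect) < 3 * np.sqrt(expect)

    def test_mix_counts_exact_and_ratio(self):
        params = sp.ProcessParams(
            process="poisson", mix_counts={"soybean": 2000, "a_trifida": 100}
        )
        layout = sp.sample_layout(params, seed=1)
        counts = layout.counts()
        assert counts == {"soybean": 2000, "a_trifida": 100}
        assert 100 * counts["a_trifida"] / counts["soybean"] == 5.0

    def test_hardcore_minimum_distance_holds(self):
        params = sp.ProcessParams(
            process="hardcore", hardcore_radius_mm=8.0, mix_counts={"soybean": 400}
        )
        for seed in (0, 1, 2):
            layout = sp.sample_layout(params, seed=seed)
            assert pdist(_positions(layout)).min() >= 8.0

    def test_hardcore_infeasible_packing_raises(self):
        params = sp.ProcessParams(
            process="hardcore", hardcore_radius_mm=30.0, mix_counts={"soybean": 500}
        )
        with pytest.raises(RuntimeError, match="infeasible"):
            sp.sample_layout(params, seed=0, max_attempts_per_seed=50)

    def test_centers_inside_belt_interior(self):
        params = sp.ProcessParams(
            process="thomas",
            cluster_parent_intensity=3e-4,
            cluster_sd_mm=12.0,
            mix_counts={"soybean": 300},
        )
        layout = sp.sample_layout(params, seed=5)
        pos = _positions(layout)
        inset = max(s.length_mm for s in sp.DEFAULT_PALETTE) / 2
        assert np.all(pos[:, 0] >= inset) and np.all(pos[:, 0] <= 384 - inset)
        assert np.all(pos[:, 1] >= inset) and np.all(pos[:, 1] <= 216 - inset)

    def test_determinism_same_seed_identical_layout(self):
        params = sp.ProcessParams(process="poisson", mix_counts={"soybean": 50})
        a = sp.sample_layout(params, seed=9)
        b = sp.sample_layout(params, seed=9)
        assert a == b
        assert a != sp.sample_layout(params, seed=10)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sp.ProcessParams(process="hardcore", hardcore_radius_mm=0.0)
        with pytest.raises(ValueError):
            sp.ProcessParams(process="poisson", hardcore_radius_mm=2.0)
        with pytest.raises(ValueError):
            sp.ProcessParams(process="poisson", cluster_sd_mm=1.0)
        params = sp.ProcessParams(process="poisson", mix_counts={"lentil": 5})
        with pytest.raises(ValueError, match="palette"):
            sp.sample_layout(params, seed=0)


class TestRenderScene:
    def test_empty_layout_renders_pure_background(self):
        layout = sp.LayoutScene(96.0, 96.0, 2.5, (), rng_seed=0)
        bg = BackgroundModel(noise_sd=0.0)
        image, mask, counts = sp.render_scene(layout, background=bg)
        assert np.all(image == np.array(bg.color, dtype=np.uint8))
        assert mask.foreground_count() == 0
        assert counts == {}

    def test_single_soybean_mask_area_matches_ellipse(self):
        # one seed at the centre, axis-aligned, 10 px/mm
        layout = sp.LayoutScene(
            96.0, 96.0, 10.0, (("soybean", (48.0, 48.0), (7.65, 6.52), 0.0),), rng_seed=1
        )
        _, mask, _ = sp.render_scene(layout)
        expected = np.pi * (76.5 / 2) * (65.2 / 2)
        assert abs(mask.foreground_count() - expected) / expected < 0.02

    def test_rendered_counts_equal_layout_counts(self, rendered_scene):
        _, _, layout, counts = rendered_scene
        assert counts == layout.counts()

    def test_render_determinism_bit_identical(self):
        params = sp.ProcessParams(process="poisson", mix_counts={"soybean": 30})
        layout = sp.sample_layout(params, seed=4, px_per_mm=2.5)
        img1, mask1, _ = sp.render_scene(layout)
        img2, mask2, _ = sp.render_scene(layout)
        assert np.array_equal(img1, img2)
        assert np.array_equal(mask1.pixels, mask2.pixels)

    def test_layout_mask_matches_render_scene_mask(self):
        params = sp.ProcessParams(process="poisson", mix_counts={"soybean": 40})
        layout = sp.sample_layout(params, seed=6, px_per_mm=2.5)
        _, mask, _ = sp.render_scene(layout)
        assert np.array_equal(layout_mask(layout).pixels, mask.pixels)

    def test_palette_missing_class_rejected(self):
        layout = sp.LayoutScene(
            96.0, 96.0, 2.5, (("mystery", (48.0, 48.0), (5.0, 4.0), 0.0),), rng_seed=0
        )
        with pytest.raises(ValueError, match="palette"):
            sp.render_scene(layout)


class TestSimulateDetections:
    def _layout(self, counts, seed=0):
        return sp.sample_layout(
            sp.ProcessParams(process="poisson", mix_counts=counts), seed=seed
        )

    def test_perfect_detector_recovers_counts(self):
        layout = self._layout({"soybean": 200, "a_trifida": 10})
        det = sp.DetectorModel(recall={"soybean": 1.0, "a_trifida": 1.0})
        assert sp.simulate_detections(layout, det) == {"soybean": 200, "a_trifida": 10}

    def test_zero_recall_detects_nothing(self):
        layout = self._layout({"soybean": 150})
        det = sp.DetectorModel(recall={"soybean": 0.0})
        assert sp.simulate_detections(layout, det)["soybean"] == 0

    def test_binomial_recall_recovered_over_replicates(self):
        layout = self._layout({"soybean": 2000})
        det = sp.DetectorModel(recall={"soybean": 0.96})
        fracs = [
            sp.simulate_detections(layout, det, seed=s)["soybean"] / 2000
            for s in range(500)
        ]
        se = np.sqrt(0.96 * 0.04 / 2000)
        assert abs(np.mean(fracs) - 0.96) < 3 * se

    def test_confusion_relabels_detections(self):
        layout = self._layout({"soybean": 100})
        det = sp.DetectorModel(
            recall={"soybean": 1.0, "a_trifida": 1.0},
            confusion={"soybean": {"a_trifida": 1.0}},
        )
        out = sp.simulate_detections(layout, det)
        assert out == {"soybean": 0, "a_trifida": 100}

    def test_false_positives_are_poisson_additions(self):
        layout = self._layout({"soybean": 10})
        det = sp.DetectorModel(recall={"soybean": 1.0}, fp_rate_per_image=5.0)
        totals = [
            sum(sp.simulate_detections(layout, det, seed=s).values()) for s in range(300)
        ]
        extra = np.mean(totals) - 10
        assert abs(extra - 5.0) < 3 * np.sqrt(5.0 / 300)

    def test_detection_determinism(self):
        layout = self._layout({"soybean": 500})
        det = sp.DetectorModel(recall={"soybean": 0.9}, rng_seed=21)
        assert sp.simulate_detections(layout, det) == sp.simulate_detections(layout, det)

    def test_missing_recall_class_rejected(self):
        layout = self._layout({"soybean": 5, "a_trifida": 5})
        det = sp.DetectorModel(recall={"soybean": 1.0})
        with pytest.raises(ValueError, match="recall"):
            sp.simulate_detections(layout, det)

    def test_invalid_detector_rejected(self):
        with pytest.raises(ValueError):
            sp.DetectorModel(recall={"soybean": 1.2})
        with pytest.raises(ValueError):
            sp.DetectorModel(
                recall={"soybean": 1.0}, confusion={"soybean": {"soybean": 0.7}}
            )
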
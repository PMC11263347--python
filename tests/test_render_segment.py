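import numpy as np
import pytest

from conftest import static_history
from shearcolony.render import (OpticsConfig, OutOfFieldError,
                                render_blank_frames, render_frames)
from shearcolony.segment import (SegmentationParams, background_model,
                                 segment_frame, segment_stack,
                                 threshold_sensitivity)

NOISELESS = OpticsConfig(noise_sd=0.0, blur_sigma=0.0, flicker_prob=0.0,
                         seed=0)


class TestRenderer:
    def test_empty_history_is_pure_background(self):
        history = static_history([])
        stack, ground_truth = render_frames(history, NOISELESS)
        assert len(ground_truth) == 0
        assert np.all(stack.frames == NOISELESS.background_level)

    def test_single_cell_covers_about_200_pixels(self):
        # a 2 x 1 um capsule at 0.1 um/px: (L-w) w + pi (w/2)^2 = 178.5 px
        # of full coverage, ~200 with the anti-aliased boundary
        history = static_history([(10.0, 10.0, 2.0, 0.0)], n_frames=1)
        stack, _ = render_frames(history, NOISELESS)
        dark = np.sum(stack.frames[0] < NOISELESS.background_level
                      - 0.3 * NOISELESS.cell_contrast)
        assert 170 <= dark <= 230

    def test_flicker_omissions_recorded_in_ground_truth(self):
        history = static_history([(10.0, 10.0, 2.0, 0.0)], n_frames=100)
        optics = OpticsConfig(noise_sd=0.0, blur_sigma=0.0, flicker_prob=0.1,
                              seed=4)
        stack, ground_truth = render_frames(history, optics)
        n_omitted = int(ground_truth["omitted"].sum())
        assert 2 <= n_omitted <= 25   # binomial(100, 0.1) bulk
        # omitted frames really lack the cell
        omitted_frames = ground_truth[ground_truth.omitted].frame.to_numpy()
        for fi in omitted_frames:
            assert np.all(stack.frames[fi] == optics.background_level)

    def test_rendering_deterministic(self):
        history = static_history([(10.0, 10.0, 2.0, 0.5)], n_frames=3)
        optics = OpticsConfig(seed=11)
        s1, _ = render_frames(history, optics)
        s2, _ = render_frames(history, optics)
        assert np.array_equal(s1.frames, s2.frames)

    def test_out_of_field_lists_agents(self):
        history = static_history([(10.0, 10.0, 2.0, 0.0),
                                  (45.0, 10.0, 2.0, 0.0)],
                                 domain=(20.0, 20.0))
        with pytest.raises(OutOfFieldError) as err:
            render_frames(history, NOISELESS)
        assert err.value.agent_ids == [1]


class TestBackgroundModel:
    def test_constant_stack(self):
        frames = np.full((12, 8, 8), 137.0)
        bg = background_model(frames, 10)
        assert np.all(bg == 137.0)
        assert np.all(frames[0] - bg == 0.0)

    def test_mean_of_first_frames(self):
        frames = np.stack([np.full((4, 4), float(i)) for i in range(12)])
        assert np.all(background_model(frames, 10) == 4.5)

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="background model needs"):
            background_model(np.zeros((3, 4, 4)), 10)

    def test_residual_variance_after_subtraction(self):
        # subtracting a 10-frame mean leaves variance sd^2 (1 + 1/10) in
        # cell-free regions
        rng = np.random.default_rng(0)
        sd = 50.0
        frames = 1000.0 + rng.normal(0, sd, (30, 64, 64))
        bg = background_model(frames, 10)
        residual = frames[20] - bg
        assert residual.var() == pytest.approx(sd**2 * 1.1, rel=0.15)


class TestSegmentFrame:
    def test_empty_frame(self):
        bg = np.full((50, 50), 30000.0)
        assert segment_frame(bg.copy(), bg, SegmentationParams()) == []

    def test_single_capsule_geometry(self):
        history = static_history([(10.0, 10.0, 2.0, 0.0)], n_frames=1)
        stack, _ = render_frames(history, OpticsConfig(noise_sd=0.0, seed=0))
        bg = np.full(stack.frames[0].shape, 30000.0)
        detections = segment_frame(stack.frames[0], bg, SegmentationParams())
        assert len(detections) == 1
        det = detections[0]
        assert 150 <= det.area_px <= 230
        assert 0.5 <= det.eccentricity <= 0.995
        # centroid within half a pixel; image coords = world + margin
        margin = OpticsConfig().margin
        assert det.centroid[0] == pytest.approx(10.0 + margin, abs=0.05)
        assert det.centroid[1] == pytest.approx(10.0 + margin, abs=0.05)
        # poles sit on the major axis, symmetric about the centroid
        pa, pb = np.array(det.pole_a), np.array(det.pole_b)
        assert np.allclose((pa + pb) / 2, det.centroid, atol=1e-9)
        assert np.hypot(*(pb - pa)) == pytest.approx(det.major_axis, rel=1e-9)

    def test_round_blob_filtered_by_eccentricity(self):
        # a 1:1 object has eccentricity below the 0.5 acceptance floor
        history = static_history([(10.0, 10.0, 1.05, 0.0)], n_frames=1)
        stack, _ = render_frames(history, OpticsConfig(noise_sd=0.0, seed=0))
        bg = np.full(stack.frames[0].shape, 30000.0)
        params = SegmentationParams(min_area_px=20)
        assert segment_frame(stack.frames[0], bg, params) == []
        relaxed = SegmentationParams(min_area_px=20, eccentricity_min=0.0)
        assert len(segment_frame(stack.frames[0], bg, relaxed)) == 1

    def test_saturated_frame_warns_and_returns_empty(self):
        bg = np.full((30, 30), 30000.0)
        with pytest.warns(UserWarning, match="saturated"):
            out = segment_frame(np.full((30, 30), 65535.0), bg,
                                SegmentationParams())
        assert out == []

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="same shape"):
            segment_frame(np.zeros((10, 10)), np.zeros((9, 9)),
                          SegmentationParams())


class TestSegmentationOnRenderedColony:
    def test_counts_match_ground_truth(self, growth_fixture):
        detections = segment_stack(growth_fixture["stack"].frames,
                                   SegmentationParams(),
                                   background=growth_fixture["background"])
        got = detections.groupby("frame").x.count()
        expected = growth_fixture["ground_truth"].groupby("frame") \
            .agent_id.count()
        err = (got.reindex(expected.index).fillna(0) - expected).abs()
        assert err.mean() < 0.1
        assert (err == 0).mean() > 0.9

    def test_centroid_accuracy_subpixel(self):
        # well-separated cells (no touching pairs): RMS centroid error
        # below half a pixel even with default noise and blur
        cells = [(8.0 + 12 * i, 8.0 + 10 * j, 2.0, 0.7 * (i + 2 * j))
                 for i in range(3) for j in range(3)]
        history = static_history(cells, n_frames=1, domain=(50.0, 50.0))
        optics = OpticsConfig(seed=9)
        stack, gt = render_frames(history, optics)
        bg = np.full(stack.frames[0].shape, optics.background_level)
        dets = segment_frame(stack.frames[0], bg, SegmentationParams(), 0)
        assert len(dets) == len(cells)
        margin = optics.margin
        errs = []
        for _, row in gt.iterrows():
            d = min(dets, key=lambda d: np.hypot(
                d.centroid[0] - row.x - margin,
                d.centroid[1] - row.y - margin))
            errs.append(np.hypot(d.centroid[0] - row.x - margin,
                                 d.centroid[1] - row.y - margin))
        rms = np.sqrt(np.mean(np.square(errs)))
        assert rms < 0.05   # um, i.e. < 0.5 px


class TestThresholdSensitivity:
    def test_growth_rate_insensitive_to_threshold(self, threshold_report):
        # +/- 18% threshold moves the fitted growth rate by < 1%
        for label in ("low", "high"):
            assert abs(threshold_report[label]["eta_change_fraction"]) < 0.01

    def test_zero_delta_identical_counts(self, growth_fixture):
        report = threshold_sensitivity(
            growth_fixture["stack"].frames[:20], SegmentationParams(), 0.0,
            fit_window=(2.0, None), background=growth_fixture["background"])
        assert np.array_equal(report["counts"]["low"],
                              report["counts"]["high"])

    def test_counts_monotone_on_sparse_stack(self):
        # well-separated static cells: a higher threshold can only shrink
        # the detected set
        cells = [(8.0 + 12 * i, 8.0 + 10 * j, 2.0, 0.4 * (i + j))
                 for i in range(3) for j in range(3)]
        history = static_history(cells, n_frames=12, domain=(50.0, 50.0))
        stack, _ = render_frames(history, OpticsConfig(seed=3))
        bg = np.full(stack.frames[0].shape, 30000.0)
        report = threshold_sensitivity(stack.frames, SegmentationParams(),
                                       0.18, fit_window=(0.0, None),
                                       background=bg)
        assert np.all(report["counts"]["high"] <= report["counts"]["low"])

    def test_bad_delta_rejected(self):
        with pytest.raises(ValueError):
            threshold_sensitivity(np.zeros((12, 8, 8)), SegmentationParams(),
                                  0.7)
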
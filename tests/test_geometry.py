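"""Depth thresholding, compartment detection and ROI extraction."""

import dataclasses

import numpy as np
import pytest

from abbt import geometry as geo
from abbt import scene_synth as ss
from abbt.frames import AlignedFrame, DEPTH_MISSING


def flat_desk_frame(shape=(60, 100), depth_mm=800):
    colour = np.full(shape + (3,), 120, dtype=np.uint8)
    depth = np.full(shape, depth_mm, dtype=np.uint16)
    return AlignedFrame(colour, depth)


def cubes_on(config, side, n=3):
    rect = config.compartment_rect(side)
    pitch = config.cube_side_px + 14
    return [
        ss.CubePlacement("red", (rect.top + 30 + i * pitch, rect.left + 30))
        for i in range(n)
    ]


class TestAlignment:
    def test_identity_map_returns_input(self):
        frame = flat_desk_frame()
        out = geo.align_depth_to_colour(
            frame.colour, frame.depth,
            geo.RegistrationMap.identity(frame.shape))
        assert np.array_equal(out.depth, frame.depth)

    def test_scaling_map_resamples_to_colour_resolution(self):
        # the two sensors of an RGB-D camera differ: 512x424 depth, 1920x1080 colour
        depth = np.full((424, 512), 700, dtype=np.uint16)
        colour = np.zeros((1080, 1920, 3), dtype=np.uint8)
        reg = geo.RegistrationMap.scaling(depth.shape, colour.shape[:2])
        out = geo.align_depth_to_colour(colour, depth, reg)
        assert out.depth.shape == (1080, 1920)
        assert np.all(out.depth == 700)

    def test_map_outside_depth_frame_flags_all_missing(self):
        frame = flat_desk_frame()
        rows = np.full(frame.shape, -1, dtype=np.int64)
        reg = geo.RegistrationMap(rows, rows.copy())
        out = geo.align_depth_to_colour(frame.colour, frame.depth, reg)
        assert np.all(out.depth == DEPTH_MISSING)
        mask = geo.threshold_height(out, geo.GeometryConfig())
        assert not mask.any()

    def test_wrong_map_dimensions_rejected(self):
        frame = flat_desk_frame()
        bad = np.zeros((3, 3), dtype=np.int64)
        with pytest.raises(geo.GeometryError):
            geo.align_depth_to_colour(frame.colour, frame.depth,
                                      geo.RegistrationMap(bad, bad))


class TestThresholdHeight:
    def test_empty_desk_gives_empty_mask(self, geo_config):
        assert not geo.threshold_height(flat_desk_frame(), geo_config).any()

    def test_box_scene_mask_is_exactly_rim_and_partition(self, clean_config,
                                                         geo_config):
        frame = ss.render_scene(clean_config, [])
        mask = geo.threshold_height(frame, geo_config)
        expected = np.zeros(frame.shape, dtype=bool)
        expected[clean_config.box_rect.slices] = True
        for side in ("left", "right"):
            expected[clean_config.compartment_rect(side).slices] = False
        expected[clean_config.partition_rect.slices] = True
        assert np.array_equal(mask, expected)

    def test_threshold_above_partition_excludes_it(self, geo_config):
        config = ss.SceneConfig(noise_sd=0.0, partition_height_mm=70.0)
        frame = ss.render_scene(config, [])
        high = dataclasses.replace(geo_config, height_threshold_mm=80.0)
        mask = geo.threshold_height(frame, high)
        assert not mask[config.partition_rect.slices].any()
        assert mask.any()  # the 100 mm rim survives

    @pytest.mark.parametrize("pair", [(20, 40), (40, 60), (60, 95)])
    def test_raising_threshold_never_adds_pixels(self, clean_config,
                                                 geo_config, pair):
        frame = ss.render_scene(clean_config,
                                cubes_on(clean_config, "left"))
        low = geo.threshold_height(
            frame, dataclasses.replace(geo_config, height_threshold_mm=pair[0]))
        high = geo.threshold_height(
            frame, dataclasses.replace(geo_config, height_threshold_mm=pair[1]))
        assert not (high & ~low).any()


class TestCleanAndLabel:
    def test_empty_mask_yields_no_regions(self, geo_config):
        assert geo.clean_and_label(np.zeros((50, 50), bool), geo_config) == []

    def test_two_rectangles_measured_exactly(self, geo_config):
        mask = np.zeros((100, 200), bool)
        mask[10:40, 20:70] = True   # 30 x 50
        mask[60:90, 120:180] = True  # 30 x 60
        cfg = dataclasses.replace(geo_config, morphology_radius_px=0)
        regions = sorted(geo.clean_and_label(mask, cfg), key=lambda r: r.area)
        assert [r.area for r in regions] == [1500, 1800]
        assert regions[0].centroid == (24.5, 44.5)
        assert (regions[1].rect.top, regions[1].rect.left) == (60, 120)

    def test_speckle_noise_removed(self, geo_config):
        mask = np.zeros((100, 100), bool)
        mask[10:50, 10:50] = True
        speckles = np.random.default_rng(1).integers(60, 99, size=(30, 2))
        mask[speckles[:, 0], speckles[:, 1]] = True
        regions = geo.clean_and_label(mask, geo_config)
        assert len(regions) == 1
        assert regions[0].area == pytest.approx(1600, rel=0.01)


class TestCompartments:
    @pytest.mark.parametrize("occupied,empty", [("left", "right"),
                                                ("right", "left")])
    def test_empty_side_detected(self, clean_config, geo_config,
                                 occupied, empty):
        frame = ss.render_scene(clean_config, cubes_on(clean_config, occupied))
        regions = geo.clean_and_label(
            geo.threshold_height(frame, geo_config), geo_config)
        left, right = geo.identify_empty_compartment(frame, regions, geo_config)
        by_side = {"left": left, "right": right}
        assert by_side[empty].is_empty
        assert not by_side[occupied].is_empty

    def test_both_occupied_refuses_to_start(self, clean_config, geo_config):
        script = cubes_on(clean_config, "left", 3) + cubes_on(clean_config,
                                                              "right", 1)
        frame = ss.render_scene(clean_config, script)
        regions = geo.clean_and_label(
            geo.threshold_height(frame, geo_config), geo_config)
        with pytest.raises(geo.CompartmentStateError, match="occupied"):
            geo.identify_empty_compartment(frame, regions, geo_config)

    def test_both_empty_refuses_to_start(self, clean_config, geo_config):
        frame = ss.render_scene(clean_config, [])
        regions = geo.clean_and_label(
            geo.threshold_height(frame, geo_config), geo_config)
        with pytest.raises(geo.CompartmentStateError, match="empty"):
            geo.identify_empty_compartment(frame, regions, geo_config)

    def test_detected_rects_match_ground_truth(self, clean_config, geo_config):
        frame = ss.render_scene(clean_config, cubes_on(clean_config, "left"))
        regions = geo.clean_and_label(
            geo.threshold_height(frame, geo_config), geo_config)
        left, right = geo.identify_empty_compartment(frame, regions, geo_config)
        tol = geo_config.morphology_radius_px
        for info, side in ((left, "left"), (right, "right")):
            truth = clean_config.compartment_rect(side)
            assert abs(info.rect.top - truth.top) <= tol
            assert abs(info.rect.left - truth.left) <= tol
            assert abs(info.rect.height - truth.height) <= 2 * tol
            assert abs(info.rect.width - truth.width) <= 2 * tol

    def test_left_right_decision_mirrors_under_horizontal_flip(
            self, clean_config, geo_config):
        frame = ss.render_scene(clean_config, cubes_on(clean_config, "left"))
        mirrored = AlignedFrame(frame.colour[:, ::-1].copy(),
                                frame.depth[:, ::-1].copy(),
                                frame.timestamp_s)
        def detect(f):
            regions = geo.clean_and_label(
                geo.threshold_height(f, geo_config), geo_config)
            return geo.identify_empty_compartment(f, regions, geo_config)
        left, right = detect(frame)
        m_left, m_right = detect(mirrored)
        width = frame.shape[1]
        # emptiness swaps sides; rectangles map onto each other exactly
        assert m_left.is_empty == right.is_empty
        assert m_right.is_empty == left.is_empty
        assert m_left.rect == right.rect.mirrored_horizontally(width)
        assert m_right.rect == left.rect.mirrored_horizontally(width)


class TestExtractRoi:
    def _empty_compartment(self, config, geo_config, frame):
        regions = geo.clean_and_label(
            geo.threshold_height(frame, geo_config), geo_config)
        left, right = geo.identify_empty_compartment(frame, regions, geo_config)
        return left if left.is_empty else right

    def test_roi_has_design_size(self, clean_config, geo_config):
        frame = ss.render_scene(clean_config, cubes_on(clean_config, "left"))
        info = self._empty_compartment(clean_config, geo_config, frame)
        roi = geo.extract_roi(frame, info)
        assert abs(roi.shape[0] - 330) <= 2 and abs(roi.shape[1] - 330) <= 2

    def test_empty_roi_is_pure_background(self, clean_config, geo_config):
        frame = ss.render_scene(clean_config, cubes_on(clean_config, "left"))
        info = self._empty_compartment(clean_config, geo_config, frame)
        roi = geo.extract_roi(frame, info)
        assert np.all(roi == ss.DEFAULT_PALETTE["background"])

    def test_extraction_is_idempotent(self, clean_config, geo_config):
        frame = ss.render_scene(clean_config, cubes_on(clean_config, "left"))
        info = self._empty_compartment(clean_config, geo_config, frame)
        assert np.array_equal(geo.extract_roi(frame, info),
                              geo.extract_roi(frame, info))

    def test_rect_outside_frame_rejected(self, clean_config, geo_config):
        frame = ss.render_scene(clean_config, [])
        from abbt.frames import Rect
        bad = geo.CompartmentInfo("left", Rect(0, 0, 5000, 5000),
                                  (0.0, 0.0), True)
        with pytest.raises(geo.GeometryError):
            geo.extract_roi(frame, bad)
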
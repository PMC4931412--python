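import numpy as np
import pytest

from lensfree_detect import (
    FeatureConfig,
    GrayImage,
    RingFeatures,
    central_width,
    circularity_ok,
    extract_cmv,
    extract_features,
    find_ppd,
    minima_width,
)
from lensfree_detect.synth_scene import ObjectSpec, SceneSpec, render_scene

RAW = FeatureConfig(denoise_sigma=0.0)  # measure on the raw pixels


def image_with_row_profile(profile, background=180, height=41):
    """Embed a 1-D profile into the middle row AND middle column of a
    square frame so both axes see the same values."""
    n = len(profile)
    px = np.full((max(height, n), max(height, n)), background, dtype=np.uint8)
    mid = px.shape[0] // 2
    start = px.shape[1] // 2 - n // 2
    px[mid, start:start + n] = profile
    px[start:start + n, mid] = profile
    return GrayImage(px), (mid, px.shape[1] // 2 - n // 2 + n // 2)


class TestCmv:
    def test_identity(self):
        px = np.full((20, 20), 160, dtype=np.uint8)
        px[7, 9] = 144
        assert extract_cmv(GrayImage(px), (7, 9)) == 144

    def test_constant_image(self, flat_image):
        assert extract_cmv(flat_image, (5, 5)) == 128

    def test_out_of_bounds_raises(self, flat_image):
        with pytest.raises(ValueError):
            extract_cmv(flat_image, (60, 0))

    def test_rendered_pattern_center_level(self, single_bead_scene):
        img, truth = single_bead_scene
        # default rendering: central level = background 165 - 20 = 145
        assert extract_cmv(img, truth.objects[0].center) == 145


class TestCentralWidth:
    def test_hand_traced_run(self):
        img, mid = image_with_row_profile([180, 150, 144, 150, 180])
        assert central_width(img, mid, "h", RAW) == 3
        assert central_width(img, mid, "v", RAW) == 3

    def test_constant_image_full_extent(self, flat_image):
        assert central_width(flat_image, (30, 30), "h", RAW) == 60

    def test_rendered_widths_match_both_axes(self, single_bead_scene):
        img, truth = single_bead_scene
        c = truth.objects[0].center
        wh = central_width(img, c, "h", RAW)
        wv = central_width(img, c, "v", RAW)
        assert wh == wv
        assert 6 <= wh <= 12  # ~2x the 4-px central half-width


class TestMinimaWidth:
    def test_symmetric_lobes(self):
        profile = [180, 120, 120, 120, 120, 150, 144, 150, 120, 120, 120, 120, 180]
        img, mid = image_with_row_profile(profile)
        assert minima_width(img, mid, "h", RAW) == 4

    def test_monotone_no_lobe(self):
        img, mid = image_with_row_profile([144] * 5, background=200)
        # central run is the flat 144 stretch; outside it only 200s
        assert minima_width(img, mid, "h", RAW) == 0

    def test_asymmetric_lobes_mean(self):
        profile = [180, 120, 120, 120, 150, 144, 150, 120, 120, 120, 120, 120, 180]
        img, mid = image_with_row_profile(profile)
        # lobes 3 (left) and 5 (right) -> mean 4
        assert minima_width(img, mid, "h", RAW) == 4


class TestFindPpd:
    def test_rendered_ring_close_to_2R(self, single_bead_scene):
        img, truth = single_bead_scene
        c = truth.objects[0].center
        expected = truth.objects[0].expected_ppd_px  # 35.7
        for axis in ("h", "v"):
            ppd = find_ppd(img, c, axis, RAW)
            assert ppd is not None
            assert abs(ppd - expected) <= 2

    def test_near_border_absent(self, single_bead_scene):
        img, _ = single_bead_scene
        cfg = FeatureConfig(denoise_sigma=0.0, scan_max=60)
        assert find_ppd(img, (10, 150), "v", cfg) is None

    def test_constant_image_absent(self, flat_image):
        # midpoint far enough from borders requires a bigger flat frame
        img = GrayImage(np.full((200, 200), 128, dtype=np.uint8))
        assert find_ppd(img, (100, 100), "h", RAW) is None


class TestCircularity:
    @pytest.mark.parametrize("wcx_v,wcx_h,wcn_v,wcn_h,ok", [
        (8, 8, 4, 4, True),     # perfectly circular
        (14, 8, 4, 4, False),   # 1.75 > 1.5
        (9, 8, 4, 4, True),     # 1.125 <= 1.5
        (8, 8, 4, 0, False),    # one zero lobe
        (8, 8, 0, 0, True),     # both lobes zero: pair passes
        (8, 8, 3, 5, False),    # 1.67 > 1.5
    ])
    def test_aspect_rules(self, wcx_v, wcx_h, wcn_v, wcn_h, ok):
        f = RingFeatures(cmv=144, wcx_h=wcx_h, wcx_v=wcx_v,
                         wcn_h=wcn_h, wcn_v=wcn_v,
                         ppd_h=38, ppd_v=38, ppd=38.0)
        assert circularity_ok(f) is ok


class TestFeatureProperties:
    def test_rotational_consistency_noise_free(self, single_bead_scene):
        img, truth = single_bead_scene
        f = extract_features(img, truth.objects[0].center)
        assert f.wcx_h == f.wcx_v
        assert f.wcn_h == f.wcn_v
        assert f.ppd_h == f.ppd_v

    def test_90_degree_rotation_swaps_axes(self):
        spec = SceneSpec(height=301, width=301, noise_sigma=2.0, seed=9,
                         objects=(ObjectSpec(center=(150, 150), size_um=20.0),))
        img, _ = render_scene(spec)
        rot = GrayImage(np.ascontiguousarray(np.rot90(img.pixels)))
        f0 = extract_features(img, (150, 150))
        f1 = extract_features(rot, (150, 150))
        assert (f0.wcx_h, f0.wcx_v) == (f1.wcx_v, f1.wcx_h)
        assert (f0.wcn_h, f0.wcn_v) == (f1.wcn_v, f1.wcn_h)
        assert (f0.ppd_h, f0.ppd_v) == (f1.ppd_v, f1.ppd_h)

    def test_ppd_monotone_in_ring_radius(self):
        last = 0
        for size in (8.0, 12.0, 20.0, 28.0):
            spec = SceneSpec(height=301, width=301, noise_sigma=0.0,
                             objects=(ObjectSpec(center=(150, 150), size_um=size),))
            img, _ = render_scene(spec)
            ppd = find_ppd(img, (150, 150), "h", RAW)
            assert ppd is not None and ppd >= last
            last = ppd

    def test_parameter_recovery_95_percent(self):
        """|PPD - 2R| <= 2 px for >= 95% of rings R in [15, 50], noise <= 3."""
        rng = np.random.default_rng(12)
        hits = 0
        n = 50
        for i in range(n):
            radius = rng.uniform(15, 50)
            sigma = rng.uniform(0, 3)
            size = radius * 2 * 0.28
            spec = SceneSpec(height=301, width=301, noise_sigma=sigma, seed=100 + i,
                             objects=(ObjectSpec(center=(150, 150), size_um=size),))
            img, truth = render_scene(spec)
            f = extract_features(img, (150, 150))
            if f.ppd is not None and abs(f.ppd - 2 * radius) <= 2:
                hits += 1
        assert hits >= 0.95 * n

    def test_ppd_exceeds_central_structure(self, single_bead_scene):
        img, truth = single_bead_scene
        f = extract_features(img, truth.objects[0].center)
        assert f.ppd >= f.wcx_h + 2 * f.wcn_h
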
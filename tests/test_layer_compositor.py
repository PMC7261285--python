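"""Tool placement sampling, layer construction and alpha compositing."""

import numpy as np
import pytest
from scipy import stats

from retinaflow import layer_compositor as lc
from retinaflow.synth_fundus import FundusParams, generate_fundus, \
    generate_tool_template


@pytest.fixture(scope="module")
def retina():
    img = generate_fundus(FundusParams(seed=1, size=(96, 128)))
    return lc.SceneLayer(color=img.astype(np.float32),
                         opacity=np.ones((96, 128), np.float32), role="retina")


@pytest.fixture(scope="module")
def template():
    return generate_tool_template("cutter", seed=4)


class TestPlacementSampling:
    def test_all_parameters_inside_ranges_and_uniform(self):
        rng = np.random.default_rng(0)
        draws = [lc.sample_tool_placement("cutter", rng) for _ in range(1000)]
        fields = {
            "scale": (lc.SCALE_RANGE, [p.scale for p in draws]),
            "stretch": (lc.STRETCH_RANGE, [p.stretch for p in draws]),
            "rotation": (lc.ROTATION_RANGE, [p.rotation_deg for p in draws]),
            "tip_x": (lc.TIP_X_RANGE_OTHER, [p.tip_x for p in draws]),
            "tip_y": (lc.TIP_Y_RANGE, [p.tip_y for p in draws]),
            "sh_off": (lc.SHADOW_OFFSET_RANGE,
                       [p.shadow_offset_px for p in draws]),
            "sh_ang": (lc.SHADOW_ANGLE_RANGE,
                       [p.shadow_angle_deg for p in draws]),
            "sh_alpha": (lc.SHADOW_ALPHA_RANGE,
                         [p.shadow_alpha for p in draws]),
            "gl_r": (lc.GLARE_RADIUS_RANGE,
                     [p.glare_radius_px for p in draws]),
            "gl_crest": (lc.GLARE_CREST_ALPHA_RANGE,
                         [p.glare_crest_alpha for p in draws]),
        }
        for name, ((lo, hi), vals) in fields.items():
            vals = np.asarray(vals)
            assert vals.min() >= lo and vals.max() <= hi, name
            # Kolmogorov-Smirnov sanity check against U[lo, hi]
            _, p = stats.kstest((vals - lo) / (hi - lo), "uniform")
            assert p > 0.01, f"{name} not uniform (p={p:.4f})"
        counts = [p.glare_n_ovals for p in draws]
        assert min(counts) >= 1 and max(counts) <= 5
        assert all(p.blur_kernel_px in (3, 5, 7) for p in draws)

    def test_light_pipe_tip_on_the_light_side(self):
        rng = np.random.default_rng(1)
        draws = [lc.sample_tool_placement("light_pipe", rng)
                 for _ in range(300)]
        assert max(p.tip_x for p in draws) <= 0.5
        assert min(p.tip_x for p in draws) >= 0.15

    def test_fixed_seed_reproducible(self):
        a = lc.sample_tool_placement("forceps", np.random.default_rng(3))
        b = lc.sample_tool_placement("forceps", np.random.default_rng(3))
        assert a == b


def _identity_placement(template, size):
    h, w = size
    return lc.ToolPlacement(
        scale=1.0, stretch=1.0, rotation_deg=0.0,
        tip_x=template.tip[0] / w, tip_y=template.tip[1] / h,
        blur_kernel_px=3, shadow_offset_px=10.0, shadow_angle_deg=0.0,
        shadow_alpha=0.3, glare_n_ovals=2, glare_radius_px=5.0,
        glare_crest_alpha=0.2)


class TestToolLayer:
    def test_identity_placement_reproduces_template(self, template):
        size = (128, 384)               # canvas larger than the template
        pl = _identity_placement(template, size)
        color, opacity, _ = lc.place_tool(template, pl, size,
                                          apply_stretch=False)
        th, tw = template.opacity.shape
        assert np.allclose(opacity[:th, :tw], template.opacity, atol=1e-3)
        assert opacity[th:].max() < 1e-3

    def test_hue_matches_retina_mean(self, template, retina):
        from skimage.color import rgb2hsv
        pl = lc.sample_tool_placement("cutter", np.random.default_rng(5))
        tool, _, _ = lc.make_tool_layer(template, pl, retina,
                                        np.random.default_rng(6))
        mh, _, _ = lc.mean_retina_hsv(retina)
        support = tool.opacity > 0.5
        hues = rgb2hsv(np.clip(tool.color, 0, 255) / 255.0)[..., 0][support]
        dh = np.minimum(np.abs(hues - mh), 1 - np.abs(hues - mh)) * 360
        assert np.median(dh) < 5

    def test_shadow_support_is_translated_tool_support(self, template):
        size = (96, 128)
        pl = _identity_placement(template, size)
        _, opacity, _ = lc.place_tool(template, pl, size)
        dx, dy = lc.shadow_offset_vector(pl)
        shifted = lc.shift_support(opacity, dx, dy)
        ys, xs = np.nonzero(opacity > 0.5)
        inb = (ys + dy < size[0]) & (xs + dx < size[1])
        assert np.array_equal(shifted[ys[inb] + dy, xs[inb] + dx],
                              opacity[ys[inb], xs[inb]])

    def test_zero_shadow_alpha_leaves_composite_unchanged(self, template,
                                                          retina):
        size = (96, 128)
        pl = _identity_placement(template, size)
        pl.shadow_alpha = 0.0
        tool, shadow, glare = lc.make_tool_layer(
            template, pl, retina, np.random.default_rng(2), with_glare=False)
        with_shadow, _ = lc.composite_stack([retina, shadow, tool])
        without, _ = lc.composite_stack([retina, tool])
        assert np.array_equal(with_shadow, without)

    def test_off_canvas_placement_raises(self, template, retina):
        pl = _identity_placement(template, (96, 128))
        pl.tip_x, pl.tip_y, pl.rotation_deg = 3.0, 3.0, 0.0
        with pytest.raises(lc.PlacementError):
            lc.make_tool_layer(template, pl, retina, np.random.default_rng(0))


class TestFovLayer:
    def test_radius_and_centre_ranges(self):
        rng = np.random.default_rng(0)
        h = 96
        for _ in range(200):
            layer = lc.make_fov_layer((h, 128), rng)
            assert 0.4 * h <= layer.meta["radius"] <= 0.8 * h
            assert 0.4 * h <= layer.meta["cy"] <= 0.6 * h
            assert 0.4 * 128 <= layer.meta["cx"] <= 0.6 * 128

    def test_opacity_centre_and_corner(self):
        layer = lc.make_fov_layer((96, 128), np.random.default_rng(1))
        cy, cx = int(layer.meta["cy"]), int(layer.meta["cx"])
        assert layer.opacity[cy, cx] < 0.01
        assert layer.opacity[0, 0] > 0.99

    def test_in_fov_area_close_to_disc_area(self):
        # a seed whose circle lies fully inside the frame
        rng = np.random.default_rng(7)
        for _ in range(50):
            layer = lc.make_fov_layer((128, 192), rng)
            r, cx, cy = (layer.meta["radius"], layer.meta["cx"],
                         layer.meta["cy"])
            if (r < cx < 192 - r) and (r < cy < 128 - r):
                area = (layer.opacity < 0.5).sum()
                assert abs(area - np.pi * r ** 2) / (np.pi * r ** 2) < 0.1
                return
        pytest.fail("no fully interior circle drawn in 50 tries")


class TestCompositeStack:
    def test_retina_only_passthrough(self, retina):
        frame, seg = lc.composite_stack([retina])
        assert np.array_equal(frame, retina.color.astype(np.uint8))
        assert seg.all()

    def test_opaque_tool_wins_but_seg_is_fov_only(self, retina):
        size = (96, 128)
        tool = lc.SceneLayer(color=np.full(size + (3,), 90, np.float32),
                             opacity=np.zeros(size, np.float32), role="tool")
        tool.opacity[30:40, 30:60] = 1.0
        fov = lc.make_fov_layer(size, np.random.default_rng(2))
        frame, seg = lc.composite_stack([retina, tool, fov])
        inside = (fov.opacity == 0)
        patch = np.zeros(size, bool)
        patch[30:40, 30:60] = True
        sel = patch & inside
        assert np.all(np.abs(frame[sel].astype(int) - 90) <= 1)
        assert np.array_equal(seg, (fov.opacity < 0.5).astype(np.uint8))

    def test_matches_bruteforce_alpha_over(self):
        rng = np.random.default_rng(8)
        size = (16, 16)
        layers = [lc.SceneLayer(color=rng.uniform(0, 255, size + (3,)),
                                opacity=np.ones(size), role="retina")]
        for _ in range(3):
            layers.append(lc.SceneLayer(color=rng.uniform(0, 255, size + (3,)),
                                        opacity=rng.uniform(0, 1, size),
                                        role="tool"))
        frame, _ = lc.composite_stack(layers)
        # per-pixel loop oracle
        for y in range(16):
            for x in range(8):
                acc = np.zeros(3)
                for layer in layers:
                    a = layer.opacity[y, x]
                    acc = layer.color[y, x] * a + acc * (1 - a)
                assert np.all(np.abs(frame[y, x].astype(float)
                                     - np.clip(np.round(acc), 0, 255)) <= 1)

    def test_structural_validation(self, retina):
        fov = lc.make_fov_layer((96, 128), np.random.default_rng(0))
        with pytest.raises(ValueError):
            lc.composite_stack([fov, retina])       # fov must be on top
        with pytest.raises(ValueError):
            lc.composite_stack([retina, retina])    # one retina only
        small = lc.SceneLayer(color=np.zeros((8, 8, 3), np.float32),
                              opacity=np.zeros((8, 8), np.float32), role="tool")
        with pytest.raises(ValueError):
            lc.composite_stack([retina, small])     # size mismatch
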
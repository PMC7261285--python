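"""Closed-form flow fields, chain application and photometric transforms."""

import json

import numpy as np
import pytest

from retinaflow import transform_engine as tr
from retinaflow.flowcore import warp_backward
from retinaflow.layer_compositor import SceneLayer
from retinaflow.synth_fundus import FundusParams, generate_fundus


@pytest.fixture(scope="module")
def retina_layer():
    img = generate_fundus(FundusParams(seed=2, size=(96, 128)))
    return SceneLayer(color=img.astype(np.float32),
                      opacity=np.ones((96, 128), np.float32), role="retina")


class TestAffineFlow:
    def test_identity_is_zero(self):
        f = tr.affine_flow((0, 0, 0, 1.0), (32, 32))
        assert np.allclose(f, 0, atol=1e-9)

    def test_pure_translation(self):
        f = tr.affine_flow((3.0, -2.0, 0, 1.0), (16, 24))
        assert np.allclose(f[..., 0], 3.0) and np.allclose(f[..., 1], -2.0)

    def test_rotation_chord_length_identity(self):
        theta = 4.0
        size = (48, 64)
        f = tr.affine_flow((0, 0, theta, 1.0), size)
        gy, gx = np.mgrid[0:48, 0:64].astype(np.float64)
        cx, cy = (64 - 1) / 2, (48 - 1) / 2
        r = np.hypot(gx - cx, gy - cy)
        chord = 2 * r * np.sin(np.radians(theta) / 2)
        assert np.abs(np.hypot(f[..., 0], f[..., 1]) - chord).max() < 1e-4

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            tr.affine_flow((0, 0, 0, -1.0), (8, 8))


class TestPincushionFlow:
    def test_zero_at_centre_max_at_corner(self):
        size = (48, 64)
        f = tr.pincushion_flow(20.0, size)
        mag = np.hypot(f[..., 0], f[..., 1])
        cx, cy = (64 - 1) / 2, (48 - 1) / 2
        assert mag[int(cy), int(round(cx))] < 0.2
        assert abs(mag[0, 0] - 20.0) < 1e-6

    def test_monotone_along_rays(self):
        f = tr.pincushion_flow(30.0, (64, 64))
        mag = np.hypot(f[..., 0], f[..., 1])
        cx = cy = (64 - 1) / 2
        rng = np.random.default_rng(0)
        for _ in range(100):
            ang = rng.uniform(0, 2 * np.pi)
            radii = np.linspace(0, 30, 40)
            xs = np.clip(np.round(cx + radii * np.cos(ang)), 0, 63).astype(int)
            ys = np.clip(np.round(cy + radii * np.sin(ang)), 0, 63).astype(int)
            vals = mag[ys, xs]
            assert np.all(np.diff(vals) >= -1e-6)


class TestBubbleFlow:
    def test_compact_support_and_centre(self):
        size = (64, 64)
        f = tr.bubble_flow((30.0, 30.0), 12.0, 5.0, size)
        gy, gx = np.mgrid[0:64, 0:64].astype(np.float64)
        r = np.hypot(gx - 30, gy - 30)
        outside = r >= 12.0
        assert np.all(f[outside] == 0)
        assert np.allclose(f[30, 30], 0)

    def test_amplitude_bound(self):
        f = tr.bubble_flow((40.0, 40.0), 20.0, 6.0, (96, 96))
        assert np.hypot(f[..., 0], f[..., 1]).max() <= 6.0 + 1e-9


class TestApplyChain:
    def test_empty_chain_is_identity(self, retina_layer):
        out, flow = tr.apply_chain(retina_layer, tr.TransformChain([]))
        assert np.array_equal(out.color, retina_layer.color)
        assert np.all(flow == 0)

    def test_translations_accumulate(self, retina_layer):
        chain = tr.TransformChain([
            tr.TransformSpec("translate", {"tx": 3.0, "ty": 0.0}),
            tr.TransformSpec("translate", {"tx": 0.0, "ty": 4.0})])
        out, flow = tr.apply_chain(retina_layer, chain)
        assert np.allclose(flow[..., 0], 3.0, atol=1e-5)
        assert np.allclose(flow[..., 1], 4.0, atol=1e-5)
        # warped layer equals a direct (3, 4) shift: out[y, x] = in[y-4, x-3]
        assert np.allclose(out.color[10:, 10:],
                           retina_layer.color[6:-4, 7:-3], atol=1.0)

    def test_rotate_scale_matches_composed_affine(self, retina_layer):
        from retinaflow.flowcore import compose_flows
        size = retina_layer.size
        chain = tr.TransformChain([
            tr.TransformSpec("rotate", {"theta_deg": 4.0}),
            tr.TransformSpec("scale", {"s": 1.05})])
        _, flow = tr.apply_chain(retina_layer, chain)
        singles = compose_flows(tr.affine_flow((0, 0, 4.0, 1.0), size),
                                tr.affine_flow((0, 0, 0.0, 1.05), size))
        assert np.abs(flow - singles)[10:-10, 10:-10].max() < 0.1

    def test_warp_consistency_of_chain(self, retina_layer):
        chain = tr.TransformChain([
            tr.TransformSpec("rotate", {"theta_deg": 3.0}),
            tr.TransformSpec("pincushion", {"max_disp_px": 15.0})])
        out, flow = tr.apply_chain(retina_layer, chain)
        warped, valid = warp_backward(out.color, flow)
        err = np.abs(warped - retina_layer.color)[valid]
        assert err.mean() < 2.0

    def test_double_exposure_blends_but_keeps_flow(self, retina_layer):
        chain_plain = tr.TransformChain([
            tr.TransformSpec("translate", {"tx": 6.0, "ty": 0.0})])
        chain_de = tr.TransformChain([
            tr.TransformSpec("translate", {"tx": 6.0, "ty": 0.0}),
            tr.TransformSpec("double_exposure", {"alpha": 0.5})])
        out_p, flow_p = tr.apply_chain(retina_layer, chain_plain)
        out_d, flow_d = tr.apply_chain(retina_layer, chain_de)
        assert np.array_equal(flow_p, flow_d)
        expect = 0.5 * out_p.color + 0.5 * retina_layer.color
        assert np.allclose(out_d.color, expect, atol=1e-3)

    def test_at_most_one_double_exposure(self):
        with pytest.raises(ValueError):
            tr.TransformChain([
                tr.TransformSpec("double_exposure", {"alpha": 0.4}),
                tr.TransformSpec("double_exposure", {"alpha": 0.5})])

    def test_photometric_never_touches_opacity_or_flow(self, retina_layer):
        chain = tr.TransformChain([
            tr.TransformSpec("translate", {"tx": 2.0, "ty": 1.0}),
            tr.TransformSpec("brightness_global", {"delta": 10.0})])
        out, flow = tr.apply_chain(retina_layer, chain)
        chain_geo = tr.TransformChain([chain.specs[0]])
        out_geo, flow_geo = tr.apply_chain(retina_layer, chain_geo)
        assert np.array_equal(flow, flow_geo)
        assert np.array_equal(out.opacity, out_geo.opacity)


class TestChainSerialization:
    def test_json_round_trip(self):
        chain = tr.TransformChain([
            tr.TransformSpec("affine", {"tx": 1.0, "ty": 2.0,
                                        "theta_deg": 3.0, "s": 1.02}),
            tr.TransformSpec("bubble", {"centre": [40.0, 50.0],
                                        "radius": 20.0, "amplitude": 4.0}),
            tr.TransformSpec("blur", {"kernel_px": 3})])
        back = tr.TransformChain.from_json(chain.to_json())
        assert back == chain

    def test_affects_flow_flag(self):
        assert tr.TransformSpec("translate", {"tx": 0, "ty": 0}).affects_flow
        assert tr.TransformSpec("double_exposure", {"alpha": .5}).affects_flow
        assert not tr.TransformSpec("blur", {"kernel_px": 3}).affects_flow


class TestPhotometric:
    def test_zero_delta_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (16, 16, 3),
                                                dtype=np.uint8)
        out = tr.apply_photometric(img, tr.TransformSpec(
            "brightness_global", {"delta": 0.0}))
        assert np.array_equal(out, img)

    def test_global_plus_15_exact(self):
        img = np.full((16, 16, 3), 128, np.uint8)
        out = tr.apply_photometric(img, tr.TransformSpec(
            "brightness_global", {"delta": 15.0}))
        assert np.all(out == 143)

    def test_local_patch_compact_support(self):
        img = np.full((64, 64, 3), 100, np.uint8)
        spec = tr.TransformSpec("brightness_local",
                                {"cx": 20.0, "cy": 20.0, "radius": 10.0,
                                 "delta": 30.0})
        out = tr.apply_photometric(img, spec)
        gy, gx = np.mgrid[0:64, 0:64].astype(float)
        far = np.hypot(gx - 20, gy - 20) > 10.0
        assert np.array_equal(out[far], img[far])
        assert out[20, 20, 0] > 120


class TestDegrade:
    def test_near_identity_at_mild_settings(self):
        img = generate_fundus(FundusParams(seed=5, size=(64, 64)))
        out = tr.degrade(img, np.random.default_rng(2), noise_sigma=0.0,
                         jpeg_quality=100)
        assert np.abs(out.astype(float) - img.astype(float)).mean() < 1.0

    def test_noise_magnitude(self):
        img = np.full((64, 64, 3), 128, np.uint8)
        out = tr.degrade(img, np.random.default_rng(3), noise_sigma=5.0,
                         jpeg_quality=95)
        sd = (out.astype(float) - img.astype(float)).std()
        assert 3.5 < sd < 6.5

    def test_deterministic_per_seed(self):
        img = np.random.default_rng(4).integers(0, 255, (32, 32, 3),
                                                dtype=np.uint8)
        a = tr.degrade(img, np.random.default_rng(9))
        b = tr.degrade(img, np.random.default_rng(9))
        assert np.array_equal(a, b)
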
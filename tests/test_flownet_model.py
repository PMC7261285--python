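"""Network construction, the four-term cost, gradients and training."""

import numpy as np
import pytest

from retinaflow import nn
from retinaflow import flownet_model as fm


class TestBuildNetwork:
    def test_full_width_parameter_count(self):
        model = fm.FlowNet(fm.NetworkConfig(width_multiplier=1.0), seed=0)
        assert 30e6 <= model.parameter_count() <= 45e6

    def test_width_scaling_is_quadratic(self):
        full = fm.FlowNet(fm.NetworkConfig(width_multiplier=1.0), seed=0)
        half = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.5), seed=0)
        ratio = half.parameter_count() / full.parameter_count()
        assert abs(ratio - 0.25) < 0.025

    def test_forward_full_resolution_shapes(self):
        model = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.25), seed=0)
        x = np.zeros((1, 6, 384, 512), np.float32)
        preds = model.forward(x)
        assert len(preds) >= 4
        factor, flow, seg = preds[-1]
        assert flow.shape == (1, 2, 384 // factor, 512 // factor)
        assert seg.shape == (1, 2, 384 // factor, 512 // factor)

    def test_comb_and_branch_share_flow_path_shapes(self):
        comb = fm.FlowNet(fm.NetworkConfig(variant="comb",
                                           width_multiplier=0.25), seed=0)
        branch = fm.FlowNet(fm.NetworkConfig(variant="branch",
                                             width_multiplier=0.25), seed=0)
        for name, p in comb.params.items():
            if name.startswith(("enc.", "dec.")):
                assert branch.params[name].data.shape == p.data.shape
        assert any(k.startswith("segdec.") for k in branch.params)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            fm.NetworkConfig(width_multiplier=0.0)
        with pytest.raises(ValueError):
            fm.NetworkConfig(variant="tiny")

    def test_save_load_round_trip(self, tmp_path):
        model = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.25, levels=3),
                           seed=4)
        model.save(tmp_path / "m.npz")
        back = fm.FlowNet.load(tmp_path / "m.npz")
        assert back.config == model.config
        for k in model.params:
            assert np.array_equal(back.params[k].data, model.params[k].data)


def _toy_preds(gt_flow, gt_seg, perfect=True, seed=0):
    """Single-scale 'predictions' wrapped as tensors."""
    if perfect:
        flow = nn.Tensor(gt_flow.copy())
        logits = np.where(np.stack([1 - gt_seg, gt_seg], axis=1) > 0.5,
                          50.0, -50.0)
    else:
        rng = np.random.default_rng(seed)
        flow = nn.Tensor(gt_flow + rng.standard_normal(gt_flow.shape))
        logits = rng.standard_normal((gt_seg.shape[0], 2) + gt_seg.shape[1:])
    return [(1, flow, nn.Tensor(np.asarray(logits, dtype=gt_flow.dtype)))]


class TestMultiscaleCost:
    def test_perfect_prediction_has_zero_flow_seg_tv(self):
        gt_flow = np.full((1, 2, 8, 8), 1.5)
        gt_seg = np.ones((1, 8, 8))
        params = {"w": nn.Tensor(np.zeros(3))}
        total, terms = fm.multiscale_cost(_toy_preds(gt_flow, gt_seg),
                                          gt_flow, gt_seg,
                                          fm.LossWeights(), params)
        assert terms["flow"] < 1e-5
        assert terms["seg"] < 1e-6
        assert terms["tv"] < 1e-5
        assert terms["reg"] == 0.0

    def test_constant_flow_has_zero_tv(self):
        gt_flow = np.zeros((1, 2, 8, 8))
        gt_seg = np.ones((1, 8, 8))
        pred = [(1, nn.Tensor(np.full((1, 2, 8, 8), 3.0)), None)]
        _, terms = fm.multiscale_cost(pred, gt_flow, gt_seg, fm.LossWeights(),
                                      {"w": nn.Tensor(np.zeros(2))})
        assert terms["tv"] < 1e-5

    def test_flow_term_matches_hand_arithmetic(self):
        # 2x2, single scale: mean of the four vector norms
        pred_f = np.array([[[[1.0, 2.0], [3.0, 4.0]],
                            [[0.0, 1.0], [2.0, 2.0]]]])
        gt_f = np.zeros((1, 2, 2, 2))
        norms = np.hypot(pred_f[0, 0], pred_f[0, 1])
        expected = norms.mean()
        preds = [(1, nn.Tensor(pred_f), None)]
        _, terms = fm.multiscale_cost(preds, gt_f, np.ones((1, 2, 2)),
                                      fm.LossWeights(),
                                      {"w": nn.Tensor(np.zeros(1))})
        assert abs(terms["flow"] - expected) < 1e-6

    def test_total_is_sum_of_terms(self):
        gt_flow = np.random.default_rng(0).standard_normal((1, 2, 8, 8))
        gt_seg = (np.random.default_rng(1).random((1, 8, 8)) > 0.3).astype(float)
        params = {"w": nn.Tensor(np.random.default_rng(2).standard_normal(5))}
        w = fm.LossWeights(lambda_seg=1e-2, lambda_reg=1e-3, lambda_var=1e-4)
        total, terms = fm.multiscale_cost(
            _toy_preds(gt_flow, gt_seg, perfect=False), gt_flow, gt_seg, w,
            params)
        assert abs(float(total.data) - sum(terms.values())) \
            <= 1e-9 * abs(float(total.data))

    def test_scale_mismatch_raises(self):
        pred = [(2, nn.Tensor(np.zeros((1, 2, 5, 5))), None)]
        with pytest.raises(ValueError):
            fm.multiscale_cost(pred, np.zeros((1, 2, 8, 8)),
                               np.ones((1, 8, 8)), fm.LossWeights(),
                               {"w": nn.Tensor(np.zeros(1))})


class TestGradients:
    def _max_rel_err(self, model, x, gt_flow, gt_seg, weights, n_probe=4):
        def cost():
            preds = model.forward(x)
            t, _ = fm.multiscale_cost(preds, gt_flow, gt_seg, weights,
                                      model.params)
            return t
        total = cost()
        for p in model.params.values():
            p.grad = None
        nn.backward(total)
        rng = np.random.default_rng(0)
        worst = 0.0
        for name, p in model.params.items():
            flat = p.data.ravel()
            for i in rng.choice(flat.size, size=min(n_probe, flat.size),
                                replace=False):
                eps = 1e-6
                orig = flat[i]
                flat[i] = orig + eps
                c1 = float(cost().data)
                flat[i] = orig - eps
                c2 = float(cost().data)
                flat[i] = orig
                num = (c1 - c2) / (2 * eps)
                ana = p.grad.ravel()[i]
                worst = max(worst, abs(num - ana)
                            / max(1e-8, abs(num) + abs(ana)))
        return worst

    def test_numeric_vs_analytic_on_4x4_toy(self):
        model = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.25, levels=2),
                           seed=2, dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 6, 4, 4))
        gt_flow = rng.standard_normal((1, 2, 4, 4))
        gt_seg = (rng.random((1, 4, 4)) > 0.4).astype(np.float64)
        w = fm.LossWeights(lambda_seg=1e-2, lambda_reg=1e-4, lambda_var=1e-3)
        assert self._max_rel_err(model, x, gt_flow, gt_seg, w) < 1e-4

    def test_numeric_vs_analytic_through_decoder(self):
        # deeper toy covering resize, concat and channel-split backward
        model = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.25, levels=3),
                           seed=3, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 6, 8, 8))
        gt_flow = rng.standard_normal((1, 2, 8, 8))
        gt_seg = (rng.random((1, 8, 8)) > 0.4).astype(np.float64)
        w = fm.LossWeights(lambda_seg=1e-2, lambda_reg=1e-4, lambda_var=1e-3)
        assert self._max_rel_err(model, x, gt_flow, gt_seg, w, n_probe=2) < 1e-4


class TestTraining:
    def test_learning_rate_schedule(self):
        cfg = fm.TrainConfig()
        assert abs(fm.learning_rate(cfg, 20000) - 1e-4 * 0.95 ** 2) < 1e-12
        assert fm.learning_rate(cfg, 0) == 1e-4

    def test_two_runs_identical(self):
        from retinaflow.dataset_builder import (sample_record,
                                                translation_subset_spec)
        spec = translation_subset_spec(size=(32, 32), n_records=12, seed=2)
        records = [sample_record(spec, i) for i in range(12)]
        losses = []
        for _ in range(2):
            model = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.25,
                                                levels=3), seed=5)
            cfg = fm.TrainConfig(epochs=2, batch_size=4, keep_best=False)
            hist = fm.train(model, records[:10], cfg, seed=5,
                            val_records=records[10:])
            losses.append(hist["train_loss"])
        assert losses[0] == losses[1]

    def test_empty_dataset_rejected(self):
        model = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.25, levels=2),
                           seed=0)
        with pytest.raises(ValueError):
            fm.train(model, [], fm.TrainConfig())


class TestPredict:
    def test_shapes_and_finiteness_on_odd_size(self):
        model = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.25, levels=3),
                           seed=1)
        frame = np.random.default_rng(0).integers(0, 255, (50, 70, 3),
                                                  dtype=np.uint8)
        flow, seg = fm.predict(model, frame, frame)
        assert flow.shape == (50, 70, 2)
        assert seg.shape == (50, 70)
        assert np.all(np.isfinite(flow))
        assert set(np.unique(seg)) <= {0, 1}

    def test_mismatched_frames_rejected(self):
        model = fm.FlowNet(fm.NetworkConfig(width_multiplier=0.25, levels=2),
                           seed=1)
        with pytest.raises(ValueError):
            fm.predict(model, np.zeros((32, 32, 3), np.uint8),
                       np.zeros((32, 48, 3), np.uint8))
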
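"""Multi-task optical-flow + FOV-segmentation network and its training loop.

The estimator follows the FlowNetSimple pattern: the two RGB frames are
concatenated channel-wise (6 input channels) and passed through a strided
convolutional encoder; a decoder with skip connections emits flow
predictions at several scales (1/64 ... 1/4 of the input), each in the
pixel units of its own grid.  Two segmentation designs are supported:

* ``comb`` — every prediction head emits 4 channels that are split
  downstream into 2 flow + 2 segmentation-logit channels;
* ``branch`` — the heads emit flow only and a second, lighter decoder
  produces the segmentation logits.

All activations are leaky ReLUs with slope 0.01.  The cost is the sum of
four terms: mean end-point error across scales, an L2 weight penalty, a
summed softmax cross-entropy on the segmentation, and a masked total
variation penalty on the finest flow prediction (the mask blanks a 3 px
band at the field-of-view border so the true flow discontinuity there is
not smoothed away).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor

# FlowNetSimple-style encoder: (kernel, stride, base_channels) per conv.
_ENCODER_PLAN = [
    ("conv1", 7, 2, 64),
    ("conv2", 5, 2, 128),
    ("conv3", 5, 2, 256), ("conv3_1", 3, 1, 256),
    ("conv4", 3, 2, 512), ("conv4_1", 3, 1, 512),
    ("conv5", 3, 2, 512), ("conv5_1", 3, 1, 512),
    ("conv6", 3, 2, 1024), ("conv6_1", 3, 1, 1024),
]
_DECODER_BASE = {5: 512, 4: 256, 3: 128, 2: 64}


@dataclass
class NetworkConfig:
    """Architecture switches; ``width_multiplier`` scales every channel
    count (rounded to the nearest multiple of 8)."""

    variant: str = "comb"              # comb | branch
    width_multiplier: float = 1.0
    multi_scale: bool = True
    seg_head: bool = True
    leaky_slope: float = 0.01
    levels: int = 6                    # number of stride-2 encoder stages

    def __post_init__(self):
        if self.variant not in ("comb", "branch"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must lie in (0, 1]")
        if not 2 <= self.levels <= 6:
            raise ValueError("levels must lie in [2, 6]")


@dataclass
class LossWeights:
    lambda_flow: float = 1.0
    lambda_seg: float = 1e-3
    lambda_reg: float = 1e-7
    lambda_var: float = 1e-6


@dataclass
class TrainConfig:
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 10
    lr0: float = 1e-4
    decay_rate: float = 0.95
    decay_steps: float = 1e4
    epochs: int = 100
    val_fraction: float = 0.05
    augment_flips: bool = True         # random H/V flips during training
    keep_best: bool = True             # restore the best-validation weights
    grad_clip: float | None = None     # global gradient-norm ceiling
    swa_fraction: float | None = None  # average weights over the last
    #                                    fraction of epochs (overrides
    #                                    keep_best when set)


def learning_rate(cfg: TrainConfig, step: int) -> float:
    """Continuous exponential decay: ``lr0 * rate^(step / decay_steps)``."""
    return cfg.lr0 * cfg.decay_rate ** (step / cfg.decay_steps)


def _round8(c: float) -> int:
    return max(8, int(round(c / 8)) * 8)


class FlowNet:
    """Encoder-decoder flow/segmentation estimator (numpy autodiff)."""

    def __init__(self, config: NetworkConfig, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.params: dict[str, Tensor] = {}
        self._build(np.random.default_rng(seed))

    # -- construction ------------------------------------------------------

    def _conv_param(self, name, cin, cout, k, rng):
        std = np.sqrt(2.0 / (cin * k * k))
        w = Tensor((rng.standard_normal((cout, cin, k, k)) * std)
                   .astype(self.dtype), name=name + ".w")
        b = Tensor(np.zeros(cout, dtype=self.dtype), name=name + ".b")
        self.params[name + ".w"] = w
        self.params[name + ".b"] = b
        return w, b

    def _encoder_plan(self):
        plan, stage = [], 0
        for name, k, s, c in _ENCODER_PLAN:
            if s == 2:
                stage += 1
                if stage > self.config.levels:
                    break
            plan.append((name, k, s, _round8(c * self.config.width_multiplier)))
        return plan

    def _build(self, rng):
        cfg = self.config
        plan = self._encoder_plan()
        cin = 6
        self._plan = plan
        for name, k, s, cout in plan:
            self._conv_param("enc." + name, cin, cout, k, rng)
            cin = cout
        # channels available at each stride level (after refinement convs)
        level_ch = {}
        stage = 0
        for name, k, s, cout in plan:
            if s == 2:
                stage += 1
            level_ch[stage] = cout
        self._level_ch = level_ch
        out_ch = 4 if (cfg.variant == "comb" and cfg.seg_head) else 2

        deepest = cfg.levels
        self._conv_param("pred.l%d" % deepest, level_ch[deepest], out_ch, 3, rng)
        feat_ch = level_ch[deepest]
        for lvl in range(deepest - 1, 1, -1):
            dec_ch = _round8(_DECODER_BASE.get(lvl, 64) * cfg.width_multiplier)
            cin_dec = feat_ch + level_ch[lvl] + 2
            self._conv_param("dec.l%d" % lvl, cin_dec, dec_ch, 3, rng)
            self._conv_param("pred.l%d" % lvl, dec_ch, out_ch, 3, rng)
            feat_ch = dec_ch

        if cfg.variant == "branch" and cfg.seg_head:
            feat_ch = level_ch[deepest]
            for lvl in range(deepest - 1, 1, -1):
                dec_ch = _round8(_DECODER_BASE.get(lvl, 64)
                                 * cfg.width_multiplier / 2)
                self._conv_param("segdec.l%d" % lvl,
                                 feat_ch + level_ch[lvl], dec_ch, 3, rng)
                self._conv_param("segpred.l%d" % lvl, dec_ch, 2, 3, rng)
                feat_ch = dec_ch

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    # -- forward -----------------------------------------------------------

    def _conv(self, name, x, k, s, act=True):
        w = self.params[name + ".w"]
        b = self.params[name + ".b"]
        out = nn.conv2d(x, w, b, stride=s, pad=k // 2)
        return nn.leaky_relu(out, self.config.leaky_slope) if act else out

    def forward(self, x):
        """Run the network; returns a list of per-scale predictions
        ``(factor, flow, seg_logits_or_None)`` ordered coarse to fine."""
        cfg = self.config
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype), requires_grad=False)
        skips = {}
        feat = x
        stage = 0
        for name, k, s, cout in self._plan:
            feat = self._conv("enc." + name, feat, k, s)
            if s == 2:
                stage += 1
            skips[stage] = feat

        out_seg = cfg.variant == "comb" and cfg.seg_head
        deepest = cfg.levels
        preds = []
        pred = self._conv("pred.l%d" % deepest, skips[deepest], 3, 1, act=False)
        preds.append((2 ** deepest, pred))
        feat = skips[deepest]
        for lvl in range(deepest - 1, 1, -1):
            hw = skips[lvl].shape[2:]
            up = nn.resize_bilinear(feat, hw)
            upflow = nn.scale(nn.resize_bilinear(_flow_part(preds[-1][1]), hw), 2.0)
            feat = self._conv("dec.l%d" % lvl,
                              nn.concat([up, skips[lvl], upflow]), 3, 1)
            preds.append((2 ** lvl, self._conv("pred.l%d" % lvl, feat, 3, 1,
                                               act=False)))

        seg_preds = {}
        if cfg.variant == "branch" and cfg.seg_head:
            feat = skips[deepest]
            for lvl in range(deepest - 1, 1, -1):
                hw = skips[lvl].shape[2:]
                up = nn.resize_bilinear(feat, hw)
                feat = self._conv("segdec.l%d" % lvl,
                                  nn.concat([up, skips[lvl]]), 3, 1)
                seg_preds[2 ** lvl] = self._conv("segpred.l%d" % lvl, feat,
                                                 3, 1, act=False)

        out = []
        for factor, p in preds:
            flow = _flow_part(p)
            if out_seg:
                seg = _seg_part(p)
            else:
                seg = seg_preds.get(factor)
            out.append((factor, flow, seg))
        if not cfg.multi_scale:
            out = out[-1:]
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path):
        arrays = {k: p.data for k, p in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FlowNet":
        data = np.load(path)
        cfg = NetworkConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = cls(cfg)
        for k in model.params:
            model.params[k].data = data[k].astype(model.dtype)
        return model


def _channel_slice(t: Tensor, c0, c1) -> Tensor:
    out = t.data[:, c0:c1]
    if not nn._GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(out, parents=(t,))

    def bw(g):
        full = np.zeros_like(t.data)
        full[:, c0:c1] = g
        t.accumulate(full)

    res.bw = bw
    return res


def _flow_part(p: Tensor) -> Tensor:
    return _channel_slice(p, 0, 2) if p.shape[1] > 2 else p


def _seg_part(p: Tensor) -> Tensor:
    return _channel_slice(p, 2, 4)


def build_network(config: NetworkConfig, seed: int = 0) -> FlowNet:
    return FlowNet(config, seed=seed)


# ---------------------------------------------------------------------------
# Multi-scale cost
# ---------------------------------------------------------------------------

def _pool_flow(gt: np.ndarray, factor: int) -> np.ndarray:
    """Batch block-average pooling with coarse-grid rescaling, NCHW."""
    if factor == 1:
        return gt
    n, c, h, w = gt.shape
    if h % factor or w % factor:
        raise ValueError(f"GT size {h}x{w} not divisible by scale {factor}")
    pooled = gt.reshape(n, c, h // factor, factor, w // factor, factor)
    return pooled.mean(axis=(3, 5)) / factor


def _pool_seg(seg: np.ndarray, factor: int) -> np.ndarray:
    """Majority pooling of a {0,1} mask, NHW."""
    if factor == 1:
        return seg
    n, h, w = seg.shape
    pooled = seg.reshape(n, h // factor, factor, w // factor, factor)
    return (pooled.mean(axis=(2, 4)) > 0.5).astype(seg.dtype)


def fov_border_mask(seg: np.ndarray, band_px: int = 3) -> np.ndarray:
    """1 away from the FOV border, 0 in a ``band_px`` band around it."""
    out = np.ones_like(seg, dtype=bool)
    for i in range(seg.shape[0]):
        edge = ndimage.binary_dilation(seg[i] > 0, iterations=1) ^ \
            ndimage.binary_erosion(seg[i] > 0, iterations=1)
        band = ndimage.binary_dilation(edge, iterations=band_px)
        out[i] = ~band
    return out


def multiscale_cost(preds, gt_flow: np.ndarray, gt_seg: np.ndarray,
                    weights: LossWeights, params: dict,
                    border_band_px: int = 3):
    """Four-term cost over the per-scale predictions.

    Parameters
    ----------
    preds : list of ``(factor, flow, seg_logits_or_None)`` from ``forward``.
    gt_flow : (N, 2, H, W) full-resolution ground-truth flow, px.
    gt_seg : (N, H, W) {0,1} FOV mask.
    weights : term weightings; the flow weight stays 1.
    params : model parameter dict (for the L2 term).

    Returns ``(total, breakdown)`` where ``total`` is a scalar tensor and
    ``breakdown`` maps term names to floats.
    """
    terms = []
    flow_parts = []
    seg_parts = []
    for factor, flow, seg in preds:
        if flow.shape[2:] != (gt_flow.shape[2] // factor,
                              gt_flow.shape[3] // factor):
            raise ValueError(
                f"prediction at scale {factor} has shape {flow.shape[2:]}, "
                f"GT implies {(gt_flow.shape[2] // factor, gt_flow.shape[3] // factor)}")
        gt_s = _pool_flow(gt_flow, factor).astype(flow.data.dtype)
        # mean EPE at this scale; scales then enter with equal weight
        flow_parts.append(nn.scale(nn.epe_sum(flow, gt_s),
                                   1.0 / flow.data[:, 0].size))
        if seg is not None and weights.lambda_seg > 0:
            seg_s = _pool_seg(gt_seg, factor)
            onehot = np.stack([1 - seg_s, seg_s], axis=1).astype(seg.data.dtype)
            seg_parts.append(nn.softmax_ce_sum(seg, onehot))

    flow_term = nn.scale(nn.add_scalars(flow_parts),
                         weights.lambda_flow / len(flow_parts))
    terms.append(("flow", flow_term))

    reg_term = nn.scale(nn.l2_energy(list(params.values())), weights.lambda_reg)
    terms.append(("reg", reg_term))

    if seg_parts:
        terms.append(("seg", nn.scale(nn.add_scalars(seg_parts),
                                      weights.lambda_seg)))
    else:
        terms.append(("seg", Tensor(np.zeros((), dtype=gt_flow.dtype),
                                    requires_grad=False)))

    # Total variation on the finest-scale prediction.
    factor, flow, _ = preds[-1]
    mask = _pool_seg(fov_border_mask(gt_seg, border_band_px)
                     .astype(np.float64), factor) > 0.5
    terms.append(("tv", nn.scale(nn.tv_sum(flow, mask), weights.lambda_var)))

    total = nn.add_scalars([t for _, t in terms])
    breakdown = {name: float(t.data) for name, t in terms}
    return total, breakdown


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def _records_to_arrays(records, dtype=np.float32):
    x = np.stack([
        np.concatenate([r.frame1, r.frame2], axis=-1).transpose(2, 0, 1)
        for r in records]).astype(dtype) / 255.0 - 0.5
    gt_flow = np.stack([r.flow_simple.transpose(2, 0, 1)
                        for r in records]).astype(dtype)
    gt_seg = np.stack([r.seg1 for r in records]).astype(dtype)
    return x, gt_flow, gt_seg


def _flip_batch(x, gt_flow, gt_seg, rng):
    """Random horizontal/vertical flips with consistently flipped flow."""
    x, gt_flow, gt_seg = x.copy(), gt_flow.copy(), gt_seg.copy()
    for i in range(x.shape[0]):
        if rng.random() < 0.5:                       # horizontal
            x[i] = x[i, :, :, ::-1]
            gt_flow[i] = gt_flow[i, :, :, ::-1]
            gt_flow[i, 0] *= -1
            gt_seg[i] = gt_seg[i, :, ::-1]
        if rng.random() < 0.5:                       # vertical
            x[i] = x[i, :, ::-1]
            gt_flow[i] = gt_flow[i, :, ::-1]
            gt_flow[i, 1] *= -1
            gt_seg[i] = gt_seg[i, ::-1]
    return x, gt_flow, gt_seg


def train(model: FlowNet, records, cfg: TrainConfig, seed: int = 0,
          val_records=None, weights: LossWeights | None = None,
          log_every_epoch: bool = True):
    """Mini-batch Adam training; deterministic given ``seed``.

    ``records`` / ``val_records`` are RecordPair lists; the target is the
    tool-suppressed ``flow_simple``.  Returns a history dict with per-epoch
    train loss (and validation loss/EPE when a validation set is given).
    """
    if not records:
        raise ValueError("empty training set")
    if val_records is not None and len(val_records) == 0:
        val_records = None
    weights = weights or LossWeights()
    x, gt_flow, gt_seg = _records_to_arrays(records, model.dtype)
    opt = nn.Adam(model.params, beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(seed)
    history = {"train_loss": [], "val_loss": [], "val_epe": [], "lr": []}
    step = 0
    n = len(records)
    swa_sum, swa_n = None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0:b0 + cfg.batch_size]
            xb, fb, sb = x[idx], gt_flow[idx], gt_seg[idx]
            if cfg.augment_flips:
                xb, fb, sb = _flip_batch(xb, fb, sb, rng)
            preds = model.forward(xb)
            total, _ = multiscale_cost(preds, fb, sb,
                                       weights, model.params)
            opt.zero_grad()
            nn.backward(total)
            if cfg.grad_clip is not None:
                gnorm = np.sqrt(sum(float((p.grad ** 2).sum())
                                    for p in model.params.values()
                                    if p.grad is not None))
                if gnorm > cfg.grad_clip:
                    for p in model.params.values():
                        if p.grad is not None:
                            p.grad *= cfg.grad_clip / gnorm
            opt.step(learning_rate(cfg, step))
            step += 1
            losses.append(float(total.data))
        history["train_loss"].append(float(np.mean(losses)))
        history["lr"].append(learning_rate(cfg, step))
        if cfg.swa_fraction is not None and \
                epoch >= (1 - cfg.swa_fraction) * cfg.epochs:
            if swa_sum is None:
                swa_sum = {k: p.data.copy() for k, p in model.params.items()}
                swa_n = 1
            else:
                for k, p in model.params.items():
                    swa_sum[k] += p.data
                swa_n += 1
        if val_records is not None:
            vl, vepe = evaluate(model, val_records, weights)
            history["val_loss"].append(vl)
            history["val_epe"].append(vepe)
            if cfg.keep_best and vepe == min(history["val_epe"]):
                best = {k: p.data.copy() for k, p in model.params.items()}
    candidates = []
    if swa_sum is not None:
        candidates.append({k: swa_sum[k] / swa_n for k in swa_sum})
    if val_records is not None and cfg.keep_best:
        candidates.append(best)
    if candidates:
        if len(candidates) > 1:
            # model selection on the validation set
            scores = []
            for cand in candidates:
                for k, p in model.params.items():
                    p.data = cand[k]
                scores.append(evaluate(model, val_records, weights)[1])
            chosen = candidates[int(np.argmin(scores))]
        else:
            chosen = candidates[0]
        for k, p in model.params.items():
            p.data = chosen[k]
    return history


def evaluate(model: FlowNet, records, weights: LossWeights | None = None):
    """(mean cost, mean full-resolution EPE) on a record list."""
    weights = weights or LossWeights()
    x, gt_flow, gt_seg = _records_to_arrays(records, model.dtype)
    with nn.no_grad():
        preds = model.forward(x)
        total, _ = multiscale_cost(preds, gt_flow, gt_seg, weights,
                                   model.params)
        factor, flow, _ = preds[-1]
        full = nn.resize_bilinear(flow, gt_flow.shape[2:])
    diff = full.data * factor - gt_flow
    epe = float(np.sqrt((diff ** 2).sum(axis=1)).mean())
    return float(total.data), epe


def zero_flow_epe(records) -> float:
    """EPE of the trivial all-zero predictor: the mean GT displacement."""
    mags = [np.hypot(r.flow_simple[..., 0], r.flow_simple[..., 1]).mean()
            for r in records]
    return float(np.mean(mags))


def translation_smoke_benchmark(seed: int = 0, n_records: int = 200,
                                size=(48, 64), epochs: int = 30,
                                width: float = 0.25, levels: int = 4):
    """Desk-scale end-to-end training check on pure-translation records.

    Trains a reduced-width network for a fixed small budget on procedurally
    generated translation-only records and compares the held-out EPE with
    the zero-flow predictor (whose EPE equals the mean GT displacement).

    Returns a dict with ``val_epe``, ``zero_flow_epe`` and ``improvement``
    (fractional EPE reduction over the zero-flow baseline).
    """
    from .dataset_builder import sample_record, translation_subset_spec
    spec = translation_subset_spec(size=size, n_records=n_records, seed=seed)
    records = [sample_record(spec, i) for i in range(n_records)]
    n_val = max(1, n_records // 10)
    train_recs, val_recs = records[:-n_val], records[-n_val:]
    model = FlowNet(NetworkConfig(width_multiplier=width, levels=levels),
                    seed=seed)
    cfg = TrainConfig(epochs=epochs, batch_size=2, lr0=1e-3, grad_clip=2.0,
                      swa_fraction=0.3)
    history = train(model, train_recs, cfg, seed=seed, val_records=val_recs)
    _, val_epe = evaluate(model, val_recs)
    zf = zero_flow_epe(val_recs)
    return {"val_epe": val_epe, "zero_flow_epe": zf,
            "improvement": 1.0 - val_epe / zf, "history": history,
            "model": model}


def predict(model: FlowNet, frame1: np.ndarray, frame2: np.ndarray):
    """Full-resolution flow and binary FOV segmentation for a frame pair.

    Sizes not divisible by the network stride are padded reflectively and
    cropped back.
    """
    if frame1.shape != frame2.shape:
        raise ValueError("frames must have equal shapes")
    h, w = frame1.shape[:2]
    stride = 2 ** model.config.levels
    ph = (-h) % stride
    pw = (-w) % stride
    f1 = np.pad(frame1, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    f2 = np.pad(frame2, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    x = np.concatenate([f1, f2], axis=-1).transpose(2, 0, 1)[None]
    x = x.astype(model.dtype) / 255.0 - 0.5
    with nn.no_grad():
        preds = model.forward(x)
        factor, flow, seg = preds[-1]
        full = nn.resize_bilinear(flow, (h + ph, w + pw)).data[0] * factor
        if seg is not None:
            seg_full = nn.resize_bilinear(seg, (h + ph, w + pw)).data[0]
            seg_out = (seg_full[1] > seg_full[0]).astype(np.uint8)
        else:
            seg_out = np.ones((h + ph, w + pw), dtype=np.uint8)
    flow_out = full.transpose(1, 2, 0)[:h, :w].astype(np.float32)
    return flow_out, seg_out[:h, :w]
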
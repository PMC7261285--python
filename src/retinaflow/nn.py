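"""A minimal reverse-mode autodiff engine for convolutional networks.

Just enough machinery for an encoder-decoder flow network on the CPU:
tensors in NCHW layout, strided convolution via im2col + BLAS, bilinear
resampling as separable interpolation matrices, leaky ReLU, channel
concatenation, and the loss primitives (end-point-error, softmax
cross-entropy, total variation, L2 weight energy) with analytic gradients.
Gradient flow is recorded on a tape of parent links and replayed in reverse
topological order.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "parents", "bw", "requires_grad", "name")

    def __init__(self, data, parents=(), bw=None, requires_grad=True, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = parents if _GRAD_ENABLED else ()
        self.bw = bw if _GRAD_ENABLED else None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g


def backward(loss: Tensor):
    """Reverse-accumulate gradients from a scalar loss tensor."""
    order, seen = [], set()

    def topo(t):
        if id(t) in seen:
            return
        seen.add(id(t))
        for p in t.parents:
            topo(p)
        order.append(t)

    topo(loss)
    loss.grad = np.ones_like(loss.data)
    for t in reversed(order):
        if t.bw is not None and t.grad is not None:
            t.bw(t.grad)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


# ---------------------------------------------------------------------------
# Structural ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D cross-correlation; x (N,C,H,W), w (Cout,C,kh,kw), b (Cout,)."""
    xd = x.data
    n, c, h, wdt = xd.shape
    cout, cin, kh, kw = w.data.shape
    assert cin == c, (cin, c)
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (N,C,Ho,Wo,kh,kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wm = w.data.reshape(cout, -1)
    out = cols @ wm.T + b.data
    out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)

    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(out, parents=(x, w, b))

    def bw(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            w.accumulate((gcols.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x.parents:
            gc = (gcols @ wm).reshape(n, ho, wo, c, kh, kw)
            gc = gc.transpose(0, 3, 1, 2, 4, 5)   # (N,C,Ho,Wo,kh,kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += gc[..., i, j]
            gx = gxp[:, :, pad:pad + h, pad:pad + wdt] if pad else gxp
            x.accumulate(gx)

    res.bw = bw
    return res


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, slope * x.data)
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(out, parents=(x,))
    res.bw = lambda g: x.accumulate(np.where(pos, g, slope * g))
    return res


def concat(tensors, axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    if not _GRAD_ENABLED:
        return Tensor(out)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    res = Tensor(out, parents=tuple(tensors))

    def bw(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(o0, o1)
            t.accumulate(g[tuple(sl)])

    res.bw = bw
    return res


def _interp_matrix(n_out: int, n_in: int, dtype):
    """Sparse-as-dense separable bilinear interpolation matrix."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    a[np.arange(n_out), i0] += 1 - t
    a[np.arange(n_out), i1] += t
    return a


def resize_bilinear(x: Tensor, out_hw) -> Tensor:
    """Bilinearly resample (N,C,H,W) to a target spatial size."""
    n, c, h, w = x.data.shape
    h2, w2 = out_hw
    ah = _interp_matrix(h2, h, x.data.dtype)
    aw = _interp_matrix(w2, w, x.data.dtype)
    tmp = np.einsum("ij,ncjw->nciw", ah, x.data, optimize=True)
    out = np.einsum("kw,nciw->ncik", aw, tmp, optimize=True)
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(out, parents=(x,))

    def bw(g):
        gt = np.einsum("kw,ncik->nciw", aw, g, optimize=True)
        x.accumulate(np.einsum("ij,nciw->ncjw", ah, gt, optimize=True))

    res.bw = bw
    return res


def scale(x: Tensor, c: float) -> Tensor:
    out = x.data * c
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(out, parents=(x,))
    res.bw = lambda g: x.accumulate(g * c)
    return res


def add(x: Tensor, y: Tensor) -> Tensor:
    out = x.data + y.data
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(out, parents=(x, y))

    def bw(g):
        x.accumulate(g)
        y.accumulate(g)

    res.bw = bw
    return res


def add_scalars(tensors) -> Tensor:
    """Sum a list of scalar tensors into one scalar tensor."""
    out = np.sum([t.data for t in tensors], axis=0)
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(out, parents=tuple(tensors))

    def bw(g):
        for t in tensors:
            t.accumulate(g)

    res.bw = bw
    return res


# ---------------------------------------------------------------------------
# Loss primitives
# ---------------------------------------------------------------------------

def epe_sum(pred: Tensor, gt: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Sum over pixels of the Euclidean norm of (pred - gt) flow vectors."""
    diff = pred.data - gt
    norm = np.sqrt((diff ** 2).sum(axis=1) + eps)       # (N,H,W)
    out = norm.sum()
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(np.asarray(out, dtype=pred.data.dtype), parents=(pred,))
    res.bw = lambda g: pred.accumulate(g * diff / norm[:, None])
    return res


def softmax_ce_sum(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Sum over pixels of cross-entropy between softmax(logits) and one-hot."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sm = ez / ez.sum(axis=1, keepdims=True)
    logsm = z - np.log(ez.sum(axis=1, keepdims=True))
    out = -(onehot * logsm).sum()
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(np.asarray(out, dtype=logits.data.dtype), parents=(logits,))
    res.bw = lambda g: logits.accumulate(g * (sm - onehot))
    return res


def tv_sum(pred: Tensor, mask: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Masked sum of |df/dx + df/dy| (forward differences, vector norm)."""
    f = pred.data
    g_ = (f[:, :, :-1, 1:] + f[:, :, 1:, :-1] - 2 * f[:, :, :-1, :-1])
    mag = np.sqrt((g_ ** 2).sum(axis=1) + eps)          # (N,h-1,w-1)
    m = mask[:, :-1, :-1].astype(f.dtype)
    out = (m * mag).sum()
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(np.asarray(out, dtype=f.dtype), parents=(pred,))

    def bw(g):
        gm = g * (m / mag)[:, None] * g_
        df = np.zeros_like(f)
        df[:, :, :-1, 1:] += gm
        df[:, :, 1:, :-1] += gm
        df[:, :, :-1, :-1] -= 2 * gm
        pred.accumulate(df)

    res.bw = bw
    return res


def l2_energy(params) -> Tensor:
    """``1/2 * sum w^2`` over a list of parameter tensors."""
    out = 0.5 * np.sum([float((p.data ** 2).sum()) for p in params])
    if not _GRAD_ENABLED:
        return Tensor(out)
    res = Tensor(np.asarray(out, dtype=params[0].data.dtype),
                 parents=tuple(params))

    def bw(g):
        for p in params:
            if p.requires_grad:
                p.accumulate(g * p.data)

    res.bw = bw
    return res


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; hyper-parameters fixed at construction."""

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
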
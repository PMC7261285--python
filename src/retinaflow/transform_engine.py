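"""Flow-producing layer transforms and flow-free photometric degradations.

Each record of the simulator is an (original, transformed) pair of layer
stacks with a known dense flow between them.  Geometric transforms
(translation, rotation, scaling, pincushion distortion, injection
"bubbling", and a double-exposure modifier) produce closed-form flow
fields; a chain of them is composed into one total flow, the layer is
warped once by that flow, and photometric transforms (brightness, contrast,
blur) then modify colour only, leaving flow and opacity untouched.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from . import flowcore
from .flowcore import as_flow, compose_flows, invert_flow
from .layer_compositor import SceneLayer

FLOW_KINDS = {"translate", "rotate", "scale", "affine", "pincushion",
              "bubble", "double_exposure"}
PHOTO_KINDS = {"brightness_global", "brightness_local", "contrast", "blur"}


@dataclass
class TransformSpec:
    """One transform: a kind tag plus its numeric parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FLOW_KINDS | PHOTO_KINDS | {"degrade"}:
            raise ValueError(f"unknown transform kind {self.kind!r}")

    @property
    def affects_flow(self) -> bool:
        return self.kind in FLOW_KINDS


@dataclass
class TransformChain:
    """Ordered transforms applied to one layer (≤ 1 double exposure)."""

    specs: list[TransformSpec] = field(default_factory=list)

    def __post_init__(self):
        if sum(s.kind == "double_exposure" for s in self.specs) > 1:
            raise ValueError("at most one double_exposure per chain")

    def to_json(self) -> str:
        return json.dumps([{"kind": s.kind, "params": s.params}
                           for s in self.specs])

    @classmethod
    def from_json(cls, text: str) -> "TransformChain":
        return cls([TransformSpec(d["kind"], d["params"])
                    for d in json.loads(text)])


# ---------------------------------------------------------------------------
# Closed-form flow fields
# ---------------------------------------------------------------------------

def _affine_matrix(tx, ty, theta_deg, s, centre):
    """3x3 homogeneous matrix of rotate-scale about ``centre`` + translate."""
    th = math.radians(theta_deg)
    a = s * math.cos(th)
    b = s * math.sin(th)
    cx, cy = centre
    # p' = A (p - c) + c + t
    m = np.array([
        [a, -b, cx - a * cx + b * cy + tx],
        [b, a, cy - b * cx - a * cy + ty],
        [0.0, 0.0, 1.0],
    ])
    return m


def affine_flow(params, size, centre=None, dtype=np.float32) -> np.ndarray:
    """Flow of a rotation-scaling about ``centre`` plus translation.

    ``params`` is ``(tx, ty, theta_deg, s)``; ``centre`` defaults to the
    image centre.  ``f(p) = A (p - c) + c + t - p`` — closed form.  Pass
    ``dtype=np.float64`` to keep the full closed-form precision.
    """
    tx, ty, theta_deg, s = params
    if s <= 0:
        raise ValueError("scale must be positive")
    h, w = size
    if centre is None:
        centre = ((w - 1) / 2.0, (h - 1) / 2.0)
    m = _affine_matrix(tx, ty, theta_deg, s, centre)
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    fx = m[0, 0] * gx + m[0, 1] * gy + m[0, 2] - gx
    fy = m[1, 0] * gx + m[1, 1] * gy + m[1, 2] - gy
    return np.stack([fx, fy], axis=-1).astype(dtype)


def pincushion_flow(max_disp_px: float, size, centre=None) -> np.ndarray:
    """Radial cubic distortion: zero at the centre, ``max_disp_px`` at the
    farthest corner (the leading term of the standard radial lens model)."""
    h, w = size
    if centre is None:
        centre = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = centre
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = gx - cx, gy - cy
    r = np.hypot(dx, dy)
    corners = [math.hypot(c[0] - cx, c[1] - cy)
               for c in ((0, 0), (w - 1, 0), (0, h - 1), (w - 1, h - 1))]
    r_corner = max(corners)
    d = max_disp_px * (r / r_corner) ** 3
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / r, 0.0)
        uy = np.where(r > 0, dy / r, 0.0)
    return np.stack([d * ux, d * uy], axis=-1).astype(np.float32)


def bubble_flow(centre, radius: float, amplitude: float, size) -> np.ndarray:
    """Compact-support radial ripple emulating local bubbling.

    ``d(r) = amplitude * sin(pi r / radius) * exp(-(r/radius)^2)`` for
    ``r < radius`` and zero outside; continuous everywhere.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    h, w = size
    cx, cy = centre
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = gx - cx, gy - cy
    r = np.hypot(dx, dy)
    d = np.where(r < radius,
                 amplitude * np.sin(np.pi * r / radius) * np.exp(-(r / radius) ** 2),
                 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / r, 0.0)
        uy = np.where(r > 0, dy / r, 0.0)
    return np.stack([d * ux, d * uy], axis=-1).astype(np.float32)


def _spec_flow(spec: TransformSpec, size) -> np.ndarray:
    p = spec.params
    if spec.kind == "translate":
        return affine_flow((p["tx"], p["ty"], 0.0, 1.0), size)
    if spec.kind == "rotate":
        return affine_flow((0.0, 0.0, p["theta_deg"], 1.0), size,
                           centre=p.get("centre"))
    if spec.kind == "scale":
        return affine_flow((0.0, 0.0, 0.0, p["s"]), size,
                           centre=p.get("centre"))
    if spec.kind == "affine":
        return affine_flow((p["tx"], p["ty"], p["theta_deg"], p["s"]), size,
                           centre=p.get("centre"))
    if spec.kind == "pincushion":
        return pincushion_flow(p["max_disp_px"], size, centre=p.get("centre"))
    if spec.kind == "bubble":
        return bubble_flow(p["centre"], p["radius"], p["amplitude"], size)
    raise ValueError(f"{spec.kind} has no flow field")


def _spec_matrix(spec: TransformSpec, size):
    """Homogeneous matrix for affine-representable specs, else None."""
    h, w = size
    c0 = ((w - 1) / 2.0, (h - 1) / 2.0)
    p = spec.params
    if spec.kind == "translate":
        return _affine_matrix(p["tx"], p["ty"], 0.0, 1.0, c0)
    if spec.kind == "rotate":
        return _affine_matrix(0.0, 0.0, p["theta_deg"], 1.0, p.get("centre", c0))
    if spec.kind == "scale":
        if p["s"] <= 0:
            raise ValueError("scale must be positive")
        return _affine_matrix(0.0, 0.0, 0.0, p["s"], p.get("centre", c0))
    if spec.kind == "affine":
        return _affine_matrix(p["tx"], p["ty"], p["theta_deg"], p["s"],
                              p.get("centre", c0))
    return None


# ---------------------------------------------------------------------------
# Chain application
# ---------------------------------------------------------------------------

def chain_flow(chain: TransformChain, size):
    """Total forward flow of a chain plus the backward sampling map.

    Pure-affine chains are composed and inverted in closed form; chains
    containing radial transforms fall back to :func:`flowcore.compose_flows`
    and fixed-point inversion.

    Returns ``(flow, (bx, by))`` where ``(bx, by)`` are the frame-1
    coordinates from which each frame-2 pixel samples.
    """
    h, w = size
    flow_specs = [s for s in chain.specs if s.affects_flow
                  and s.kind != "double_exposure"]
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    if not flow_specs:
        zero = np.zeros((h, w, 2), np.float32)
        return zero, (gx, gy)

    mats = [_spec_matrix(s, size) for s in flow_specs]
    if all(m is not None for m in mats):
        total = np.eye(3)
        for m in mats:                      # applied in chain order
            total = m @ total
        fx = total[0, 0] * gx + total[0, 1] * gy + total[0, 2] - gx
        fy = total[1, 0] * gx + total[1, 1] * gy + total[1, 2] - gy
        flow = np.stack([fx, fy], axis=-1).astype(np.float32)
        inv = np.linalg.inv(total)
        bx = inv[0, 0] * gx + inv[0, 1] * gy + inv[0, 2]
        by = inv[1, 0] * gx + inv[1, 1] * gy + inv[1, 2]
        return flow, (bx, by)

    flow = _spec_flow(flow_specs[0], size)
    for spec in flow_specs[1:]:
        flow = compose_flows(flow, _spec_flow(spec, size))
    b = invert_flow(flow)
    return flow, (gx + b[..., 0], gy + b[..., 1])


def apply_chain(layer: SceneLayer, chain: TransformChain):
    """Warp a layer by its chain's total flow, then apply photometry.

    Returns ``(layer2, flow)``: the transformed layer (frame 2 side) and the
    forward flow from frame 1 to frame 2.  A double-exposure spec blends the
    warped and unwarped colour (ghosting from sudden eye motion) while the
    flow stays the full-motion flow.
    """
    size = layer.size
    flow, (bx, by) = chain_flow(chain, size)

    mode = "nearest" if layer.role in ("retina", "fov") else "constant"
    coords = np.stack([by, bx])

    def warp(arr):
        if arr.ndim == 2:
            return ndimage.map_coordinates(arr.astype(np.float64), coords,
                                           order=1, mode=mode).astype(np.float32)
        return np.stack([ndimage.map_coordinates(arr[..., c].astype(np.float64),
                                                 coords, order=1, mode=mode)
                         for c in range(arr.shape[2])], axis=-1).astype(np.float32)

    if any(s.affects_flow and s.kind != "double_exposure" for s in chain.specs):
        color = warp(layer.color)
        opacity = warp(layer.opacity)
    else:
        color = layer.color.copy()
        opacity = layer.opacity.copy()

    for spec in chain.specs:
        if spec.kind == "double_exposure":
            alpha = spec.params["alpha"]
            color = alpha * color + (1 - alpha) * layer.color
        elif spec.kind in PHOTO_KINDS:
            color = apply_photometric(color, spec)

    out = SceneLayer(color=color, opacity=np.clip(opacity, 0, 1),
                     role=layer.role, flow=flow)
    return out, flow


# ---------------------------------------------------------------------------
# Photometric transforms (no flow / segmentation impact)
# ---------------------------------------------------------------------------

def apply_photometric(frame: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Brightness/contrast/blur on colour only; output clipped to [0, 255]."""
    was_uint8 = frame.dtype == np.uint8
    img = frame.astype(np.float64)
    p = spec.params
    if spec.kind == "brightness_global":
        img = img + p["delta"]
    elif spec.kind == "brightness_local":
        h, w = img.shape[:2]
        gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
        r = np.hypot(gx - p["cx"], gy - p["cy"])
        # Smooth cosine feather inside the patch radius, zero outside.
        wgt = np.where(r < p["radius"],
                       0.5 * (1 + np.cos(np.pi * r / p["radius"])), 0.0)
        img = img + p["delta"] * wgt[..., None]
    elif spec.kind == "contrast":
        mean = img.mean(axis=(0, 1), keepdims=True)
        img = mean + p["factor"] * (img - mean)
    elif spec.kind == "blur":
        sigma = p["kernel_px"] / 4.0
        img = ndimage.gaussian_filter(img, (sigma, sigma, 0))
    else:
        raise ValueError(f"{spec.kind} is not photometric")
    img = np.clip(img, 0, 255)
    return np.round(img).astype(np.uint8) if was_uint8 else img.astype(np.float32)


def degrade(frame: np.ndarray, rng: np.random.Generator,
            noise_sigma: float | None = None,
            jpeg_quality: int | None = None) -> np.ndarray:
    """Sensor noise plus a JPEG encode/decode round trip.

    Mimics the camera noise and compression artefacts of real surgical
    video.  Defaults sample sigma from U[1, 5] intensity counts and quality
    from U{60..90}; deterministic for a seeded generator.
    """
    if noise_sigma is None:
        noise_sigma = float(rng.uniform(1.0, 5.0))
    if jpeg_quality is None:
        jpeg_quality = int(rng.integers(60, 91))
    img = frame.astype(np.float64)
    img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    buf = io.BytesIO()
    # chroma subsampling off at high quality so the round trip is faithful
    subsampling = 0 if jpeg_quality >= 95 else 2
    Image.fromarray(img).save(buf, format="JPEG", quality=int(jpeg_quality),
                              subsampling=subsampling)
    buf.seek(0)
    return np.asarray(Image.open(buf).convert("RGB"))
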
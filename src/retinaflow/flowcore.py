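"""Dense optical-flow primitives: the flow-field data model, Middlebury
``.flo`` I/O, backward warping, flow composition/inversion, multi-scale
down-sampling and the standard hue/saturation colour coding.

Conventions
-----------
A flow field is an ``(H, W, 2)`` float array of *forward* displacements in
pixels: a point at position ``p`` in frame 1 appears at ``p + f(p)`` in
frame 2.  Component order is ``(u, v) = (x, y)`` with x rightward and y
downward, 0-based pixel coordinates.  Images are ``(H, W, 3)`` uint8 arrays.
"""

from __future__ import annotations

import io
import os

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb

FLO_MAGIC = 202021.25


class FlowFormatError(ValueError):
    """Raised for a malformed .flo header."""


def as_flow(vectors: np.ndarray) -> np.ndarray:
    """Validate and return a flow field as float32 ``(H, W, 2)``."""
    arr = np.asarray(vectors, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError(f"flow must be (H, W, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("flow contains non-finite values")
    return arr


def as_image(pixels: np.ndarray) -> np.ndarray:
    """Validate an 8-bit colour frame."""
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"image must be (H, W, 3), got {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError("image must be at least 8x8")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("image values outside [0, 255]")
        arr = np.round(arr).astype(np.uint8)
    return arr


# ---------------------------------------------------------------------------
# Middlebury .flo I/O
# ---------------------------------------------------------------------------

def read_flo(path) -> np.ndarray:
    """Read a Middlebury ``.flo`` file into an ``(H, W, 2)`` float32 array."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 12:
        raise IOError(f"{path}: truncated .flo header")
    magic = np.frombuffer(data, dtype="<f4", count=1)[0]
    if magic != np.float32(FLO_MAGIC):
        raise FlowFormatError(f"{path}: bad magic {magic!r}, not a .flo file")
    width, height = np.frombuffer(data, dtype="<i4", count=2, offset=4)
    if width <= 0 or height <= 0:
        raise FlowFormatError(f"{path}: invalid dimensions {width}x{height}")
    expected = 12 + 8 * int(width) * int(height)
    if len(data) < expected:
        raise IOError(f"{path}: truncated payload ({len(data)} < {expected} bytes)")
    vec = np.frombuffer(data, dtype="<f4", count=2 * width * height, offset=12)
    return vec.reshape(int(height), int(width), 2).copy()


def write_flo(flow: np.ndarray, path) -> None:
    """Write a flow field as Middlebury ``.flo`` (bit-exact round trip)."""
    flow = as_flow(flow)
    h, w = flow.shape[:2]
    header = np.float32(FLO_MAGIC).tobytes() + np.array([w, h], "<i4").tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(flow.astype("<f4").tobytes())


# ---------------------------------------------------------------------------
# Sampling, warping, composition
# ---------------------------------------------------------------------------

def _grid(h: int, w: int):
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float32)
    return gx, gy


def bilinear_sample(field: np.ndarray, x: np.ndarray, y: np.ndarray,
                    mode: str = "constant", cval: float = 0.0) -> np.ndarray:
    """Bilinearly sample a (H, W) or (H, W, C) field at float positions."""
    field = np.asarray(field, dtype=np.float32)
    coords = np.stack([y, x])
    if field.ndim == 2:
        return ndimage.map_coordinates(field, coords, order=1, mode=mode,
                                       cval=cval).astype(np.float32)
    out = [ndimage.map_coordinates(field[..., c], coords, order=1, mode=mode,
                                   cval=cval) for c in range(field.shape[2])]
    return np.stack(out, axis=-1).astype(np.float32)


def warp_backward(frame2: np.ndarray, flow: np.ndarray, fill: float = 0.0):
    """Reconstruct frame 1 from frame 2 under a forward flow.

    The output pixel at ``p`` is ``frame2`` sampled bilinearly at
    ``p + f(p)``.  Samples falling outside ``frame2`` take ``fill``.

    Returns
    -------
    (warped, valid) : the warped frame (same dtype family as the input) and a
    boolean mask of in-bounds samples.
    """
    flow = as_flow(flow)
    frame2 = np.asarray(frame2)
    if frame2.shape[:2] != flow.shape[:2]:
        raise ValueError("frame and flow shapes differ")
    h, w = flow.shape[:2]
    gx, gy = _grid(h, w)
    sx = gx + flow[..., 0]
    sy = gy + flow[..., 1]
    valid = (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1)
    warped = bilinear_sample(frame2.astype(np.float32), sx, sy,
                             mode="constant", cval=fill)
    warped = np.where(valid[..., None] if warped.ndim == 3 else valid,
                      warped, np.float32(fill))
    if frame2.dtype == np.uint8:
        warped = np.clip(np.round(warped), 0, 255).astype(np.uint8)
    return warped, valid


def compose_flows(f_ab: np.ndarray, f_bc: np.ndarray) -> np.ndarray:
    """Compose two forward flows: ``f_ac(p) = f_ab(p) + f_bc(p + f_ab(p))``.

    Out-of-bounds samples of ``f_bc`` are extrapolated by the nearest edge
    value.
    """
    f_ab = as_flow(f_ab)
    f_bc = as_flow(f_bc)
    if f_ab.shape != f_bc.shape:
        raise ValueError("flow shapes differ")
    h, w = f_ab.shape[:2]
    gx, gy = _grid(h, w)
    sampled = bilinear_sample(f_bc, gx + f_ab[..., 0], gy + f_ab[..., 1],
                              mode="nearest")
    return f_ab + sampled


def invert_flow(flow: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Backward displacement ``b`` with ``q + b(q) = p`` where ``p + f(p) = q``.

    Fixed-point iteration ``b <- -f(q + b)``; converges for smooth flows with
    displacement gradients below 1 (all simulator transforms qualify).
    """
    flow = as_flow(flow)
    h, w = flow.shape[:2]
    gx, gy = _grid(h, w)
    b = -flow.copy()
    for _ in range(n_iter):
        b = -bilinear_sample(flow, gx + b[..., 0], gy + b[..., 1], mode="nearest")
    return b


# ---------------------------------------------------------------------------
# Multi-scale helpers
# ---------------------------------------------------------------------------

def downsample_flow(flow: np.ndarray, factor: int) -> np.ndarray:
    """Block-average pooling with magnitudes rescaled to coarse-grid units."""
    flow = as_flow(flow)
    factor = int(factor)
    if factor < 1 or (factor & (factor - 1)) != 0:
        raise ValueError(f"factor must be a positive power of two, got {factor}")
    if factor == 1:
        return flow.copy()
    h, w = flow.shape[:2]
    if h % factor or w % factor:
        raise ValueError(f"dimensions {h}x{w} not divisible by {factor}")
    pooled = flow.reshape(h // factor, factor, w // factor, factor, 2).mean(axis=(1, 3))
    return (pooled / factor).astype(np.float32)


def upsample_flow_nearest(flow: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour upsampling with magnitudes rescaled to fine units."""
    flow = as_flow(flow)
    up = np.repeat(np.repeat(flow, factor, axis=0), factor, axis=1)
    return (up * factor).astype(np.float32)


# ---------------------------------------------------------------------------
# Visualization and PNG helpers
# ---------------------------------------------------------------------------

def flow_to_color(flow: np.ndarray, max_mag: float) -> np.ndarray:
    """Colour-code a flow field: hue = direction, saturation = magnitude."""
    if max_mag <= 0:
        raise ValueError("max_mag must be positive")
    flow = as_flow(flow)
    mag = np.hypot(flow[..., 0], flow[..., 1])
    ang = np.arctan2(flow[..., 1], flow[..., 0])
    hsv = np.stack([
        (ang / (2 * np.pi)) % 1.0,
        np.clip(mag / max_mag, 0.0, 1.0),
        np.ones_like(mag),
    ], axis=-1)
    rgb = hsv2rgb(hsv)
    return np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)


def save_image(path, image: np.ndarray) -> None:
    import imageio.v3 as iio
    iio.imwrite(os.fspath(path), as_image(image))


def load_image(path) -> np.ndarray:
    import imageio.v3 as iio
    arr = iio.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return as_image(arr[..., :3])


def save_mask(path, mask: np.ndarray) -> None:
    """Store a {0,1} segmentation mask as an 8-bit {0,255} PNG."""
    import imageio.v3 as iio
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must contain only {0, 1}")
    iio.imwrite(os.fspath(path), (mask.astype(np.uint8) * 255))


def load_mask(path) -> np.ndarray:
    import imageio.v3 as iio
    arr = iio.imread(os.fspath(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr >= 128).astype(np.uint8)
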
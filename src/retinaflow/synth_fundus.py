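"""Procedural retinal-fundus textures and surgical-tool templates.

Intra-operative walk-through recordings are clinical data that cannot ship
with the package, so the bottom layer of the simulator is either a
user-supplied fundus frame (run through :func:`extract_retina_crop`) or a
procedural texture from :func:`generate_fundus`: a smooth red-orange
background, a brighter optic-disc blob and a tree of dark vessels grown by
branching random walks.  Tool templates (light pipe, vitrectomy cutter,
forceps) are likewise generated procedurally as elongated metallic shafts
with kind-specific tips.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb
from skimage.filters import threshold_otsu

from .flowcore import as_image


class ContentError(ValueError):
    """Raised when an input image has no usable retina region."""


@dataclass
class FundusParams:
    """Recipe for one procedural fundus texture."""

    seed: int = 0
    size: tuple[int, int] = (384, 512)          # (H, W) px
    vessel_count: int = 10
    vessel_width_range: tuple[float, float] = (1.5, 5.0)
    disc_radius: float = 0.12                   # fraction of H
    base_hue_range: tuple[float, float] = (0.015, 0.07)  # red-orange, HSV in [0,1]

    def __post_init__(self):
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        if not 0.0 < self.disc_radius < 0.5:
            raise ValueError("disc_radius must lie in (0, 0.5)")


@dataclass
class ToolTemplate:
    """A tool sprite: colour, opacity, functional tip and shaft centreline."""

    color: np.ndarray            # h x w x 3 uint8
    opacity: np.ndarray          # h x w float in [0, 1]
    kind: str                    # light_pipe | cutter | forceps
    tip: tuple[float, float]     # (x, y) px inside the support
    centreline: np.ndarray = field(repr=False, default=None)  # (N, 2) xy px

    def __post_init__(self):
        if self.kind not in ("light_pipe", "cutter", "forceps"):
            raise ValueError(f"unknown tool kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Fundus texture
# ---------------------------------------------------------------------------

def _smooth_noise(rng, h, w, sigma):
    n = rng.standard_normal((h, w))
    n = ndimage.gaussian_filter(n, sigma, mode="nearest")
    s = n.std()
    return n / s if s > 0 else n


def _fundus_fields(params: FundusParams):
    """Background RGB (float [0,1]) and the vessel-darkness field in [0,1]."""
    rng = np.random.default_rng(params.seed)
    h, w = params.size

    # Smooth red-orange background in HSV with a mild vignette.
    hue0 = rng.uniform(*params.base_hue_range)
    hue = np.clip(hue0 + 0.012 * _smooth_noise(rng, h, w, h / 5), 0.0, 0.12)
    sat = np.clip(0.82 + 0.08 * _smooth_noise(rng, h, w, h / 6), 0.55, 0.98)
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = w / 2, h / 2
    r = np.hypot((gx - cx) / w, (gy - cy) / h)
    val = 0.62 + 0.10 * _smooth_noise(rng, h, w, h / 4) - 0.25 * r ** 2
    val = np.clip(val, 0.25, 0.92)

    # Optic disc: a brighter, slightly desaturated elliptical blob.
    dr = params.disc_radius * h
    dcx = rng.uniform(0.25, 0.75) * w
    dcy = rng.uniform(0.3, 0.7) * h
    ecc = rng.uniform(0.75, 1.0)
    d2 = ((gx - dcx) / dr) ** 2 + ((gy - dcy) / (dr * ecc)) ** 2
    disc = np.exp(-d2 * 1.8)
    val = np.clip(val + 0.28 * disc, 0.0, 0.97)
    sat = np.clip(sat - 0.35 * disc, 0.15, 1.0)

    vessels = _vessel_field(rng, params, (dcx, dcy))
    bg = hsv2rgb(np.stack([hue, sat, val], axis=-1))
    return bg, vessels, (dcx, dcy)


def _vessel_field(rng, params: FundusParams, origin):
    """Darkness map in [0,1] built from branching random walks."""
    h, w = params.size
    dark = np.zeros((h, w), dtype=np.float64)
    wlo, whi = params.vessel_width_range
    max_r = int(np.ceil(whi / 2)) + 1
    gy, gx = np.mgrid[-max_r:max_r + 1, -max_r:max_r + 1]
    stamp_d = np.hypot(gx, gy)

    def stamp(x, y, width):
        r = max(width / 2, 0.6)
        xi, yi = int(round(x)), int(round(y))
        if xi < -max_r or yi < -max_r or xi >= w + max_r or yi >= h + max_r:
            return
        mask = np.clip(r + 0.5 - stamp_d, 0.0, 1.0)
        y0, y1 = yi - max_r, yi + max_r + 1
        x0, x1 = xi - max_r, xi + max_r + 1
        sy0, sx0 = max(0, -y0), max(0, -x0)
        ty0, tx0 = max(0, y0), max(0, x0)
        ty1, tx1 = min(h, y1), min(w, x1)
        if ty1 <= ty0 or tx1 <= tx0:
            return
        view = dark[ty0:ty1, tx0:tx1]
        np.maximum(view, mask[sy0:sy0 + ty1 - ty0, sx0:sx0 + tx1 - tx0],
                   out=view)

    def walk(x, y, angle, width, depth):
        step = 2.0
        n_steps = int(rng.integers(h // 3, int(h * 0.9)))
        for _ in range(n_steps):
            stamp(x, y, width)
            angle += rng.normal(0.0, 0.12)
            x += step * np.cos(angle)
            y += step * np.sin(angle)
            width *= 0.9975
            if width < 0.8 or not (-2 * max_r < x < w + 2 * max_r
                                   and -2 * max_r < y < h + 2 * max_r):
                break
            if depth < 2 and rng.random() < 0.015:
                walk(x, y, angle + rng.choice([-1, 1]) * rng.uniform(0.4, 0.9),
                     width * 0.65, depth + 1)

    ox, oy = origin
    for _ in range(params.vessel_count):
        a = rng.uniform(0, 2 * np.pi)
        w0 = rng.uniform(wlo, whi)
        walk(ox + rng.normal(0, 4), oy + rng.normal(0, 4), a, w0, 0)
    return np.clip(ndimage.gaussian_filter(dark, 0.6), 0.0, 1.0)


def generate_fundus(params: FundusParams) -> np.ndarray:
    """Render a procedural fundus texture, deterministic per seed."""
    bg, vessels, _ = _fundus_fields(params)
    # Vessels darken the background towards a dark red.
    vessel_rgb = bg * np.array([0.35, 0.2, 0.2])
    out = bg * (1 - vessels[..., None]) + vessel_rgb * vessels[..., None]
    return as_image(np.round(out * 255))


# ---------------------------------------------------------------------------
# Retina crop extraction for user-supplied frames
# ---------------------------------------------------------------------------

def largest_rectangle(mask: np.ndarray):
    """Largest all-True axis-aligned rectangle as ``(row, col, h, w)``.

    Histogram-stack algorithm, O(H*W).  Ties are broken by the first (i.e.
    topmost, then leftmost) maximal rectangle encountered.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    heights = np.zeros(w, dtype=np.int64)
    best = (0, 0, 0, 0)
    best_area = 0
    for row in range(h):
        heights = np.where(mask[row], heights + 1, 0)
        stack = []  # (start_col, height)
        for col in range(w + 1):
            cur = heights[col] if col < w else 0
            start = col
            while stack and stack[-1][1] >= cur:
                s, ht = stack.pop()
                area = ht * (col - s)
                if area > best_area:
                    best_area = area
                    best = (row - ht + 1, s, ht, col - s)
                start = s
            if cur > 0:
                stack.append((start, cur))
    return best


def extract_retina_crop(frame: np.ndarray, min_size: int = 64) -> np.ndarray:
    """Crop the largest rectangle of below-threshold (retina) brightness.

    Brightness is median-filtered with a 3 px kernel, thresholded with Otsu's
    method, and the largest axis-aligned rectangle inside the dark region is
    returned.  Raises :class:`ContentError` if it is smaller than
    ``min_size`` per side.
    """
    frame = as_image(frame)
    gray = frame.astype(np.float64).mean(axis=2)
    gray = ndimage.median_filter(gray, size=3)
    if gray.max() - gray.min() < 1.0:
        # Degenerate (uniform) image: dark counts as retina, bright does not.
        thr = 128.0
        mask = gray < thr
    else:
        thr = threshold_otsu(gray)
        mask = gray < thr
    row, col, rh, rw = largest_rectangle(mask)
    if rh < min_size or rw < min_size:
        raise ContentError(
            f"largest dark rectangle {rh}x{rw} is below {min_size}x{min_size}")
    return frame[row:row + rh, col:col + rw]


# ---------------------------------------------------------------------------
# Tool templates
# ---------------------------------------------------------------------------

def generate_tool_template(kind: str, seed: int = 0) -> ToolTemplate:
    """Procedural tool sprite with shaft along +x and the tip at the right.

    The shaft is an elongated, slightly tapered quadrilateral (length at
    least 4x width) with a kind-specific tip: rounded for the light pipe, a
    notched port for the cutter, twin prongs for the forceps.
    """
    if kind not in ("light_pipe", "cutter", "forceps"):
        raise ValueError(f"unknown tool kind {kind!r}")
    kind_id = {"light_pipe": 1, "cutter": 2, "forceps": 3}[kind]
    rng = np.random.default_rng([seed, kind_id])
    h, w = 96, 320
    shaft_w = rng.uniform(24.0, 32.0)
    length = rng.uniform(260.0, 290.0)
    x0 = 6.0
    tip_x = x0 + length
    slope = rng.uniform(-0.03, 0.03)
    taper = rng.uniform(0.7, 0.9)

    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    t = np.clip((gx - x0) / length, 0.0, 1.0)
    cy = h / 2 + slope * (gx - x0)
    width = shaft_w * (1 - (1 - taper) * t)
    dy = gy - cy
    body = (gx >= x0) & (gx <= tip_x) & (np.abs(dy) <= width / 2)

    if kind == "light_pipe":
        # Rounded cap past the tip.
        cap = ((gx - tip_x) ** 2 + (gy - (h / 2 + slope * length)) ** 2
               <= (shaft_w * taper / 2) ** 2)
        body |= cap
    elif kind == "cutter":
        # Side port: a rectangular notch cut out near the tip.
        notch = ((gx > tip_x - 36) & (gx < tip_x - 12)
                 & (dy < -width / 2 + width * 0.45))
        body &= ~notch
    else:  # forceps: carve a wedge gap so the end splits into two prongs.
        split_from = 0.72
        gap = (t > split_from) & (np.abs(dy) < width / 2
                                  * 0.55 * (t - split_from) / (1 - split_from))
        body &= ~gap

    opacity = ndimage.gaussian_filter(body.astype(np.float64), 0.7)
    opacity = np.clip(opacity * 1.2, 0.0, 1.0)

    # Metallic shading: bright specular stripe along the centreline, mild
    # axial falloff, slight blue-grey tint, fine grain.
    stripe = np.exp(-(dy / np.maximum(width / 4, 1e-6)) ** 2)
    base = 150 + 70 * stripe - 35 * t + 6 * rng.standard_normal((h, w))
    color = np.stack([base * 0.96, base * 0.98, base * 1.02], axis=-1)
    color = np.clip(color, 0, 255)

    n_cl = 64
    cl_x = np.linspace(x0, tip_x, n_cl)
    cl_y = h / 2 + slope * (cl_x - x0)
    centreline = np.stack([cl_x, cl_y], axis=-1)

    # Crop to the support bounding box with a small margin.
    ys, xs = np.nonzero(opacity > 0.01)
    m = 4
    y0c, y1c = max(0, ys.min() - m), min(h, ys.max() + m + 1)
    x0c, x1c = max(0, xs.min() - m), min(w, xs.max() + m + 1)
    tip = (float(tip_x - x0c), float(h / 2 + slope * length - y0c))
    centreline = centreline - np.array([x0c, y0c])
    return ToolTemplate(
        color=color[y0c:y1c, x0c:x1c].astype(np.uint8),
        opacity=opacity[y0c:y1c, x0c:x1c].astype(np.float32),
        kind=kind,
        tip=tip,
        centreline=centreline.astype(np.float32),
    )
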
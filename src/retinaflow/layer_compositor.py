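"""Scene layers and their compositing.

A simulated microscope frame is an alpha-over stack of three layer roles:
the retinal fundus at the bottom (fully opaque), zero or more tool groups in
the middle (tool shaft + cast shadow + glare), and the circular
field-of-view (FOV) vignette on top.  This module builds those layers —
including the full tool-appearance pipeline (scaling, perspective shaft
widening, rotation, tip placement, blur, HSV blending with the retina,
shadow, glare) — and merges a stack into a frame plus its FOV segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv, hsv2rgb

from .flowcore import as_image
from .synth_fundus import ToolTemplate

# Sampling intervals for the tool placement parameters.
SCALE_RANGE = (0.8, 1.5)
STRETCH_RANGE = (1.5, 3.0)
ROTATION_RANGE = (-80.0, 80.0)
TIP_X_RANGE_LIGHT_PIPE = (0.15, 0.5)
TIP_X_RANGE_OTHER = (0.4, 0.85)
TIP_Y_RANGE = (0.2, 0.8)
BLUR_KERNELS = (3, 5, 7)
SHADOW_OFFSET_RANGE = (0.0, 70.0)
SHADOW_ANGLE_RANGE = (-45.0, 45.0)
SHADOW_ALPHA_RANGE = (0.0, 0.5)
GLARE_COUNT_RANGE = (1, 5)
GLARE_RADIUS_RANGE = (2.0, 12.0)
GLARE_CREST_ALPHA_RANGE = (0.1, 0.6)
FOV_RADIUS_RANGE = (0.4, 0.8)      # fraction of H
FOV_CENTRE_RANGE = (0.4, 0.6)      # fraction of H and of W
FOV_EDGE_BLUR_PX = 15


class PlacementError(ValueError):
    """Raised when a tool placement pushes the whole support off-canvas."""


@dataclass
class SceneLayer:
    """One composable layer: colour (float, [0,255]), opacity and a role."""

    color: np.ndarray                 # H x W x 3 float32 in [0, 255]
    opacity: np.ndarray               # H x W float32 in [0, 1]
    role: str                         # retina | tool | fov
    flow: np.ndarray | None = None    # attached by the transform engine

    def __post_init__(self):
        if self.role not in ("retina", "tool", "fov"):
            raise ValueError(f"unknown layer role {self.role!r}")
        self.color = np.asarray(self.color, dtype=np.float32)
        self.opacity = np.asarray(self.opacity, dtype=np.float32)
        if self.color.shape[:2] != self.opacity.shape:
            raise ValueError("colour and opacity shapes differ")

    @property
    def size(self):
        return self.opacity.shape


@dataclass
class ToolPlacement:
    """Sampled appearance parameters for one tool instance."""

    scale: float
    stretch: float
    rotation_deg: float
    tip_x: float                      # fraction of W
    tip_y: float                      # fraction of H
    blur_kernel_px: int
    shadow_offset_px: float
    shadow_angle_deg: float
    shadow_alpha: float
    glare_n_ovals: int
    glare_radius_px: float
    glare_crest_alpha: float

    def to_dict(self):
        return asdict(self)


def sample_tool_placement(kind: str, rng: np.random.Generator) -> ToolPlacement:
    """Draw every placement parameter uniformly from its stated interval."""
    tip_x_range = TIP_X_RANGE_LIGHT_PIPE if kind == "light_pipe" else TIP_X_RANGE_OTHER
    return ToolPlacement(
        scale=float(rng.uniform(*SCALE_RANGE)),
        stretch=float(rng.uniform(*STRETCH_RANGE)),
        rotation_deg=float(rng.uniform(*ROTATION_RANGE)),
        tip_x=float(rng.uniform(*tip_x_range)),
        tip_y=float(rng.uniform(*TIP_Y_RANGE)),
        blur_kernel_px=int(rng.choice(BLUR_KERNELS)),
        shadow_offset_px=float(rng.uniform(*SHADOW_OFFSET_RANGE)),
        shadow_angle_deg=float(rng.uniform(*SHADOW_ANGLE_RANGE)),
        shadow_alpha=float(rng.uniform(*SHADOW_ALPHA_RANGE)),
        glare_n_ovals=int(rng.integers(GLARE_COUNT_RANGE[0], GLARE_COUNT_RANGE[1] + 1)),
        glare_radius_px=float(rng.uniform(*GLARE_RADIUS_RANGE)),
        glare_crest_alpha=float(rng.uniform(*GLARE_CREST_ALPHA_RANGE)),
    )


# ---------------------------------------------------------------------------
# Tool placement geometry
# ---------------------------------------------------------------------------

def place_tool(template: ToolTemplate, placement: ToolPlacement,
               size: tuple[int, int], apply_stretch: bool = True):
    """Geometrically place a template on a canvas (pre-blur, pre-colouring).

    The template is scaled, rotated and translated so its tip lands at the
    placement's tip position; the shaft is widened orthogonally to its axis,
    interpolating a factor of 1 where the shaft crosses the image centre up
    to the sampled stretch at the shaft point farthest from it (a flat-shaded
    stand-in for the 3-D pose of a tool pivoting at a scleral port).

    Returns ``(color, opacity, centreline_xy)`` on the canvas.
    """
    h, w = size
    s = placement.scale
    th = math.radians(placement.rotation_deg)
    ux, uy = math.cos(th), math.sin(th)
    tip_cx, tip_cy = placement.tip_x * w, placement.tip_y * h
    tip_tx, tip_ty = template.tip

    # Shaft endpoints on the canvas (tip and tail along -axis direction).
    shaft_len = s * float(np.hypot(*(template.centreline[-1] - template.centreline[0])))
    tail = (tip_cx - shaft_len * ux, tip_cy - shaft_len * uy)
    icx, icy = w / 2.0, h / 2.0

    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = gx - tip_cx, gy - tip_cy
    t = dx * ux + dy * uy                       # signed along-axis coordinate
    foot_x, foot_y = tip_cx + t * ux, tip_cy + t * uy
    if apply_stretch:
        # Distance of the axis foot point from the image centre, normalised by
        # the farthest shaft end.
        d = np.hypot(foot_x - icx, foot_y - icy)
        d_max = max(math.hypot(tip_cx - icx, tip_cy - icy),
                    math.hypot(tail[0] - icx, tail[1] - icy), 1e-6)
        k = 1.0 + (placement.stretch - 1.0) * np.clip(d / d_max, 0.0, 1.0)
    else:
        k = 1.0
    px = foot_x + (gx - foot_x) / k
    py = foot_y + (gy - foot_y) / k

    # Inverse rigid+scale map back to template coordinates.
    rx, ry = px - tip_cx, py - tip_cy
    qx = (rx * ux + ry * uy) / s + tip_tx
    qy = (-rx * uy + ry * ux) / s + tip_ty

    coords = np.stack([qy, qx])
    opacity = ndimage.map_coordinates(template.opacity.astype(np.float64),
                                      coords, order=1, mode="constant")
    color = np.stack([
        ndimage.map_coordinates(template.color[..., c].astype(np.float64),
                                coords, order=1, mode="constant")
        for c in range(3)], axis=-1)
    if opacity.max() < 0.5:
        raise PlacementError("tool support entirely off-canvas")

    cl = template.centreline.astype(np.float64) - np.array([tip_tx, tip_ty])
    clx = tip_cx + s * (cl[:, 0] * ux - cl[:, 1] * uy)
    cly = tip_cy + s * (cl[:, 0] * uy + cl[:, 1] * ux)
    centreline = np.stack([clx, cly], axis=-1)
    return (color.astype(np.float32), opacity.astype(np.float32),
            centreline.astype(np.float32))


def shadow_offset_vector(placement: ToolPlacement) -> tuple[int, int]:
    """Integer (dx, dy) shift of the cast shadow, angle measured from +x."""
    a = math.radians(placement.shadow_angle_deg)
    return (int(round(placement.shadow_offset_px * math.cos(a))),
            int(round(placement.shadow_offset_px * math.sin(a))))


def shift_support(opacity: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate a support map by an integer offset, zero-filled."""
    out = np.zeros_like(opacity)
    h, w = opacity.shape
    sy0, sy1 = max(0, -dy), min(h, h - dy)
    sx0, sx1 = max(0, -dx), min(w, w - dx)
    if sy1 > sy0 and sx1 > sx0:
        out[sy0 + dy:sy1 + dy, sx0 + dx:sx1 + dx] = opacity[sy0:sy1, sx0:sx1]
    return out


def mean_retina_hsv(retina: SceneLayer):
    """(circular-mean hue, mean saturation, mean value) of the retina layer."""
    hsv = rgb2hsv(np.clip(retina.color, 0, 255) / 255.0)
    ang = hsv[..., 0] * 2 * np.pi
    hue = (math.atan2(float(np.sin(ang).mean()), float(np.cos(ang).mean()))
           / (2 * np.pi)) % 1.0
    return hue, float(hsv[..., 1].mean()), float(hsv[..., 2].mean())


def make_tool_layer(template: ToolTemplate, placement: ToolPlacement,
                    retina: SceneLayer, rng: np.random.Generator,
                    hsv_match: bool = True, with_shadow: bool = True,
                    with_glare: bool = True):
    """Build the tool layer group for one placed tool.

    Returns ``(tool, shadow, glare)`` scene layers (shadow/glare may have
    zero opacity when disabled).  The tool colour is re-hued to the retina's
    circular-mean hue and mean saturation, with its value rescaled to a
    random level between black and the retina's mean value — mimicking the
    retina reflecting off the metallic shaft.
    """
    size = retina.size
    color, opacity, centreline = place_tool(template, placement, size)

    # Shadow support: the *pre-blur* tool support translated by the offset.
    dx, dy = shadow_offset_vector(placement)
    shadow_op = shift_support(opacity, dx, dy) * placement.shadow_alpha
    if not with_shadow:
        shadow_op = np.zeros_like(shadow_op)

    sigma = placement.blur_kernel_px / 4.0
    color = ndimage.gaussian_filter(color, (sigma, sigma, 0))
    opacity = ndimage.gaussian_filter(opacity, sigma)
    shadow_op = ndimage.gaussian_filter(shadow_op, sigma)

    if hsv_match:
        mh, ms, mv = mean_retina_hsv(retina)
        hsv = rgb2hsv(np.clip(color, 0, 255) / 255.0)
        hsv[..., 0] = mh
        hsv[..., 1] = ms
        support = opacity > 0.05
        cur = float(hsv[..., 2][support].mean()) if support.any() else 1.0
        target = float(rng.uniform(0.0, mv))
        hsv[..., 2] = np.clip(hsv[..., 2] * (target / max(cur, 1e-6)), 0.0, 1.0)
        color = (hsv2rgb(hsv) * 255.0).astype(np.float32)

    tool = SceneLayer(color=color, opacity=opacity, role="tool")
    shadow = SceneLayer(color=np.zeros(size + (3,), np.float32),
                        opacity=shadow_op, role="tool")
    glare = _glare_overlay(size, centreline, placement, rng) if with_glare \
        else SceneLayer(color=np.zeros(size + (3,), np.float32),
                        opacity=np.zeros(size, np.float32), role="tool")
    return tool, shadow, glare


def _glare_overlay(size, centreline, placement: ToolPlacement,
                   rng: np.random.Generator) -> SceneLayer:
    """White faded ovals along the shaft centreline with coloured crests."""
    h, w = size
    n = placement.glare_n_ovals
    r = placement.glare_radius_px
    # Equal arc-length spacing along the centreline polyline.
    seg = np.diff(centreline, axis=0)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    total = arclen[-1]
    targets = (np.arange(1, n + 1) / (n + 1)) * total
    centres = np.stack([np.interp(targets, arclen, centreline[:, 0]),
                        np.interp(targets, arclen, centreline[:, 1])], axis=-1)

    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    op = np.zeros((h, w))
    color = np.zeros((h, w, 3))
    axis = centreline[-1] - centreline[0]
    ax = axis / max(np.hypot(*axis), 1e-6)
    for cx, cy in centres:
        if not (-2 * r < cx < w + 2 * r and -2 * r < cy < h + 2 * r):
            continue
        dx, dy = gx - cx, gy - cy
        # Oval: elongated 1.6:1 along the shaft axis.
        a_ = dx * ax[0] + dy * ax[1]
        b_ = -dx * ax[1] + dy * ax[0]
        d = np.hypot(a_ / 1.6, b_)
        blob = np.exp(-(d / (r / 1.6)) ** 2)
        np.maximum(op, blob, out=op)
        # Crests: thin outline at the oval border, yellow on one side of the
        # axis, blue on the other, at the sampled crest transparency.
        ring = (d > r) & (d < r + 1.5)
        yellow, blue = ring & (b_ <= 0), ring & (b_ > 0)
        crest = placement.glare_crest_alpha
        color[yellow] = (255, 225, 60)
        color[blue] = (70, 110, 255)
        op[yellow & (op < crest)] = crest
        op[blue & (op < crest)] = crest
    white = op[..., None] >= placement.glare_crest_alpha
    color = np.where((color.sum(-1, keepdims=True) == 0) | white, 255.0, color)
    return SceneLayer(color=color.astype(np.float32),
                      opacity=np.clip(op, 0, 1).astype(np.float32), role="tool")


# ---------------------------------------------------------------------------
# Field-of-view layer and compositing
# ---------------------------------------------------------------------------

def make_fov_layer(size: tuple[int, int], rng: np.random.Generator,
                   edge_blur_px: int = FOV_EDGE_BLUR_PX) -> SceneLayer:
    """Black vignette with a circular transparent hole of blurred edge."""
    h, w = size
    radius = float(rng.uniform(*FOV_RADIUS_RANGE)) * h
    cy = float(rng.uniform(*FOV_CENTRE_RANGE)) * h
    cx = float(rng.uniform(*FOV_CENTRE_RANGE)) * w
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    opacity = (np.hypot(gx - cx, gy - cy) > radius).astype(np.float64)
    opacity = ndimage.gaussian_filter(opacity, edge_blur_px / 4.0)
    layer = SceneLayer(color=np.zeros((h, w, 3), np.float32),
                       opacity=np.clip(opacity, 0, 1).astype(np.float32),
                       role="fov")
    layer.meta = {"radius": radius, "cx": cx, "cy": cy}
    return layer


def composite_stack(layers: list[SceneLayer]):
    """Alpha-over merge of a bottom-to-top layer stack.

    Returns ``(frame, seg)``: the uint8 composite and the FOV segmentation
    (1 inside the field of view — tool coverage does not change it).  With no
    FOV layer the segmentation is all ones.
    """
    if not layers:
        raise ValueError("empty layer stack")
    size = layers[0].size
    roles = [l.role for l in layers]
    if any(l.size != size for l in layers):
        raise ValueError("layer sizes differ")
    if roles.count("retina") > 1 or roles.count("fov") > 1:
        raise ValueError("at most one retina and one fov layer")
    if "retina" in roles and roles[0] != "retina":
        raise ValueError("retina layer must be at the bottom")
    if "fov" in roles and roles[-1] != "fov":
        raise ValueError("fov layer must be on top")

    out = np.zeros(size + (3,), dtype=np.float64)
    for layer in layers:
        a = layer.opacity[..., None].astype(np.float64)
        out = layer.color.astype(np.float64) * a + out * (1 - a)

    if "fov" in roles:
        fov = layers[roles.index("fov")]
        seg = (fov.opacity < 0.5).astype(np.uint8)
    else:
        seg = np.ones(size, dtype=np.uint8)
    return as_image(np.clip(out, 0, 255)), seg
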
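"""Point-tracking evaluation: s-EPE, l-EPE and the grid-loop metric.

Points are tracked by integrating dense flow: ``p <- p + f_t(p)`` with
bilinear sampling at each frame step.  Errors are reported as

* **s-EPE** — mean end-point error over every 11-frame fragment (tracked in
  both directions, re-seeded from the annotation at the fragment start);
* **l-EPE** — end-point error at the final frame of the full sequence;
* **grid EPE** — every in-FOV pixel of frame 1 is tracked forward through
  the odd frames and back through the even frames; the distance between a
  vertex's final and initial position measures loop consistency, which an
  invertible-but-wrong estimator cannot fake to zero.

A synthetic clip generator provides temporally coherent sequences with
exact closed-form ground truth (and an optional occluding tool sweep), so
the evaluator — and trained models — can be exercised without clinical
recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flowcore import as_flow, bilinear_sample
from .synth_fundus import FundusParams, generate_fundus, generate_tool_template
from .layer_compositor import SceneLayer
from .transform_engine import _affine_matrix

ANNOTATION_STRIDE = 10


@dataclass
class FlowSequence:
    """Per-frame-pair forward flows for a clip (optionally backward too)."""

    flows: list                       # F-1 arrays (H, W, 2), frame t -> t+1
    flows_backward: list | None = None
    fov_masks: dict = field(default_factory=dict)   # frame index -> (H, W)

    def __post_init__(self):
        if len(self.flows) < 1:
            raise ValueError("a flow sequence needs at least one field")

    @property
    def n_frames(self):
        return len(self.flows) + 1

    @property
    def shape(self):
        return self.flows[0].shape[:2]


@dataclass
class Trajectory:
    """Tracked positions of one point with per-frame validity flags."""

    point_id: int
    positions: np.ndarray             # (F, 2) xy px
    valid: np.ndarray                 # (F,) bool


@dataclass
class TrackReport:
    s_epe_mean: float
    s_epe_sd: float
    l_epe_mean: float
    l_epe_sd: float
    grid_epe_mean: float
    grid_epe_sd: float

    def to_dict(self):
        return {k: float(v) for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# Flow integration
# ---------------------------------------------------------------------------

def _step(points: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Advance (M, 2) points by one bilinearly sampled flow field."""
    fx = bilinear_sample(flow[..., 0], points[:, 0], points[:, 1], mode="nearest")
    fy = bilinear_sample(flow[..., 1], points[:, 0], points[:, 1], mode="nearest")
    return points + np.stack([fx, fy], axis=-1)


def _inside(points, shape):
    h, w = shape
    return ((points[:, 0] >= 0) & (points[:, 0] <= w - 1)
            & (points[:, 1] >= 0) & (points[:, 1] <= h - 1))


def track_points(seq: FlowSequence, starts, direction: str = "forward"):
    """Track points through every frame of a sequence.

    ``direction='backward'`` uses the backward flow fields and runs from the
    last frame to the first.  A point that leaves the frame (or the FOV mask
    at an annotated frame) is flagged invalid from that frame on.

    Returns a list of :class:`Trajectory` (positions indexed by frame,
    chronological order regardless of direction).
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=np.float64))
    f = seq.n_frames
    h, w = seq.shape
    if direction == "forward":
        flows = seq.flows
        frame_order = range(f)
    elif direction == "backward":
        if seq.flows_backward is None:
            raise ValueError("sequence has no backward flows")
        flows = seq.flows_backward
        frame_order = range(f - 1, -1, -1)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    positions = np.zeros((f, len(starts), 2))
    valid = np.ones((f, len(starts)), dtype=bool)
    pts = starts.copy()
    alive = _inside(pts, (h, w))
    for i, t in enumerate(frame_order):
        positions[t] = pts
        if t in seq.fov_masks:
            m = seq.fov_masks[t]
            iy = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
            ix = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
            alive &= m[iy, ix] > 0
        valid[t] = alive
        if i < f - 1:
            step_flow = flows[t] if direction == "forward" else flows[t - 1]
            pts = _step(pts, step_flow)
            alive = alive & _inside(pts, (h, w))
    # once invalid, stay invalid (in chronological tracking order)
    order = list(frame_order)
    for i in range(1, f):
        valid[order[i]] &= valid[order[i - 1]]
    return [Trajectory(point_id=i, positions=positions[:, i], valid=valid[:, i])
            for i in range(len(starts))]


# ---------------------------------------------------------------------------
# Sequence EPE (short / long)
# ---------------------------------------------------------------------------

def sequence_epe(seq: FlowSequence, annotations: np.ndarray):
    """Short- and long-sequence end-point errors against sparse annotations.

    ``annotations`` has shape (A, P, 2): positions of P points at frames
    ``0, 10, 20, ...``.  Each 11-frame fragment is tracked from its start
    annotation to its end annotation, in both directions when backward
    flows are available; errors of invalid points are excluded.

    Returns ``(s_epe, l_epe, s_errors, l_errors)``; the means are NaN when
    no fragment is valid.
    """
    ann = np.asarray(annotations, dtype=np.float64)
    if ann.ndim != 3 or ann.shape[2] != 2:
        raise ValueError("annotations must be (A, P, 2)")
    n_ann = ann.shape[0]
    expected = (seq.n_frames - 1) // ANNOTATION_STRIDE + 1
    if n_ann != expected:
        raise ValueError(f"expected {expected} annotation frames, got {n_ann}")

    directions = ["forward"]
    if seq.flows_backward is not None:
        directions.append("backward")

    s_errors = []
    for a in range(n_ann - 1):
        t0, t1 = a * ANNOTATION_STRIDE, (a + 1) * ANNOTATION_STRIDE
        frag_f = FlowSequence(flows=seq.flows[t0:t1],
                              flows_backward=None, fov_masks={})
        trajs = track_points(frag_f, ann[a])
        for tr, gt in zip(trajs, ann[a + 1]):
            if tr.valid[-1]:
                s_errors.append(float(np.hypot(*(tr.positions[-1] - gt))))
        if "backward" in directions:
            frag_b = FlowSequence(flows=[np.zeros_like(f) for f in seq.flows[t0:t1]],
                                  flows_backward=seq.flows_backward[t0:t1],
                                  fov_masks={})
            trajs = track_points(frag_b, ann[a + 1], direction="backward")
            for tr, gt in zip(trajs, ann[a]):
                if tr.valid[0]:
                    s_errors.append(float(np.hypot(*(tr.positions[0] - gt))))

    l_errors = []
    trajs = track_points(seq, ann[0])
    for tr, gt in zip(trajs, ann[-1]):
        if tr.valid[-1]:
            l_errors.append(float(np.hypot(*(tr.positions[-1] - gt))))
    if "backward" in directions:
        trajs = track_points(seq, ann[-1], direction="backward")
        for tr, gt in zip(trajs, ann[0]):
            if tr.valid[0]:
                l_errors.append(float(np.hypot(*(tr.positions[0] - gt))))

    s_epe = float(np.mean(s_errors)) if s_errors else float("nan")
    l_epe = float(np.mean(l_errors)) if l_errors else float("nan")
    return s_epe, l_epe, np.asarray(s_errors), np.asarray(l_errors)


# ---------------------------------------------------------------------------
# Grid-loop metric
# ---------------------------------------------------------------------------

def grid_loop_epe(seq_odd: FlowSequence, seq_even: FlowSequence,
                  fov: np.ndarray):
    """Track every in-FOV pixel out through one leg and back through the
    other; returns ``(mean, sd, per_vertex_errors)`` over vertices that stay
    valid for the whole loop."""
    fov = np.asarray(fov)
    if fov.sum() == 0:
        raise ValueError("empty FOV mask")
    h, w = fov.shape
    ys, xs = np.nonzero(fov > 0)
    pts = np.stack([xs, ys], axis=-1).astype(np.float64)
    start = pts.copy()
    alive = np.ones(len(pts), dtype=bool)
    for flow in seq_odd.flows:
        pts = _step(pts, flow)
        alive &= _inside(pts, (h, w))
    for flow in seq_even.flows:
        pts = _step(pts, flow)
        alive &= _inside(pts, (h, w))
    err = np.hypot(*(pts - start).T)[alive]
    if err.size == 0:
        raise ValueError("no vertex survived the loop")
    return float(err.mean()), float(err.std()), err


# ---------------------------------------------------------------------------
# Synthetic benchmark clips
# ---------------------------------------------------------------------------

def _motion_matrices(n_frames, size, rng, max_translation=8.0,
                     max_rotation_deg=3.0, max_scale_dev=0.04):
    """Smooth sinusoidal camera motion: a 3x3 map per frame (frame 0 = id)."""
    h, w = size
    centre = ((w - 1) / 2, (h - 1) / 2)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    periods = rng.uniform(0.6, 1.4, size=4) * n_frames
    mats = []
    for t in range(n_frames):
        tx = max_translation * np.sin(2 * np.pi * t / periods[0] + phases[0])
        ty = max_translation * np.sin(2 * np.pi * t / periods[1] + phases[1])
        th = max_rotation_deg * np.sin(2 * np.pi * t / periods[2] + phases[2])
        s = 1 + max_scale_dev * np.sin(2 * np.pi * t / periods[3] + phases[3])
        mats.append(_affine_matrix(tx, ty, th, s, centre))
    mats[0] = np.eye(3)
    return mats


def _pair_flow(m_a, m_b, size):
    """Closed-form flow between two frames given their motion matrices."""
    h, w = size
    m = m_b @ np.linalg.inv(m_a)
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    fx = m[0, 0] * gx + m[0, 1] * gy + m[0, 2] - gx
    fy = m[1, 0] * gx + m[1, 1] * gy + m[1, 2] - gy
    return np.stack([fx, fy], axis=-1).astype(np.float32)


def _render_frame(base, m, size):
    from scipy import ndimage
    h, w = size
    inv = np.linalg.inv(m)
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    qx = inv[0, 0] * gx + inv[0, 1] * gy + inv[0, 2]
    qy = inv[1, 0] * gx + inv[1, 1] * gy + inv[1, 2]
    out = np.stack([ndimage.map_coordinates(base[..., c].astype(np.float64),
                                            [qy, qx], order=1, mode="nearest")
                    for c in range(3)], axis=-1)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _pick_annotation_points(frame, fov, n_points, rng, margin=12):
    """High-gradient, well-separated in-FOV points (vessel-like features)."""
    from scipy import ndimage
    gray = frame.astype(np.float64).mean(axis=2)
    gx = ndimage.sobel(gray, axis=1)
    gy = ndimage.sobel(gray, axis=0)
    mag = np.hypot(gx, gy)
    h, w = gray.shape
    mag[:margin] = mag[-margin:] = 0
    mag[:, :margin] = 0
    mag[:, -margin:] = 0
    mag[fov == 0] = 0
    pts = []
    work = mag.copy()
    min_sep = max(h, w) // 8
    while len(pts) < n_points and work.max() > 0:
        iy, ix = np.unravel_index(np.argmax(work), work.shape)
        pts.append((float(ix), float(iy)))
        y0, y1 = max(0, iy - min_sep), min(h, iy + min_sep)
        x0, x1 = max(0, ix - min_sep), min(w, ix + min_sep)
        work[y0:y1, x0:x1] = 0
    while len(pts) < n_points:
        pts.append((w / 2 + rng.uniform(-5, 5), h / 2 + rng.uniform(-5, 5)))
    return np.asarray(pts)


def make_synthetic_clip(n_frames: int = 21, size=(96, 128),
                        with_tool: bool = False, seed: int = 0,
                        n_points: int = 4, motion_kwargs: dict | None = None):
    """Temporally coherent clip with exact ground truth.

    Returns a dict with frames, the retina-motion (inpainted) flow sequence
    including backward flows, a full-motion flow sequence where a sweeping
    tool overrides the retina flow (equal to the retina flows when
    ``with_tool`` is false), annotations every 10 frames, the FOV mask, and
    the odd/even leg flow sequences for grid-loop evaluation.
    """
    if n_frames < 11 or n_frames % 2 == 0:
        raise ValueError("n_frames must be odd and >= 11")
    h, w = size
    rng = np.random.default_rng(seed)
    base = generate_fundus(FundusParams(seed=int(rng.integers(2 ** 31)),
                                        size=size, vessel_count=8))
    mats = _motion_matrices(n_frames, size, rng, **(motion_kwargs or {}))

    # Static circular FOV fully inside the frame.
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    radius = 0.46 * h
    fov = (np.hypot(gx - w / 2, gy - h / 2) <= radius).astype(np.uint8)

    frames = [_render_frame(base, m, size) for m in mats]
    flows_f = [_pair_flow(mats[t], mats[t + 1], size)
               for t in range(n_frames - 1)]
    flows_b = [_pair_flow(mats[t + 1], mats[t], size)
               for t in range(n_frames - 1)]

    ann_frames = list(range(0, n_frames, ANNOTATION_STRIDE))
    p0 = _pick_annotation_points(frames[0], fov, n_points, rng)
    hom = np.concatenate([p0, np.ones((len(p0), 1))], axis=1).T
    annotations = np.stack([(mats[t] @ hom)[:2].T for t in ann_frames])

    full_f = [f.copy() for f in flows_f]
    tool_masks = None
    if with_tool:
        tmpl = generate_tool_template("cutter", seed=int(rng.integers(2 ** 31)))
        # Sweep the tool tip through the first annotated point mid-clip.
        # The amplitude is capped so that a point dragged along by the
        # full-motion flow stays inside the frame (and in the statistics).
        target = annotations[len(ann_frames) // 2 if len(ann_frames) > 2 else 1][0]
        amp = float(np.clip(min(0.35 * w, target[0] - 4, w - 5 - target[0]),
                            6.0, None))
        sweep = np.linspace(-amp, amp, n_frames)
        tool_masks = []
        sc = 0.35 * h / tmpl.opacity.shape[0]
        for t in range(n_frames):
            cx = target[0] + sweep[t]
            cy = target[1]
            mask = _stamp_tool_mask(tmpl, (cx, cy), sc, size)
            tool_masks.append(mask)
        # Tool motion: horizontal sweep speed, overriding retina flow.
        for t in range(n_frames - 1):
            dm = sweep[t + 1] - sweep[t]
            m = tool_masks[t] > 0.5
            full_f[t][m] = np.array([dm, 0.0], dtype=np.float32)
            frames[t] = _paint_tool(frames[t], tmpl, tool_masks[t])
        frames[-1] = _paint_tool(frames[-1], tmpl, tool_masks[-1])

    fov_masks = {t: fov for t in ann_frames}
    gt_seq = FlowSequence(flows=flows_f, flows_backward=flows_b,
                          fov_masks=fov_masks)
    full_seq = FlowSequence(flows=full_f, flows_backward=flows_b,
                            fov_masks=fov_masks)

    odd = list(range(0, n_frames, 2))
    even_back = list(range(n_frames - 1, -1, -1))
    even_back = [t for t in even_back if t % 2 == 1 or t in (n_frames - 1, 0)]
    seq_odd = FlowSequence(flows=[_pair_flow(mats[a], mats[b], size)
                                  for a, b in zip(odd[:-1], odd[1:])])
    seq_even = FlowSequence(flows=[_pair_flow(mats[a], mats[b], size)
                                   for a, b in zip(even_back[:-1], even_back[1:])])

    return {"frames": frames, "gt": gt_seq, "full": full_seq,
            "annotations": annotations, "fov": fov, "motion": mats,
            "seq_odd": seq_odd, "seq_even": seq_even,
            "tool_masks": tool_masks}


def _stamp_tool_mask(tmpl, tip_xy, scale, size):
    from scipy import ndimage
    h, w = size
    th, tw = tmpl.opacity.shape
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    qx = (gx - tip_xy[0]) / scale + tmpl.tip[0]
    qy = (gy - tip_xy[1]) / scale + tmpl.tip[1]
    return ndimage.map_coordinates(tmpl.opacity.astype(np.float64),
                                   [qy, qx], order=1, mode="constant")


def _paint_tool(frame, tmpl, mask):
    out = frame.astype(np.float64)
    grey = np.array([120.0, 120.0, 130.0])
    out = out * (1 - mask[..., None]) + grey * mask[..., None]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def evaluate_clip(clip: dict, flow_source: str = "gt") -> TrackReport:
    """Full report (s-EPE, l-EPE, grid EPE) for one synthetic clip using its
    stored ground-truth (``'gt'``) or full-motion (``'full'``) flows."""
    seq = clip[flow_source]
    s_epe, l_epe, s_err, l_err = sequence_epe(seq, clip["annotations"])
    g_mean, g_sd, _ = grid_loop_epe(clip["seq_odd"], clip["seq_even"],
                                    clip["fov"])
    return TrackReport(
        s_epe_mean=s_epe, s_epe_sd=float(s_err.std()) if s_err.size else 0.0,
        l_epe_mean=l_epe, l_epe_sd=float(l_err.std()) if l_err.size else 0.0,
        grid_epe_mean=g_mean, grid_epe_sd=g_sd)
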
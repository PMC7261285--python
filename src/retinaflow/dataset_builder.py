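"""Assembly of full training records and the 16-subset dataset recipe.

A record is an image pair with dense ground-truth flow, derived from known
per-layer transforms: ``flow_full`` contains every layer's motion (topmost
opaque layer wins per pixel) while ``flow_simple`` — the training target —
keeps the *retina* flow under tools and shadows and zeroes flow outside the
field of view.  A network trained on ``flow_simple`` therefore learns to
inpaint retinal motion through occlusions.

The default recipe builds 16 subsets of 2000 records (32 000 pairs) at
512x384 px: five retina-only subsets (translation, rotation, scaling,
pincushion, bubbling), five retina+FOV subsets, and six subsets with one or
two tools.  Variants ``nl`` (no shadows/glare/HSV matching) and ``nl_nb``
(additionally no brightness changes) realise the two ablation datasets.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import flowcore
from .flowcore import save_image, save_mask, write_flo
from .synth_fundus import FundusParams, generate_fundus, generate_tool_template
from .layer_compositor import (SceneLayer, composite_stack, make_fov_layer,
                               make_tool_layer, sample_tool_placement,
                               PlacementError)
from .transform_engine import (TransformChain, TransformSpec, apply_chain,
                               degrade)

# Per-frame transform parameter intervals of the main recipe.
TRANSLATION_MAX_PX = 10.0
ROTATION_RANGE_DEG = (-5.0, 5.0)
SCALING_RANGE = (0.9, 1.1)
PINCUSHION_RANGE_PX = (10.0, 50.0)
BUBBLE_CENTRE_RANGE = (0.2, 0.8)       # fraction of H and W
BUBBLE_RADIUS_RANGE = (0.15, 0.3)      # fraction of H
BUBBLE_AMPLITUDE_RANGE = (2.0, 10.0)   # px
BLUR_PROB = 0.10
BLUR_MAX_KERNEL_PX = 5
GLOBAL_BRIGHTNESS_PROB = 0.25
GLOBAL_BRIGHTNESS_MAX = 15.0
LOCAL_BRIGHTNESS_PROB = 0.10
LOCAL_BRIGHTNESS_MAX = 40.0
LOCAL_BRIGHTNESS_RADIUS = (0.1, 0.3)   # fraction of H
DOUBLE_EXPOSURE_PROB = 0.05
DOUBLE_EXPOSURE_ALPHA = (0.3, 0.7)
NOISE_SIGMA_RANGE = (1.0, 5.0)
JPEG_QUALITY_RANGE = (60, 90)

DEFAULT_RESOLUTION = (384, 512)        # (H, W)
RECORD_FILES = ("frame1.png", "frame2.png", "flow_full.flo",
                "flow_simple.flo", "seg1.png", "seg2.png", "meta.json")
TOOL_KINDS = ("light_pipe", "cutter", "forceps")


@dataclass
class RecordPair:
    """One training record plus all sampled parameters."""

    frame1: np.ndarray
    frame2: np.ndarray
    flow_full: np.ndarray
    flow_simple: np.ndarray
    seg1: np.ndarray
    seg2: np.ndarray
    meta: dict
    occlusion: np.ndarray | None = None   # px where layer blending makes the
    #                                       single-flow warp model ambiguous


@dataclass
class SubsetSpec:
    """Recipe for one dataset subset."""

    name: str
    layers: str                        # retina | retina+fov | retina+tools+fov
    menu: dict                         # role -> list of transform families
    n_tools: int = 0
    n_records: int = 2000
    resolution: tuple[int, int] = DEFAULT_RESOLUTION
    seed: int = 0
    augment_probs: dict = field(default_factory=lambda: {
        "blur": BLUR_PROB,
        "global_brightness": GLOBAL_BRIGHTNESS_PROB,
        "local_brightness": LOCAL_BRIGHTNESS_PROB,
    })
    double_exposure_prob: float = DOUBLE_EXPOSURE_PROB
    with_shadow: bool = True
    with_glare: bool = True
    hsv_match: bool = True
    degrade: bool = True

    def __post_init__(self):
        for v in self.augment_probs.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("augment probabilities must lie in [0, 1]")


@dataclass
class DatasetConfig:
    """Declarative description of a whole dataset build."""

    subsets: list
    resolution: tuple[int, int] = DEFAULT_RESOLUTION
    variant: str = "main"
    seed: int = 0

    def to_dict(self):
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "DatasetConfig":
        d = yaml.safe_load(text)
        subsets = [SubsetSpec(**{**s, "resolution": tuple(s["resolution"])})
                   for s in d.pop("subsets")]
        return cls(subsets=subsets, resolution=tuple(d["resolution"]),
                   variant=d["variant"], seed=d["seed"])

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(variant: str = "main",
                   resolution: tuple[int, int] = DEFAULT_RESOLUTION,
                   n_records: int = 2000, seed: int = 0) -> DatasetConfig:
    """The standard 16-subset recipe (or its nl / nl_nb ablation)."""
    if variant not in ("main", "nl", "nl_nb"):
        raise ValueError(f"unknown variant {variant!r}")
    retina_families = ["translate", "rotate", "scale", "pincushion", "bubble"]
    subsets = []
    for i, fam in enumerate(retina_families, start=1):
        subsets.append(SubsetSpec(
            name=f"{i:02d}_retina_{fam}", layers="retina",
            menu={"retina": [fam]}, seed=seed * 1000 + i))
    # Retina + FOV subsets: one family per subset in the listed order, the
    # last subset taking the remaining rotation+scaling pair.
    fov_families = [["translate"], ["rotate"], ["scale"], ["bubble"],
                    ["rotate", "scale"]]
    for j, fams in enumerate(fov_families, start=6):
        fov_menu = [f for f in fams if f != "bubble"]
        subsets.append(SubsetSpec(
            name=f"{j:02d}_fov_{'_'.join(fams)}", layers="retina+fov",
            menu={"retina": fams, "fov": fov_menu}, seed=seed * 1000 + j))
    # Tool subsets: every layer with translation/rotation/scaling.
    for k in range(11, 17):
        n_tools = 1 if k <= 13 else 2
        subsets.append(SubsetSpec(
            name=f"{k:02d}_tools{n_tools}", layers="retina+tools+fov",
            menu={"retina": ["translate", "rotate", "scale"],
                  "fov": ["translate", "rotate", "scale"],
                  "tool": ["translate", "rotate", "scale"]},
            n_tools=n_tools, seed=seed * 1000 + k))
    for s in subsets:
        s.n_records = n_records
        s.resolution = resolution
        if variant in ("nl", "nl_nb"):
            s.with_shadow = False
            s.with_glare = False
            s.hsv_match = False
        if variant == "nl_nb":
            s.augment_probs["global_brightness"] = 0.0
            s.augment_probs["local_brightness"] = 0.0
    return DatasetConfig(subsets=subsets, resolution=resolution,
                         variant=variant, seed=seed)


# ---------------------------------------------------------------------------
# Per-record sampling
# ---------------------------------------------------------------------------

def _sample_family(fam: str, rng: np.random.Generator, size) -> TransformSpec:
    h, w = size
    if fam == "translate":
        mag = rng.uniform(0.0, TRANSLATION_MAX_PX)
        ang = rng.uniform(0.0, 2 * np.pi)
        return TransformSpec("translate", {"tx": float(mag * np.cos(ang)),
                                           "ty": float(mag * np.sin(ang))})
    if fam == "rotate":
        return TransformSpec("rotate",
                             {"theta_deg": float(rng.uniform(*ROTATION_RANGE_DEG))})
    if fam == "scale":
        return TransformSpec("scale", {"s": float(rng.uniform(*SCALING_RANGE))})
    if fam == "pincushion":
        return TransformSpec("pincushion",
                             {"max_disp_px": float(rng.uniform(*PINCUSHION_RANGE_PX))})
    if fam == "bubble":
        return TransformSpec("bubble", {
            "centre": [float(rng.uniform(*BUBBLE_CENTRE_RANGE) * w),
                       float(rng.uniform(*BUBBLE_CENTRE_RANGE) * h)],
            "radius": float(rng.uniform(*BUBBLE_RADIUS_RANGE) * h),
            "amplitude": float(rng.uniform(*BUBBLE_AMPLITUDE_RANGE)),
        })
    raise ValueError(f"unknown transform family {fam!r}")


def _sample_chain(families, spec: SubsetSpec, rng, size,
                  allow_double_exposure: bool) -> TransformChain:
    specs = [_sample_family(f, rng, size) for f in families]
    if (allow_double_exposure and specs
            and rng.random() < spec.double_exposure_prob):
        specs.append(TransformSpec("double_exposure", {
            "alpha": float(rng.uniform(*DOUBLE_EXPOSURE_ALPHA))}))
    return TransformChain(specs)


def _sample_augments(spec: SubsetSpec, rng, size) -> list[TransformSpec]:
    h, w = size
    out = []
    if rng.random() < spec.augment_probs.get("blur", 0.0):
        out.append(TransformSpec("blur", {
            "kernel_px": int(rng.choice([3, BLUR_MAX_KERNEL_PX]))}))
    if rng.random() < spec.augment_probs.get("global_brightness", 0.0):
        out.append(TransformSpec("brightness_global", {
            "delta": float(rng.uniform(-GLOBAL_BRIGHTNESS_MAX,
                                       GLOBAL_BRIGHTNESS_MAX))}))
    if rng.random() < spec.augment_probs.get("local_brightness", 0.0):
        out.append(TransformSpec("brightness_local", {
            "cx": float(rng.uniform(0, w)), "cy": float(rng.uniform(0, h)),
            "radius": float(rng.uniform(*LOCAL_BRIGHTNESS_RADIUS) * h),
            "delta": float(rng.uniform(-LOCAL_BRIGHTNESS_MAX,
                                       LOCAL_BRIGHTNESS_MAX))}))
    return out


def sample_record(spec: SubsetSpec, index: int,
                  fundus_source=None) -> RecordPair:
    """Build one record deterministically from ``(spec.seed, index)``.

    ``fundus_source`` may be a callable ``(rng, size) -> uint8 image``
    supplying real retina textures; by default the procedural generator is
    used.  Tool placements that fall off-canvas are retried with a fresh
    sub-seed up to 10 times.
    """
    size = tuple(spec.resolution)
    h, w = size
    for attempt in range(10):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, index, attempt]))
        try:
            return _sample_record_once(spec, index, rng, size, fundus_source)
        except PlacementError:
            continue
    raise PlacementError(f"record {spec.name}/{index}: placement failed 10x")


def _sample_record_once(spec, index, rng, size, fundus_source) -> RecordPair:
    h, w = size
    meta = {"subset": spec.name, "index": index, "layers": spec.layers,
            "chains": {}, "augments": {}, "tools": []}

    if fundus_source is not None:
        fundus = fundus_source(rng, size)
    else:
        fp = FundusParams(seed=int(rng.integers(2 ** 31)), size=size,
                          vessel_count=int(rng.integers(6, 14)))
        meta["fundus_seed"] = fp.seed
        fundus = generate_fundus(fp)
    retina1 = SceneLayer(color=fundus.astype(np.float32),
                         opacity=np.ones(size, np.float32), role="retina")

    groups1, groups2 = [[retina1]], []
    flows = {}

    chain = _sample_chain(spec.menu.get("retina", []), spec, rng, size,
                          allow_double_exposure=True)
    meta["chains"]["retina"] = chain.to_json()
    retina2, retina_flow = apply_chain(retina1, chain)
    groups2.append([retina2])
    flows["retina"] = retina_flow

    with_tools = "tools" in spec.layers
    if with_tools:
        for t in range(spec.n_tools):
            kind = TOOL_KINDS[int(rng.integers(len(TOOL_KINDS)))]
            tmpl = generate_tool_template(kind, seed=int(rng.integers(2 ** 31)))
            placement = sample_tool_placement(kind, rng)
            tool1, shadow1, glare1 = make_tool_layer(
                tmpl, placement, retina1, rng, hsv_match=spec.hsv_match,
                with_shadow=spec.with_shadow, with_glare=spec.with_glare)
            tchain = _sample_chain(spec.menu.get("tool", []), spec, rng, size,
                                   allow_double_exposure=False)
            tool2, tool_flow = apply_chain(tool1, tchain)
            shadow2, _ = apply_chain(shadow1, tchain)
            glare2, _ = apply_chain(glare1, tchain)
            groups1.append([shadow1, tool1, glare1])
            groups2.append([shadow2, tool2, glare2])
            flows[f"tool{t}"] = tool_flow
            meta["tools"].append({"kind": kind,
                                  "placement": placement.to_dict()})
            meta["chains"][f"tool{t}"] = tchain.to_json()

    with_fov = "fov" in spec.layers
    if with_fov:
        fov1 = make_fov_layer(size, rng)
        fchain = _sample_chain(spec.menu.get("fov", []), spec, rng, size,
                               allow_double_exposure=False)
        fov2, fov_flow = apply_chain(fov1, fchain)
        groups1.append([fov1])
        groups2.append([fov2])
        flows["fov"] = fov_flow
        meta["chains"]["fov"] = fchain.to_json()

    # Photometric augmentation: an appearance change between the two frames,
    # applied to the frame-2 side of each layer.
    from .transform_engine import apply_photometric
    for gi, group in enumerate(groups2):
        augs = _sample_augments(spec, rng, size)
        meta["augments"][f"group{gi}"] = [
            {"kind": a.kind, "params": a.params} for a in augs]
        for a in augs:
            for layer in group:
                layer.color = apply_photometric(layer.color, a)

    stack1 = [l for g in groups1 for l in g]
    stack2 = [l for g in groups2 for l in g]
    frame1, seg1 = composite_stack(stack1)
    frame2, seg2 = composite_stack(stack2)

    # Full flow: topmost layer with opacity > 0.5 wins per frame-1 pixel.
    flow_full = flows["retina"].copy()
    if with_tools:
        for t, group in enumerate(groups1[1:1 + spec.n_tools]):
            tool1 = group[1]
            mask = tool1.opacity > 0.5
            flow_full[mask] = flows[f"tool{t}"][mask]
    if with_fov:
        fov1 = groups1[-1][0]
        mask = fov1.opacity > 0.5
        flow_full[mask] = flows["fov"][mask]

    # Simplified flow: retina motion everywhere inside the FOV, zero outside.
    flow_simple = flows["retina"].copy()
    flow_simple[seg1 == 0] = 0.0

    # Occlusion/ambiguity mask: pixels whose colour mixes layers with
    # different motions (semi-transparent tool halos, shadows, glare, the
    # blurred FOV rim) in either frame; the backward-warp identity cannot
    # hold there.
    def _ambiguous(groups, fov_full: bool):
        amb = np.zeros(size, dtype=bool)
        for group in groups[1:]:
            for layer in group:
                if layer.role == "fov" and not fov_full:
                    # frame-1 side: the opaque black interior follows the fov
                    # flow onto equally black pixels, only the rim blends
                    amb |= (layer.opacity > 0.01) & (layer.opacity < 0.99)
                else:
                    amb |= layer.opacity > 0.01
        return amb

    amb1 = _ambiguous(groups1, fov_full=False)
    amb2 = _ambiguous(groups2, fov_full=True)
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float32)
    amb2_at_p = flowcore.bilinear_sample(
        amb2.astype(np.float32), gx + flow_full[..., 0],
        gy + flow_full[..., 1], mode="nearest") > 0.01
    occlusion = (amb1 | amb2_at_p).astype(np.uint8)

    if spec.degrade:
        ns1, q1 = (float(rng.uniform(*NOISE_SIGMA_RANGE)),
                   int(rng.integers(JPEG_QUALITY_RANGE[0],
                                    JPEG_QUALITY_RANGE[1] + 1)))
        ns2, q2 = (float(rng.uniform(*NOISE_SIGMA_RANGE)),
                   int(rng.integers(JPEG_QUALITY_RANGE[0],
                                    JPEG_QUALITY_RANGE[1] + 1)))
        frame1 = degrade(frame1, rng, ns1, q1)
        frame2 = degrade(frame2, rng, ns2, q2)
        meta["degrade"] = {"sigma": [ns1, ns2], "quality": [q1, q2]}

    meta["geometry_only"] = (
        not spec.degrade
        and all(not a for a in meta["augments"].values())
        and "double_exposure" not in meta["chains"]["retina"])
    return RecordPair(frame1=frame1, frame2=frame2, flow_full=flow_full,
                      flow_simple=flow_simple, seg1=seg1, seg2=seg2,
                      meta=meta, occlusion=occlusion)


# ---------------------------------------------------------------------------
# Disk builds
# ---------------------------------------------------------------------------

def build_dataset(config: DatasetConfig, out_dir,
                  limit_per_subset: int | None = None,
                  progress: bool = False) -> dict:
    """Write a dataset to ``out_dir`` and return its manifest.

    Each record occupies one directory with the seven standard files;
    existing complete records are skipped, so interrupted builds resume.
    The manifest (also written to ``manifest.json``) lists every record with
    its subset and seed alongside the config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    iterator = config.subsets
    if progress:
        from tqdm import tqdm
        iterator = tqdm(config.subsets, desc="subsets")
    try:
        for spec in iterator:
            n = spec.n_records if limit_per_subset is None \
                else min(spec.n_records, limit_per_subset)
            for i in range(n):
                rid = f"{spec.name}/{i:05d}"
                rdir = out / spec.name / f"{i:05d}"
                if not all((rdir / f).exists() for f in RECORD_FILES):
                    rec = sample_record(spec, i)
                    rdir.mkdir(parents=True, exist_ok=True)
                    save_image(rdir / "frame1.png", rec.frame1)
                    save_image(rdir / "frame2.png", rec.frame2)
                    write_flo(rec.flow_full, rdir / "flow_full.flo")
                    write_flo(rec.flow_simple, rdir / "flow_simple.flo")
                    save_mask(rdir / "seg1.png", rec.seg1)
                    save_mask(rdir / "seg2.png", rec.seg2)
                    (rdir / "meta.json").write_text(
                        json.dumps(rec.meta, sort_keys=True))
                records.append({"id": rid, "subset": spec.name,
                                "seed": spec.seed, "index": i})
    finally:
        manifest = {"config_hash": config.content_hash(),
                    "variant": config.variant,
                    "resolution": list(config.resolution),
                    "records": records}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def scheduled_records(config: DatasetConfig) -> int:
    """Total number of records the configuration will produce."""
    return sum(s.n_records for s in config.subsets)


def train_val_split(manifest: dict, val_fraction: float, seed: int = 0):
    """Per-subset stratified random split into (train_ids, val_ids)."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    records = manifest["records"]
    if not records:
        raise ValueError("empty manifest")
    by_subset = {}
    for rec in records:
        by_subset.setdefault(rec["subset"], []).append(rec["id"])
    rng = np.random.default_rng(seed)
    train, val = [], []
    for subset in sorted(by_subset):
        ids = sorted(by_subset[subset])
        perm = rng.permutation(len(ids))
        n_val = int(round(len(ids) * val_fraction))
        val.extend(ids[i] for i in perm[:n_val])
        train.extend(ids[i] for i in perm[n_val:])
    return sorted(train), sorted(val)


def retina_flow_of(record: RecordPair) -> np.ndarray:
    """Recompute the retina-layer flow of a record from its stored chain."""
    from .transform_engine import chain_flow
    chain = TransformChain.from_json(record.meta["chains"]["retina"])
    return chain_flow(chain, record.seg1.shape)[0]


def audit_parameters(meta: dict, resolution) -> list:
    """Check every sampled parameter of a record against its stated
    interval; returns a list of violation strings (empty when clean)."""
    h, w = resolution
    bad = []

    def chk(ok, msg):
        if not ok:
            bad.append(msg)

    for lname, cjson in meta["chains"].items():
        for spec in TransformChain.from_json(cjson).specs:
            p = spec.params
            if spec.kind == "translate":
                chk(np.hypot(p["tx"], p["ty"]) <= TRANSLATION_MAX_PX + 1e-9,
                    f"{lname}: translation magnitude {p}")
            elif spec.kind == "rotate":
                chk(ROTATION_RANGE_DEG[0] <= p["theta_deg"] <= ROTATION_RANGE_DEG[1],
                    f"{lname}: rotation {p}")
            elif spec.kind == "scale":
                chk(SCALING_RANGE[0] <= p["s"] <= SCALING_RANGE[1],
                    f"{lname}: scale {p}")
            elif spec.kind == "pincushion":
                chk(PINCUSHION_RANGE_PX[0] <= p["max_disp_px"] <= PINCUSHION_RANGE_PX[1],
                    f"{lname}: pincushion {p}")
            elif spec.kind == "bubble":
                cx, cy = p["centre"]
                chk(BUBBLE_CENTRE_RANGE[0] * w <= cx <= BUBBLE_CENTRE_RANGE[1] * w
                    and BUBBLE_CENTRE_RANGE[0] * h <= cy <= BUBBLE_CENTRE_RANGE[1] * h,
                    f"{lname}: bubble centre {p}")
                chk(BUBBLE_RADIUS_RANGE[0] * h <= p["radius"] <= BUBBLE_RADIUS_RANGE[1] * h,
                    f"{lname}: bubble radius {p}")
                chk(BUBBLE_AMPLITUDE_RANGE[0] <= p["amplitude"] <= BUBBLE_AMPLITUDE_RANGE[1],
                    f"{lname}: bubble amplitude {p}")
            elif spec.kind == "double_exposure":
                chk(DOUBLE_EXPOSURE_ALPHA[0] <= p["alpha"] <= DOUBLE_EXPOSURE_ALPHA[1],
                    f"{lname}: double exposure {p}")

    for augs in meta["augments"].values():
        for a in augs:
            p = a["params"]
            if a["kind"] == "blur":
                chk(p["kernel_px"] <= BLUR_MAX_KERNEL_PX, f"blur {p}")
            elif a["kind"] == "brightness_global":
                chk(abs(p["delta"]) <= GLOBAL_BRIGHTNESS_MAX, f"global brightness {p}")
            elif a["kind"] == "brightness_local":
                chk(abs(p["delta"]) <= LOCAL_BRIGHTNESS_MAX, f"local brightness {p}")
                chk(LOCAL_BRIGHTNESS_RADIUS[0] * h <= p["radius"]
                    <= LOCAL_BRIGHTNESS_RADIUS[1] * h, f"local radius {p}")

    from . import layer_compositor as lc
    for tool in meta.get("tools", []):
        p = tool["placement"]
        kind = tool["kind"]
        tip_x_range = (lc.TIP_X_RANGE_LIGHT_PIPE if kind == "light_pipe"
                       else lc.TIP_X_RANGE_OTHER)
        checks = [
            (lc.SCALE_RANGE, p["scale"], "scale"),
            (lc.STRETCH_RANGE, p["stretch"], "stretch"),
            (lc.ROTATION_RANGE, p["rotation_deg"], "rotation"),
            (tip_x_range, p["tip_x"], "tip_x"),
            (lc.TIP_Y_RANGE, p["tip_y"], "tip_y"),
            (lc.SHADOW_OFFSET_RANGE, p["shadow_offset_px"], "shadow offset"),
            (lc.SHADOW_ANGLE_RANGE, p["shadow_angle_deg"], "shadow angle"),
            (lc.SHADOW_ALPHA_RANGE, p["shadow_alpha"], "shadow alpha"),
            (lc.GLARE_COUNT_RANGE, p["glare_n_ovals"], "glare count"),
            (lc.GLARE_RADIUS_RANGE, p["glare_radius_px"], "glare radius"),
            (lc.GLARE_CREST_ALPHA_RANGE, p["glare_crest_alpha"], "crest alpha"),
        ]
        for (lo, hi), v, nm in checks:
            chk(lo <= v <= hi, f"tool {nm} {v}")
        chk(p["blur_kernel_px"] in (3, 5, 7), f"tool blur {p['blur_kernel_px']}")

    if "degrade" in meta:
        for s in meta["degrade"]["sigma"]:
            chk(NOISE_SIGMA_RANGE[0] <= s <= NOISE_SIGMA_RANGE[1], f"noise {s}")
        for q in meta["degrade"]["quality"]:
            chk(JPEG_QUALITY_RANGE[0] <= q <= JPEG_QUALITY_RANGE[1], f"jpeg {q}")
    return bad


def audit_build(n_records: int = 200, resolution=(192, 256), seed: int = 11):
    """In-memory audit sample spread across all 16 subsets.

    Image degradation is disabled so the geometric ground truth can be
    checked against the rendered frames directly; photometric augmentation
    keeps its standard probabilities so those draws are audited too.
    Returns a list of ``(SubsetSpec, RecordPair)``.
    """
    cfg = default_config("main", resolution=resolution, seed=seed)
    for s in cfg.subsets:
        s.degrade = False
    per = -(-n_records // len(cfg.subsets))
    out = []
    for spec in cfg.subsets:
        for i in range(per):
            out.append((spec, sample_record(spec, i)))
    return out[:n_records]


def translation_subset_spec(size=(48, 64), n_records: int = 200,
                            seed: int = 0) -> SubsetSpec:
    """A clean retina-only translation subset for desk-scale training runs."""
    return SubsetSpec(name="smoke_translation", layers="retina",
                      menu={"retina": ["translate"]}, n_records=n_records,
                      resolution=size, seed=seed,
                      augment_probs={"blur": 0.0, "global_brightness": 0.0,
                                     "local_brightness": 0.0},
                      double_exposure_prob=0.0, degrade=False)
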
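# retinaflow

Tools for intra-operative tracking of the retinal fundus by dense optical
flow.  During vitreoretinal surgery the retina deforms with breathing,
pulsation and manipulation, and sub-millimetre instruments continually
occlude it — yet upcoming regenerative therapies need any chosen retinal
point tracked for minutes at a time.  Manually annotating dense motion in
surgical video is infeasible, so this package takes the synthetic-data
route end to end:

1. **Simulate** microscope frames as layered scenes — fundus texture at the
   bottom, metallic tools (with shadows and glare) in the middle, the
   circular field-of-view vignette on top — transformed by known motions so
   every record carries an exact dense flow field `f` (pixel `p` in frame 1
   appears at `p + f(p)` in frame 2), with the tool motion *removed* from
   the training target so an estimator learns to inpaint retinal flow
   through occlusions.
2. **Train** a FlowNetSimple-style encoder–decoder that jointly predicts
   flow and field-of-view segmentation at multiple scales, with the
   four-term cost

   `Cost = λ_flow · mean_s mean_xy ‖f_pred − f_gt‖ + λ_reg · ½ Σ w² +
   λ_seg · Σ −p_gt log p_pred + λ_var · Σ m·|∂f/∂x + ∂f/∂y|`

   (λ_flow = 1, λ_seg = 1e−3, λ_reg = 1e−7, λ_var = 1e−6; `m` masks a 3 px
   band at the FOV border).
3. **Evaluate** any flow source by point tracking: short-fragment EPE
   (s-EPE, over 11-frame fragments re-seeded at sparse annotations),
   long-sequence EPE (l-EPE, at the final frame), and the grid-loop EPE
   (every in-FOV pixel tracked out through the odd frames and back through
   the even frames; loop-closure distance per vertex).

The whole stack is plain scientific Python (numpy/scipy/scikit-image); the
network and its training loop run on a small reverse-mode autodiff engine
included in the package, so everything works on one CPU.

## Worked example

```python
import numpy as np
import retinaflow as rf

# one synthetic training record (two-tool subset of the default recipe)
cfg = rf.default_config("main", resolution=(192, 256), seed=0)
rec = rf.sample_record(cfg.subsets[15], index=0)
inside = rec.seg1 > 0
moved = np.abs(rec.flow_full - rec.flow_simple).max(axis=-1) > 0.1
print("in-FOV fraction:", round(float(inside.mean()), 3))
print("pixels whose tool motion was suppressed:", int((moved & inside).sum()))

# evaluator on a synthetic clip with an occluding tool sweep
clip = rf.make_synthetic_clip(n_frames=21, seed=7, with_tool=True)
s_inp, _, _, _ = rf.sequence_epe(clip["gt"], clip["annotations"])
s_full, _, _, _ = rf.sequence_epe(clip["full"], clip["annotations"])
print(f"s-EPE inpainted flow: {s_inp:.3f} px, full flow: {s_full:.3f} px")
```

prints

```
in-FOV fraction: 0.421
pixels whose tool motion was suppressed: 5429
s-EPE inpainted flow: 0.000 px, full flow: 8.799 px
```

The first two numbers show the record structure: only ~42 % of this frame
lies inside the microscope circle, and over five thousand of those pixels
sat under a tool whose motion was replaced by the underlying retinal motion
in the training target.  The last line is the package's central property in
miniature: tracking annotated points with the tool-suppressed (inpainted)
flow is essentially exact, while tracking with the raw full-motion flow
drags the occluded point along with the instrument and accumulates an
8.8 px error over the clip.

A command-line interface wraps the same library:

```bash
retinaflow fundus --seed 3 --size 384x512 --out fundus.png
retinaflow generate --variant main --limit 2 --seed 0 --out data/
retinaflow train --data data/ --variant comb --width 0.5 --epochs 5 \
    --seed 0 --out model.npz
retinaflow predict --ckpt model.npz --frames a.png b.png --out-flo f.flo
retinaflow bench-synth --frames 201 --seed 1 --out report.json
```

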
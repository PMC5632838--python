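# hifutrack

Motion compensation for MR-guided high-intensity focused ultrasound
(MRg-HIFU) thermal ablation in the abdomen.

During a lengthy MRg-HIFU therapy the target anatomy moves on several
time-scales at once: quasi-periodic respiration (3–5 s cycles), slow
irreversible drifts over minutes (digestion, muscle relaxation — up to
several mm per hour), and EPI geometric distortion that displaces the
fast thermometry images relative to the true anatomy.  Left unaddressed,
these misalignments divert therapeutic energy from the planned target and
corrupt the accumulated thermal-dose maps.  `hifutrack` implements the
image-based machinery that keeps such a therapy spatially consistent, for
researchers developing or validating motion-compensated thermal-therapy
pipelines.

## What is inside

* **Two dense deformable registration engines.**  A mono-modal
  variational optical flow minimising
  `E(u) = Σ_r |I(r) − J(r+u(r))| + α‖∇u(r)‖²` (L1 data term, Charbonnier
  IRLS, coarse-to-fine), and a multi-modal engine based on
  modality-independent neighbourhood descriptors (MIND),
  `MIND(I,r,γ) = exp(−D_p/V)/Z`, minimising the squared mean absolute
  descriptor difference with Gauss–Newton.  Both return per-voxel
  displacements in millimetres with monotone energy traces.
* **The linked registration steps** of a gated therapy work-flow: 3D
  drift tracking against a reference anchor (RS#1), per-dynamic residual
  respiratory motion (RS#2), cross-contrast 2D-to-3D residual alignment
  after plane reformatting (RS#3), EPI distortion estimation against a
  non-distorted EPI scan (RS#4), and a mono-modal silver standard for
  validating the multi-modal step (RS#5).
* **Plan and dose propagation.**  Sonication plans are re-targeted
  *down-stream* with the latest drift field; CEM43 thermal dose
  (Sapareto–Dean, R = 0.5/0.25, lethal at 240 CEM43) is accumulated from
  motion-aligned temperature series and mapped *up-stream* — distortion,
  then residual, then drift — into the 3D planning frame, where plan
  coverage is scored.
* **A synthetic moving grid phantom** (gel cylinder with two orthogonal
  grid structures, breathing trace with injected 5 mm drift steps, gated
  acquisition, EPI-like contrast, calibrated phase-encode distortions,
  Gaussian heating hotspots) with *exact* ground truth for every scan, so
  the whole chain is testable without any data download.

## Worked example

```python
import numpy as np
from hifutrack import (PhantomSpec, ProtocolConfig, acquire_session,
                       rs1_estimate_drift)
from hifutrack.phantom import structure_mask_at

spec = PhantomSpec()                      # 96x96x40 voxels, 2 mm isotropic
protocol = ProtocolConfig(n_anchors=9, n_bundles=0, n_dynamics=0)
session, truth = acquire_session(spec, None, protocol, seed=1)

ref = session.reference_anchor
roi = structure_mask_at(spec, ref, displacement_mm=truth.reference_displacement)

res = rs1_estimate_drift(session.anchors[8], ref)   # last anchor: ~10 mm drift
gt = truth.rs1_truth(8)
ee = np.linalg.norm(res.field.vectors[roi.mask] - gt, axis=-1)
print(f"injected drift {np.linalg.norm(gt):.2f} mm")
print(f"EE mean {ee.mean():.2f} mm, 95th percentile {np.percentile(ee, 95):.2f} mm")
```

Output:

```
injected drift 9.48 mm
EE mean 0.31 mm, 95th percentile 0.58 mm
```

The injected drift is the two 5 mm steps plus the gated breathing
residual; the optical-flow engine recovers it with sub-voxel accuracy
(voxels are 2 mm) on the phantom's structure voxels.

A command-line interface wraps the same operations:

```
hifutrack phantom generate --seed 1 --out session/
hifutrack run --manifest session/session.json --out results/
hifutrack register of --fixed a.nii --moving b.nii --out field.nii
hifutrack metrics ee --a field.nii --b truth.nii --out stats.json
```

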
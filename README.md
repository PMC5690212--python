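# regiq — registration quality evaluation for 2D/3D rigid image registration

Intensity-based 2D/3D registration aligns a 3D planning volume (e.g., a CT
of the head) to a pair of orthogonal planar radiographs by optimizing an
image-similarity measure over the six rigid pose parameters (three
translations in mm, three rotations in deg about the isocenter). The
similarity landscape has local optima; an optimizer trapped in one returns a
confidently wrong pose, which in image-guided radiotherapy means a wrong
patient setup. `regiq` implements a **registration quality evaluator
(RQE)**: a small neural network that looks at the *shape* of the cost
function around a candidate solution and decides whether to accept it or to
retry the registration from a new random start.

The package targets medical-physics / image-guidance researchers who want a
complete, reproducible desk-scale testbed for this idea: every stage is
seeded, synthetic, and runs on one CPU.

## Method at a glance

* **Cost.** DRRs (digitally reconstructed radiographs) are ray-cast from the
  posed volume onto two orthogonal panels; the cost is the negated mean
  normalized mutual information `NMI = (H(A)+H(B)) / H(A,B)` against the
  reference images inside per-panel ROIs (range [-2, -1); -2 = perfect).
* **Normalized pose space.** Rotations are rescaled by the **mean voxel
  displacement** (MVD): one unit of any parameter displaces the voxels of a
  3D ROI by 1 mm on average, so pose error is a Euclidean distance in mm.
  A solution farther than 1 mm MVD from the per-case gold standard
  (best-of-N multi-start registration) is labeled *unsuccessful*.
* **Features.** The cost is sampled at `±k·s` (k = 1..3) along the six
  normalized axes around the solution. Distinctiveness of optimum
  `DO = mean(cost(offset) − cost(center))` (deeper valley ⇒ larger) and
  mirror symmetry `MS = mean |c₊−c₋| / (|c₊−c₀|+|c₋−c₀|+ε)` (global optima
  are more symmetric ⇒ smaller), each over translations and rotations
  separately, give the feature vector (DO_t, DO_r, MS_t, MS_r).
* **Classifier.** A 4-2-1 tanh network (output mapped to [0,1], > 0.5 ⇒
  unsuccessful) trained by scaled conjugate gradient with early stopping,
  evaluated leave-one-subject-out; the profile step size `s` is swept over
  {1, 5, 10, 15, 20, 25, 30} mm and chosen by held-out balanced accuracy.
* **Robust loop.** register → score → accept or retry (≤ 5 trials, fresh
  random starts in ±20 mm / ±8°). Efficiency is summarized by the
  trial-to-acceptance ratio (TAR) and the final acceptance ratio (FAR).

Details, assumptions and limitations: [`docs/methods.md`](docs/methods.md).

## Worked example

```python
import numpy as np
from regiq import (RigidTransform, make_head_phantom, make_case,
                   normalization_factors, mvd_distance, register,
                   sample_profiles, compute_features)
from regiq.phantom import brain_roi

vol = make_head_phantom(seed=1, grid_size=48, spacing=2.5)
case = make_case(vol, true_pose=RigidTransform.identity(), noise_sd=0.0, seed=0)
nf = normalization_factors(brain_roi(vol), vol.isocenter)

sol = register(vol, case, init=RigidTransform(t=[4.0, -3.0, 2.0], r=[1.5, -1.0, 0.5]))
print(sol.pose, round(sol.final_cost, 3))
print("MVD error vs truth:", round(mvd_distance(sol.pose, RigidTransform.identity(), nf), 3), "mm")

fv = compute_features(sample_profiles(vol, case, sol.pose, nf, step_size=5.0))
print(fv)
```

prints

```
RigidTransform(t=[0.000, 0.000, 0.000] mm, r=[-0.000, -0.000, -0.000] deg) -2.0
MVD error vs truth: 0.0 mm
FeatureVector(do_trans=0.5338539511751546, do_rot=0.6174560646856821, ms_trans=6.1805407528193e-05, ms_rot=0.003277153251319791)
```

i.e., from a 4-5 mm / 1.5° initial offset the optimizer recovers the exact
true pose of the noiseless case (cost −2, the perfect-match bound). The
profile features show a deep valley (DO ≈ 0.53-0.62: the cost rises steeply
within ±15 mm of the solution) that is highly symmetric (MS ≈ 0.0001-0.003)
— the signature of a trustworthy solution that the classifier learns to
recognize; failed registrations show shallower, lopsided profiles.

The full experiment — campaign generation, gold standards, labeled dataset,
step-size sweep, classifier training, robust loop — is one call (or the
equivalent `regiq` CLI subcommands `simulate`, `gold-standard`,
`build-dataset`, `sweep`, `train`, `robust-run`, `report`):

```python
from regiq.pipeline import ExperimentConfig, run_pipeline
result = run_pipeline(ExperimentConfig(seed=1), outdir="out")
```

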
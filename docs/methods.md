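# Methods

## Problem

Intensity-based 2D/3D rigid registration aligns a 3D planning volume to a
pair of orthogonal planar radiographs by maximizing an image-similarity
measure over the six rigid-pose parameters. The similarity landscape has
local optima, and an optimizer that terminates in one returns a confidently
wrong pose. `regiq` implements a *registration quality evaluator* (RQE): a
classifier that inspects the local shape of the cost function around a
candidate solution and predicts whether the solution is within a clinical
error tolerance, enabling an automatic accept/reject/retry loop.

## Pipeline

1. **DRR rendering.** A digitally reconstructed radiograph is the line
   integral of trilinearly interpolated volume intensity along each detector
   pixel's ray (fixed-step midpoint rule; step = half the minimum voxel
   spacing by default). Two orthogonal panels are used: lateral (view along
   +x) and PA (view along +y). Parallel-beam is the default geometry —
   it admits closed-form test cases (shift equivalence, analytic path
   lengths); a divergent (perspective) mode with configurable
   source/detector distances is available. Rays are clipped to the posed
   volume's bounding interval; misses contribute 0. The inner loop is a
   numba kernel (~2 ms for a 48-cubed volume onto a 48x48 panel), which is what
   makes multi-start campaigns tractable on one CPU.

2. **Similarity.** Normalized mutual information
   `NMI = (H(A)+H(B))/H(A,B)` over a rectangular per-panel ROI, from a
   joint intensity histogram (64 bins per image by default). The shipped
   campaign configurations use 32 bins: their detector ROIs hold only
   ~1-2k pixels, and joint-histogram occupancy (rule of thumb: bins ~
   sqrt(n_pixels)) governs how sharply the NMI localizes the optimum — with
   64 bins the 4096 joint cells are mostly empty and the cost surface
   develops a noise-roughened plateau ~1 mm wide around the optimum,
   measurably widening the solution cluster. The reference image's bin
   range is frozen from its ROI once per registration so the cost is
   comparable across iterations; the DRR is binned min-max per evaluation.
   Entropies are accumulated in a canonical (sorted) order so
   `nmi(a, b) == nmi(b, a)` holds bitwise. The registration
   cost is the negated mean NMI of the two panels, in [-2, -1). A constant
   image inside the ROI has zero entropy and raises a distinct degenerate
   error; pipeline stages that must evaluate far-field poses (profile
   sampling beyond the capture range, the robust loop) instead assign such
   panels the exact zero-information limit `NMI -> 1`.

3. **Optimization.** A derivative-free Powell-style coordinate search:
   probe +-step on one parameter at a time, walk greedily while the cost
   improves, and halve the steps (coarse 2 mm / 1 deg down to 0.05 mm /
   0.025 deg) when a sweep stalls. The coarse-to-fine schedule is run
   twice: after converging, the steps are re-coarsened and the search
   repeated from the converged iterate, which lets the single-axis walk
   step over narrow noise-induced bumps it would otherwise stall on
   (measured to collapse the population of 1-2 mm near-miss stalls).
   Deterministic given the start; evaluation-budgeted (900 by default,
   typically ~300 used); the kept iterate never exceeds the starting cost.
   Degenerate trial points are treated as +inf and never accepted.

4. **MVD normalization.** Rotational parameters are rescaled so one unit of
   any parameter displaces the voxels of a user-chosen cuboid ROI (here: a
   box covering the phantom interior, centred on the isocenter) by 1 mm on
   average: factor per degree = `(pi/180) * mean perpendicular distance` to
   the rotation axis. Pose error is the Euclidean norm in this normalized
   space; this is a first-order (small-angle) surrogate for the exact mean
   point displacement, and `mvd_exact` (brute-force point averaging) bounds
   the approximation — within 5% for perturbations up to 2 mm / 1 deg.
   Solutions farther than 1 mm MVD from the gold standard are labeled
   unsuccessful (strictly greater; the boundary counts as successful).

5. **Gold standards.** Per case, the best (minimal-cost) of `n_restarts`
   registrations started uniformly within +-5 mm / +-2 deg of the
   isocenter-aligned pose. The solution-cluster spread (per-parameter SD
   after excluding solutions > 3x the median MVD from the best) and a
   re-registration validation routine (restarts centred on the best pose)
   are reported as stability diagnostics.

6. **Features.** The cost is sampled at `+-k*s`, `k = 1..3`, along each of
   the six normalized axes around the solution (37 evaluations at one step
   size). Distinctiveness of optimum `DO = mean(cost(offset) - cost(center))`
   and mirror symmetry
   `MS = mean |c(+ks)-c(-ks)| / (|c(+ks)-c0| + |c(-ks)-c0| + 1e-12)`,
   each computed separately over the translational and rotational axes,
   giving the 4-vector (DO_trans, DO_rot, MS_trans, MS_rot). MS is
   normalized per offset pair so it is scale-free across step sizes; both
   features depend only on cost differences. The step size `s` is swept
   over {1, 5, 10, 15, 20, 25, 30} mm and chosen to maximize mean held-out
   balanced accuracy. Offsets at different steps nest (`2s, k=1` equals
   `s, k=2`), so the sweep shares cost evaluations through a memoized cost
   function.

7. **Classifier.** A 4-2-1 feed-forward network, tanh in both layers, the
   output affinely mapped to [0, 1] (this reconciles a tanh output unit
   with a probability-like score); > 0.5 strictly means unsuccessful.
   Two hidden units are the smallest architecture that can represent the
   curved class boundary; one unit measurably degrades performance (tested
   on an XOR-style construction). Training minimizes MSE with Moller's
   scaled conjugate gradient — conjugate directions with a finite-difference
   Hessian-vector estimate (sigma0 = 1e-4) and trust-region lambda
   adaptation, no line search — with early stopping (patience 25 checks) on
   a 20% validation split. Inputs are standardized on the training split;
   weight init is uniform +-0.5 per seed; everything is deterministic per
   seed.

8. **Evaluation.** Leave-one-subject-out: each subject's solutions are held
   out in turn, the network is trained on the remaining subjects (80/20
   internal split), and sensitivity/specificity are computed with
   *unsuccessful* as the positive class. Zero-denominator metrics are
   reported as NaN and flagged, never coerced.

9. **Robust loop.** Register from a random start (+-20 mm / +-8 deg, the
   training distribution), score the solution's features, accept at or below
   threshold 0.5, otherwise retry with a fresh random start, at most 5
   trials; exhaustion is a final rejection. TAR = trials/acceptances,
   FAR = acceptances/(acceptances + final rejections).

## Synthetic data

No imaging data ship with the package; the phantom generator emulates the
study design. A phantom is a bright ellipsoidal shell ("skull", ~1000
intensity units) with a ~60-unit interior containing 5-8 asymmetrically
placed Gaussian blobs (200-700 units) plus two quasi-periodic chains of
equal bone-density blobs (sigma 9-12 mm, period 20-25 mm, in two roughly
orthogonal directions) on a zero background. The random blobs guarantee no
rotation maps the phantom onto itself, so the registration optimum is
unique; the chains provide repetitive structure whose self-similarity
under a one-period shift creates the distant local minima that trap
intensity-based registration — the failure mechanism the quality evaluator
exists to detect. Per-subject anatomy varies by seed (shell eccentricity,
blob and chain placement); per-fraction true poses are drawn within
+-3 mm / +-1.5 deg of identity (plausible daily setup variation; a
stand-in choice — no distribution was available to emulate). Reference
projections get additive Gaussian noise with sd = 3% of the peak
projection intensity. The noise level is the generator's realism knob:
without noise this phantom's NMI landscape is benign enough that
registrations essentially never fail from +-20 mm / +-8 deg starts; the
3% level was calibrated so the campaign reproduces the reference study's
stated condition of roughly balanced successful/unsuccessful classes
(~40-50% failures), which that study achieved through its initialization
range against much busier clinical image content.

What the phantom does *not* emulate: divergent-beam magnification in the
default geometry, scatter/beam hardening, soft-tissue deformation,
truncated fields of view, and out-of-ROI clutter (immobilization devices,
shoulders). Passing tests therefore demonstrate the correctness of the
machinery and the internal consistency of the method — not clinical-grade
sensitivity/specificity, which depend on exactly those nuisances.

## Problem sizes and numerical choices

The shipped default campaign is 4 subjects x 4 fractions x 8 repeats on
48-cubed phantoms at 2.5 mm spacing (128 labeled solutions; full sweep and
robust loop in roughly fifteen minutes on one CPU, with the robust loop run
4 times per fraction); the gold standard in these configs uses 5 restarts,
since on this phantom all +-5 mm / +-2 deg restarts converge to a single
cluster and more restarts only repeat it. The function
defaults keep the reference study's values (50 restarts, 5 max trials,
1 mm tolerance). Ray step: half the minimum voxel spacing. Histogram bins:
64 default, 32 in the shipped campaigns (see Similarity above). Optimizer
tolerances as above; ties in the step-size sweep break toward the smaller
step. Rotation parameter differences are wrapped into
(-180, 180] before MVD normalization. All randomness derives from one
master seed through named `SeedSequence` substreams per stage, so campaign
artifacts are bit-reproducible.

## Known limitations

* **The desk-scale NMI localization shelf.** With ~2k-pixel panels and
  realistic noise, the NMI cost develops a shelf of near-degenerate local
  minima (cost gaps ~1e-3, below the reference-noise floor) of roughly
  1-1.5 mm radius around the optimum. This is a property of the similarity
  statistics at this image size, not of the optimizer: direction-set
  (Powell) polish from such a minimum does not escape it, and its cost
  profile matches the global optimum's at every swept step size, so no
  profile-shape classifier can separate shelf minima from true solutions.
  Because the 1 mm error tolerance sits inside this localization
  uncertainty, labels near the shelf edge are arbitrary, which caps
  held-out sensitivity at roughly the far-trap share of the failure class
  and caps the fraction of gate-accepted solutions within tolerance at
  ~0.8-0.95 depending on the seed's draw of phantoms. Clinical panels hold
  25-50x more ROI pixels, which sharpens the NMI enough that the same
  tolerance lies well outside the shelf; conclusions about the clinical
  regime should therefore come from the classifier's behaviour on the far
  (structural) failure class, which it separates cleanly.
* The MVD Euclidean distance is first-order in the rotations; `mvd_exact`
  exists to bound the error, and both are exposed.
* The small-angle normalization factors are computed on a regular grid at
  voxel spacing; factor error from discretization is < 1% (tested against
  brute-force rotation of the grid).
* The coordinate-search optimizer is a stand-in for whatever local
  optimizer a clinical system uses; the quality evaluator only assumes a
  deterministic local minimizer, but TAR/FAR figures depend on the
  optimizer's capture range.
* Perspective mode is rendered but the shipped campaigns use parallel beam;
  feature behaviour under strong divergence is untested.
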
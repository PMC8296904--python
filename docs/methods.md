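# Methods

## Problem and scope

Electrode localization for simultaneous EEG–fMRI proceeds in two
stages: a segmentation network marks candidate electrodes in an
ultra-short echo-time MR volume as labeled blobs, and a geometric
refinement turns those candidates into exactly one labeled position per
electrode. This package implements everything downstream of the
network: centroid extraction from a labeled volume, template
construction, the two-stage ICP refinement, the evaluation protocol,
and a synthetic generator that stands in for the MR/network front end.
The network itself, raw MR images, and scalp-surface projection are out
of scope; any NIfTI label map (or TSV detection cloud) is accepted as
input.

## Detection (volume_detect)

Connected components are computed separately within each voxel label
value using 26-connectivity, so touching spheres with different labels
remain distinct and a label split into several blobs yields several
candidates. Components smaller than `min_voxels` (default 2) are
dropped as speckle — a minimal filter, chosen because a genuine
electrode sphere at ~0.94 mm spacing occupies ~600 voxels and a
1-voxel blob is necessarily noise. The centroid is the unweighted mean
of the component's voxel indices mapped through the header affine; no
intensity weighting is used because the input is a label map. Voxel
indices are 0-based; all outputs are world millimetres.

## Similarity registration (registration)

`fit_similarity` is the closed-form least-squares solution for
`min Σ ‖s·R·pᵢ + t − qᵢ‖²` over isotropic scale, proper rotation and
translation: SVD of the cross-covariance, determinant sign correction
(reflections are never returned — an anatomically mirrored cap is never
an acceptable fit), and the variance-ratio scale. A single isotropic
scale is used rather than per-axis scaling, since head-size variation
is approximately isotropic at cap scale. Fits with scale outside
[0.5, 2.0] emit a warning: they are geometrically valid but almost
always indicate mis-registration.

`icp` alternates nearest-neighbour matching (KD-tree; ties broken
toward the lowest fixed-point index for determinism) with a full refit
of the moving→fixed transform on the matched pairs. Because each refit
is globally optimal for its matches, the recorded RMS residual sequence
is non-increasing; convergence is declared when it changes by less than
`tolerance` (default 1e-6 mm) or after `max_iterations` (default 100).

**Multi-start initialization.** Plain ICP is a local optimizer: with
~26 mm between neighbouring electrodes, an initial pose error beyond
roughly half that spacing can lock the correspondence onto shifted
neighbours, producing a consistently mislabeled cap with an RMS residual
near 11 mm instead of the jitter-level optimum. The default
`centroid_and_scale` policy (translate centroids together, match RMS
radii) therefore restarts the loop from a fixed coarse rotation grid —
identity plus ±15° and ±30° about seven well-spread axes (the three
coordinate axes and four body diagonals, 29 starts) — and keeps the run
with the lowest final residual. The grid is fixed and the selection
rule deterministic, so results remain reproducible; at 65 points the
cost is milliseconds. This reliably recovers poses up to ~30° of
rotation, which covers realistic head orientations in a scanner.
Disable with `ICPParams(multi_start=False)`.

## Template (template)

The template is the average of several labeled ground-truth caps (12
training subjects in the standard harness, one cap per subject to
absorb head-shape variability). Plain coordinate averaging is only
meaningful in a common frame, so the clouds are aligned first by
generalized Procrustes analysis with similarity transforms; since all
clouds share the 65-label set, correspondence is known and each
alignment is a closed-form paired fit — no nearest-neighbour search.
The consensus starts from the centered first cloud and iterates
align-all/re-average until the mean moves by under 1e-6 mm. The
canonical frame is centered at the electrode centroid with no
rotational normalization: the refinement re-registers the template
anyway, so only the template's shape matters.

The canonical label set is the 64-channel extended 10–20 layout plus
the AFz ground electrode. Other montages are supported only by
supplying a matching template.

## Refinement (refinement)

The template is the *moving* set throughout, registered into detection
space; the equally valid opposite convention would require inverting
the transform before imputing, so this direction is chosen for
convenience, not correctness. Pipeline:

1. ICP #1 registers the template onto the detections.
2. Pruning, exactly two passes: every detection is associated with its
   nearest aligned-template point; within each template bucket only the
   closest detection survives. At most one detection per template label
   remains; duplicates of one electrode resolve to the nearer one. No
   distance gate is applied by default — a far detection is kept if it
   is some template point's closest — but an optional gate
   (`distance_gate`, mm) can reject far pairs.
3. The registration is re-estimated from the surviving pairs. Because
   pruning fixed the correspondence, the default is a single
   closed-form paired fit (`second_icp="paired"`); a full
   nearest-neighbour ICP against the kept detections is available
   (`second_icp="full"`) and agrees on clean data.
4. Every template label without a surviving detection is imputed at its
   re-registered template position, flagged `imputed`; surviving
   detections are passed through unchanged, flagged `measured`.

The output therefore always contains exactly 65 uniquely labeled
points. Final labels come exclusively from the template association;
provisional (network) labels are ignored, because intermediate labeling
can carry chain-shifted errors while the geometry cannot.

## Evaluation (evaluation)

Position error (PE) is the distance from a prediction to its *nearest*
ground-truth electrode, labels disregarded. Predictions with PE above
the threshold (default 10 mm, one cup diameter) are false positives;
all others are true positives, so two detections of one electrode can
both count as good. PE statistics (mean, population std, max) are
computed over true positives only — false positives would otherwise
leak arbitrary distances into the mean. A ground-truth electrode is a
false negative if no true positive has it as nearest neighbour; with 65
predictions against 65 ground truths this makes FP = FN whenever the
true positives cover distinct electrodes, which holds in the intended
regime (errors well below the ~18 mm electrode spacing) but can break
at extreme noise when two true positives share one nearest electrode.
Labeling errors are counted among true positives whose label differs
from their nearest ground-truth electrode's. When multiple volumes are
scored, electrodes are pooled; per-volume metrics are available by
calling `evaluate` per volume.

## Synthetic data (synthetic)

The generator emulates the *output* of the front end, not MR physics:

* **Cap geometry.** A scalp ellipsoid with semi-axes (90, 110, 95) mm
  and the classic proportional-arc construction of the extended 10–20
  system: midline sites every 18° of the nasion–inion arc, a 10%
  circumference ring at 72° inclination, interior sites by spherical
  interpolation at 25/50/75% of each midline→ring arc, plus the
  inferior temporal chains (FT9/FT10, TP9/TP10) at ear level. This is a
  realistic cap geometry (minimum inter-electrode distance ≈ 18 mm),
  not a digitized anatomical standard — the refinement needs plausible
  shape, not anatomical fidelity. Per-subject cap placement differs by
  tangential jitter of 1.5 mm per electrode (points stay exactly on the
  ellipsoid); no published inter-subject figure was available, so this
  was set once at a value giving visible but sub-spacing variability.
* **Detection noise.** An unknown pose drawn as a similarity transform
  (defaults: rotation ≤ 20°, scale 0.95–1.05, translation ≤ 20 mm),
  isotropic Gaussian jitter (default σ = 1 mm per axis, matching the
  few-millimetre error scale observed with real network detections),
  `n_drop` dropped electrodes, `n_spurious` blobs placed 10–30 mm
  outside the scalp, and optional label scrambling. Each noise source
  consumes an independent seed-derived stream, so realizations are
  bit-reproducible and individually controllable.
* **Painting.** Electrodes become digital spheres of radius 5 mm (cup
  diameter 10 mm; the 4 mm cup height is ignored — spheres, as in the
  ground-truth convention) on a 0.9375 mm isotropic grid, later labels
  overwriting earlier on overlap, grid centered on the cloud centroid.

What a green synthetic test does **not** establish: performance on real
PETRA volumes (no MR intensities, no segmentation failure modes such as
merged blobs behind the ears, no anatomically accurate false-positive
geometry), and no claim about the trained network. The synthetic
evidence supports the *structural* claims only: output cardinality,
label correctness under mild noise, and the registration machinery.

## Numerical choices and degeneracies

* Similarity fits require ≥ 3 non-collinear source points; collinear or
  coincident sources raise `DegenerateGeometryError` (second singular
  value ≤ 1e-12 of the first).
* Nearest-neighbour and pruning ties break toward the lowest index.
* NIfTI voxel data must be integer-valued within 1e-3 after rounding.
* Refinement warns below 20 detections and fails below 3.
* A mean-PE bound for the jittered pipeline must respect
  E‖N(0, σ²I₃)‖ = σ·2√(2/π) ≈ 1.596σ: with σ = 1 mm, measured outputs
  cannot average below ~1.6 mm, and the through-volume tests allow
  1.75 mm (jitter plus centroid quantization, which stays within half a
  voxel diagonal ≈ 0.81 mm and typically under 0.1 mm).

## Known limitations

* The refinement presumes the detection cloud is predominantly a cap:
  with fewer than ~20 detections or adversarial outlier structure the
  first ICP can mis-register, and no confidence score is attached to
  the output.
* Imputed positions inherit template shape: for a subject whose cap
  deviates strongly from the average, imputed electrodes are less
  accurate than measured ones (they are flagged, so downstream users
  can weight them).
* Rotations far beyond the multi-start grid's coverage (≫ 30°,
  e.g. upside-down poses) are not guaranteed to converge; the cap's
  near left–right symmetry makes ~180° yaw genuinely ambiguous without
  anatomical landmarks.
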
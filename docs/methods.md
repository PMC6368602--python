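# Methods

## Problem and pipeline

filtrack tracks curvilinear structures — growing actin filaments,
contractile rings, fibers of a 3D biopolymer network — through time-lapse
fluorescence images. The pipeline has three stages per the design of
temporally consistent network tracking:

1. **Detection.** Each frame's centerlines are extracted independently.
2. **Local matching.** Curve segments dissected at network junctions are
   re-linked (spliced) so that the partition of the network into curves is
   smooth in space and consistent with the previous frame.
3. **Global matching.** All curves of all frames become vertices of a
   k-partite DAG; tracks are the minimum path cover of that graph, found
   exactly by reduction to minimum-cost bipartite matching.

## Detection

The original approach evolves stretching open active contours; this package
deliberately replaces that machinery with a ridge tracer that reproduces its
input/output contract on the synthetic validation images:

- Gaussian pre-smoothing at `smoothing_sigma` (default 1.0 px in 2D,
  1.5 px in 3D — the thicker 3D tubes need the extra smoothing for a
  frame-stable skeleton).
- Thresholding at `ridge_threshold` and topological skeletonization
  (2D and 3D thinning from scikit-image).
- Decomposition of the skeleton into inter-junction **branches**: skeleton
  voxels with ≥3 neighbors are junction voxels, merged into junction nodes;
  each maximal ordinary-voxel chain between nodes or free ends becomes one
  polyline, extended to the junction-node centroid so incident tips meet.
  Terminal branches shorter than 4 voxels are pruned as spurs; pure cycles
  are traced as near-closed curves. Curves intentionally *stop* at
  junctions — re-linking them is the local-matching stage's job.
- Sub-pixel refinement: every point moves to the intensity-weighted
  centroid of the smoothed image sampled (cubic interpolation) on a ±3 px
  grid transverse to the local tangent; the correction is projected off the
  tangent and clipped to 1 px per iteration (3 iterations). On noiseless
  renders this brings centerlines to ~0.2 px of the true curve.
- Arc-length resampling at `point_spacing` (1 px) and removal of curves
  shorter than `min_curve_length`.

Junction detection then clusters collision points (any point of one curve
within `junction_radius` = 2 px of a non-adjacent point of another, or of
the same curve at least 4 index positions away) by single linkage within
twice the radius. Dissection cuts every curve passing within twice the
junction radius at its closest point, duplicating the cut point; each
resulting tip is assigned to its nearest junction only, so no tip can be
paired at two junctions. Near-closed open curves whose tips face each other
(gap ≤ `loop_close_gap`, outward tangents > 120° apart) are flagged as
rings, which is how constricting contractile rings are represented.

## Local matching

At each junction a complete bipartite graph over two copies of the incident
tips is solved by the Hungarian algorithm with dissimilarity
`D = D_ori + D_tem ∈ [0, 2]`:

- `D_ori = 1 − θ/π` with θ the angle between outward tip tangents
  (1 when both tips belong to the same curve). Tip tangents are
  least-squares line fits over the outermost min(5, ⌈n/2⌉) points —
  single-segment differences are noise-dominated.
- `D_tem` compares each curve's one-way distance `f` to its closest,
  already-spliced curve of the previous frame: 1 when the two closest
  previous curves differ, otherwise `|f_i − f_j|` clamped to [0, 1] so the
  same-predecessor branch can never exceed the different-predecessor
  penalty. `f` weights nearest-point distances by `exp(−|cos φ|)` where φ
  compares the local tangents, so aligned nearby curves score lower than
  perpendicular ones. The first frame has no predecessor and `D_tem` is 0.

A pair is accepted only when matched in both directions (symmetrization),
when its total cost is below `pair_cost_max` (0.9), **and** when
`D_ori < 1/3`, i.e. the splice continues the curve within 60° — the same
turning limit the tracer uses. Without the orientation gate, leftover tips
pair promiscuously whenever the temporal term cannot arbitrate (any tip
angle over ~18° clears 0.9 on its own), which over-merges distinct fibers
in the first frame and then propagates inconsistency. Ties are broken by
ascending curve id everywhere, making the stage deterministic.

Accepted pairs are spliced transitively; chains closing on themselves
become rings. The dissected segments are retained alongside the spliced
curves: with *grouping* enabled, global matching tracks the spliced curves
(whole filaments — appropriate for elongating filaments that extend past
crossings); with grouping disabled it tracks the inter-junction segments
(appropriate for network deformation analyses). Local matching runs in
both modes, because it is what keeps the detected topology consistent over
time.

## Global matching

Curve dissimilarity is the symmetric average nearest-point distance; the
edge weight between a curve in frame l and one in frame m > l is
`exp(c (m − l − 1)) · d`, saturated at η (20 px by default; c defaults to
1/frame). Edges are built for frame gaps up to `max_frame_gap` (3) — longer
gaps saturate at η by construction and carry no information. The minimum
path cover is solved exactly: a square cost matrix with one row (as
predecessor) and one column (as successor) per curve, absent pairs at η,
Hungarian assignment, and matched pairs *strictly below* η become successor
links. A matched weight equal to η means "indistinguishable from
unrelated", which is the only reading under which isolated curves form
zero-length tracks. Tracks may skip frames: a structure missing for a few
frames re-links when the gap-inflated weight stays below η.

## Synthetic data

**2D elongating filaments.** A filament is a walk of constant step
δ = 0.05 px whose heading turns by N(0, σ_θ = 0.015 rad) per step, giving
persistence length l_p = δ/σ_θ² = 222 px (a 76 nm pixel for actin's 17 µm
persistence length). Per frame, segment addition is attempted 300 times,
each accepted with probability 0.8 — 240 segments ≈ 12 px of growth per
frame on average, growth from one end only (barbed-end growth). Each
segment carries brightness 5 jittered multiplicatively within ±10%;
rendering deposits the walk points bilinearly, convolves with a Gaussian
kernel of σ = 1.5 px and adds per-pixel Uniform(0, 10) noise. New filaments
nucleate at Poisson(0.25)/frame, aimed loosely toward the image interior so
most growth stays on canvas; the default movie is 15 frames of 256×256 px
with 5 initial filaments. The stated acceptance process implies a growth
std of ≈0.35 px/frame; a figure of 1.5 px/frame sometimes quoted for this
construction is not reproducible from Binomial(300, 0.8) counts and is not
enforced.

**3D deforming fiber network.** A geometric stand-in for a
Brownian-dynamics bundle network: ~30 quasi-straight fibers (unit steps,
3D angular wiggle σ = 0.02/step, length 40 ± 10 px) placed uniformly
throughout a 100-px box, growth stopping at the walls so the spatial
density is homogeneous — concentrating fibers in the interior makes them
overlap and is not representative of the imaged networks. Rendering
deposits points at 0.3 px spacing trilinearly, convolves with an
anisotropic Gaussian PSF (default 1.5 px isotropic) and adds
Uniform(0, 10) voxel noise. Deformation applies a fixed matrix per frame —
simple shear with λ = 0.05 (x′ = x + λz) or a 3.5° rotation about z —
**about the box center**, so the network stays in view; every analysis
below operates on direction/axis *vectors*, which transform by the bare
matrix regardless of the centering offset, and the generator's
ground-truth coordinates satisfy the matrix-power identity exactly.

What these generators do *not* emulate: photobleaching, depth-dependent
PSF, filament severing or depolymerization, bundling, merging/splitting
events, and camera gain statistics. Passing tests therefore demonstrate
correctness of the tracking and analysis machinery under controlled
conditions, not robustness to every artifact of real microscopy data.

## Analyses

- **Elongation.** Per-track length changes per frame are collected;
  samples with |dL| < 3 px (the stall peak from curves that fail to
  advance past a junction) are excluded, and a Gaussian is fitted by least
  squares to the 1-px histogram of the rest. The histogram fit locates the
  main peak and ignores the sparse far outliers that splice errors produce,
  which destroy a plain maximum-likelihood fit; when fewer than 4 bins are
  populated the sample moments are used directly.
- **Persistence length.** `⟨cos Δθ(s)⟩ = exp(−s/2l_p)` (the 2D decay law)
  fitted through the origin on −log correlation. One walk provides
  effectively a single independent correlation sample at separations
  comparable to its length, and 1/slope of a noisy near-zero slope is
  strongly biased, so the validation pools the correlation across 500
  filaments before fitting, restricted to the well-sampled decay
  (correlation ≥ 0.4).
- **Constriction.** Ordinary least-squares slope of length versus frame.
- **Nematic order.** S is the largest eigenvalue of
  Q = 3/2⟨u⊗u⟩ − ½I over per-segment unit directions (2D directions are
  embedded with z = 0); the eigenvalue construction makes S independent of
  the sample's overall orientation.
- **Affine recovery.** Each tracked snake contributes an axis pair
  (frame k, frame k+1). Triplets of unit frame-k axes form X; the frame-k+1
  axes, scaled by the same frame-k lengths, form X′; the triplet estimate
  is A = X′X⁻¹ and estimates are averaged (mean ± SE) over 10 triplets
  drawn without replacement while tracks last. Scaling X′ by the *frame-k*
  length rather than normalizing it makes the solve exact for any affine
  map on noiseless tracks; normalizing both sides cannot recover A exactly
  even without noise. On detected (noisy) tracks the workflow additionally
  applies axis-pair hygiene: both curves trimmed to their mutually
  overlapping extent before the axis is taken (detection does not recover
  identical sub-extents in both frames, and on a wiggly fiber different
  sub-extents genuinely have different axes), principal-component extent
  axes, rejection of probable mislinks (pair distance > 3 px), short axes
  (< 8 px) and extent mismatches (> 15%), and triplets restricted to
  condition number ≤ 2.5 — the triplet solve amplifies axis noise by the
  condition number, and second-order noise terms bias ill-conditioned
  solves.
- **Angular deviation ψ** between a track's axis at frame k+1 and the
  imposed-matrix image of its frame-k axis, axis sign ignored (ψ ∈ [0°, 90°]).
- **Angle drift.** Azimuth of an axis taken modulo 180°, frame-to-frame
  differences unwrapped into (−90°, 90°]; polar angle folded into [0°, 90°].
- **Precision/recall.** Detected curves map to the ground-truth filament
  covering the majority of their points within 2 px; a predicted link is a
  true positive when both endpoints map to the same filament, precision is
  TP/P over predicted links and recall TP/(TP+FN) against the generator's
  identity correspondences.

## Validation scales and known limitations

The end-to-end validations run at desk scale: a 15-frame 256² px movie
with ~8 filaments for elongation, and 100-voxel, ~30-fiber stacks for the
deformation analyses. At these scales the elongation rate is recovered to
~0.2 px/frame, rotation drift to ~0.1°/frame and median ψ is below 1°.
The recovered shear matrix is the tightest readout: with ground-truth
axes the solve is exact, and the residual element scatter (~±0.01 on the
xz shear element, up to ~±0.04 on other elements) is set entirely by the
angular noise of detected axes (~0.5–1°), which in turn reflects the
simplified detector's endpoint jitter at signal-to-noise ≈ 3. The full
active-contour refinement that the original software uses for detection
would reduce this further; it is intentionally out of scope here.

Other limitations: merging/splitting filaments are not modeled (each curve
has at most one successor); matching uses only one previous frame of
temporal context; interoperability with external curve-file dialects is
best-effort via the text format documented in `filtrack.io`.
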
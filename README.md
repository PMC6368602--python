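# filtrack

Tracking of curvilinear biopolymer networks — elongating actin filaments,
constricting contractile rings, deforming 3D fiber networks — in 2D and 3D
time-lapse fluorescence images.

Filament-like structures collide, cross and span network junctions, so
tracking them is harder than tracking point-like objects: the way a network
is partitioned into curves must stay consistent from frame to frame, or
temporal correspondence becomes meaningless. filtrack addresses this with
three stages:

1. **Detection** — per-frame centerline extraction by ridge tracing
   (smooth → threshold → skeletonize → branch decomposition → sub-pixel
   transverse refinement).
2. **Local matching** — curve segments dissected at junctions are
   re-spliced by minimum-cost bipartite assignment of their tips, with
   dissimilarity `D = D_ori + D_tem`: `D_ori = 1 − θ/π` penalizes
   non-smooth continuations (θ = angle between outward tip tangents) and
   `D_tem` compares each segment's one-way distance
   `f(u, r) = ⟨min_z‖y − z‖ · e^(−|cos φ|)⟩` to its nearest curve of the
   previous frame, enforcing a temporally consistent topology.
3. **Global matching** — every curve of every frame is a vertex of a
   k-partite DAG with forward edges weighted
   `w = e^(c(m−l−1)) · d(v_i^l, v_j^m)`, saturated at η; `d` is the
   symmetric average nearest-point distance. Tracks are the minimum path
   cover of this graph, solved exactly as a minimum-cost bipartite matching
   (Hungarian algorithm) over two copies of the vertex set. Tracks may
   skip frames and may consist of a single curve.

The package also ships the two synthetic-data generators used to validate
the method — TIRFM-like movies of elongating semiflexible 2D filaments
(persistence length `l_p = δ/σ_θ² = 222 px`), and 3D fiber networks under
per-frame shear (`x' = x + λz`, λ = 0.05) or rotation (3.5° about z) —
plus analyses: elongation-rate histograms, constriction rates, the nematic
order parameter (largest eigenvalue of `Q = 3/2⟨u⊗u⟩ − ½I`), affine
deformation recovery from tracked snake triplets (`X' = AX`), angular
deviation ψ, axis-angle drift, and precision/recall against ground truth.

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.

## Worked example

Simulate a 10-frame movie of elongating filaments (growth 12 px/frame),
track it, and measure the elongation rate:

```sh
$ filtrack simulate2d --seed 1 --frames 10 --size 192 --out movie
wrote 10 frames to movie

$ filtrack track movie/images.tif --out movie/tracks.txt
19 tracks over 10 frames -> movie/tracks.txt

$ filtrack analyze movie/tracks.txt --elongation
rate_mean_px_per_frame  rate_sigma  n_used  n_excluded
12.278                  1.443       57      30

$ filtrack evaluate movie/tracks.txt movie/truth.txt
TP=85 P=87 FN=0
precision=0.9770 recall=1.0000
```

The analyze step histograms the per-frame length change of every track,
drops the small peak near zero (curves that stalled at a crossing) and fits
a Gaussian: the fitted mode of 12.28 px/frame recovers the generator's
imposed 12 px/frame growth, with σ ≈ 1.4 px of frame-to-frame fluctuation.
`evaluate` scores the tracker's frame-to-frame links against the
generator's ground truth: 85 of 87 predicted correspondences connect
curves of the same true filament.

The same workflow runs on 3D stacks (a directory of per-timepoint TIFFs);
`--no-grouping` tracks inter-junction segments instead of whole spliced
filaments, which is the right mode for network-deformation analysis:

```sh
filtrack simulate3d --seed 1 --mode shear --steps 4 --out net
filtrack track net/stacks --no-grouping --out net/tracks.txt
```

Library use mirrors the CLI: `filtrack.simulate2d.simulate_sequence`,
`filtrack.track_images`, `filtrack.analyze.*`, and
`filtrack.workflows.*` for complete experiment drivers.

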
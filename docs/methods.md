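# Methods

`neuritree` extracts individually labelled, directed rooted neuronal trees
(soma → neurites, with crossings resolved) from 2D fluorescence images of
multicellular neuronal cultures, and computes background-corrected
intensity profiles and axon-initial-segment (AIS) statistics per neuron.
This note describes the model behind each stage, the parameters that
matter, the synthetic data the package is validated on, and the numerical
and design choices that were genuinely open.

## The model: a neuron as a directed rooted tree

A neuron in a culture image is modelled as a rooted tree: the soma is the
root and every neurite node has exactly one path back to it. Extracting
these trees — rather than an undifferentiated network graph — is what makes
single-cell profiling possible: every fluorescence measurement along a
neurite can be indexed by its arclength distance from its own soma.

The central difficulty is that maximum-intensity projections of thin
confocal stacks (10–30 optical sections) collapse the z axis, so neurites
of *different* neurons appear to intersect. The tracer resolves this with
an orientation-continuity principle: neurites change direction smoothly, so
a trace that would have to turn sharply at a junction is about to jump onto
the crossing neurite, and is forbidden from doing so.

## Pipeline stages

### Projection

Confocal stacks are projected to 2D by maximum intensity (MIP, the default
for tracing) or average intensity (AIP). Working pixel size is 0.28 µm/px
by default (63× oil objective at 512 × 512).

### Denoising (optional)

Photon counting makes the noise Poisson. The image is variance-stabilised
with the Anscombe transform, the detail coefficients of an undecimated
(stationary) wavelet transform (`sym4`, 3 levels) are soft-thresholded at
`k·σ̂` with σ̂ from the robust median rule on the finest diagonal band, and
the transform is inverted. Default `k = 2`: soft thresholds are
conventionally set lower than hard ones, and at `k = 2` denoising a noisy
bar phantom reduces RMSE against the clean image while `k = 3` visibly
attenuates thin neurites. On high-SNR phantoms plain thresholding already
segments essentially perfectly, so denoising is optional and off for
noise-free phantoms; it matters on real data with lower SNR or structured
background.

### Segmentation

Per-pixel features are a multiscale bank (scales 1, 2, 4 px): an isotropic
Laplacian-of-Gaussian plane, eight oriented elongated Gaussian
second-derivative planes (tube detectors), and a Gaussian-smoothed
intensity plane per scale. The intensity plane is necessary: on the flat
interior of any bright region every derivative feature vanishes, so
derivative-only features cannot separate such interiors from flat
background. A linear-kernel SVM (balanced subsampled pixels, standardized
features) is trained once per image type on (image, truth-mask) pairs; an
Otsu-threshold fallback serves model-free runs. Components under 20 px are
removed and holes under 10 px filled, because seeding assumes connected
tubular foreground.

### Soma detection: directional ratio

At each foreground pixel, line filters of length 15 px are evaluated on the
binary mask over 16 orientations; the **directional ratio** is min/max of
the oriented responses. Blobs wider than the filter score ≈ 1 in every
direction; a thin tube scores ≈ width/length. Pixels scoring ≥ 0.6 are
opened (disk 2) into soma cores; each core grows back to the soma boundary
by a bounded geodesic front (≈ half a filter length of steps) restricted to
pixels scoring ≥ 0.3, then an opening at the neurite scale (disk 4) cuts
the stumps the front crept into. Two shape gates reject neurite-tangle
blobs that pass the area threshold: a genuine soma contains a near-isotropic
interior point (directional-ratio maximum ≥ 0.7) and is at most mildly
elliptical (area ≤ 1.65 × its inscribed-disk area; an ellipse of aspect 1.5
gives ≈ 1.55). Touching somas are split by a marker-controlled watershed on
the lightly smoothed interior distance transform with h-maxima markers
(h = 3 px; two equal disks overlapping at 1.5 radii have a saddle ≈ 0.34 r
deep, well above h).

Filters are applied to the mask, not intensities: the descriptor measures
geometry and is then robust to staining variation. The detection guarantee
weakens for somas whose minor radius is below about half the filter length;
the filter length is configurable for other magnifications.

### Tree extraction

**Initialization.** The soma mask is notionally scaled about its centroid by
rates 1.1/1.2/1.3; for a convex soma, scaling by rate r offsets the
boundary by (r − 1)·radius, so the two rings (between rates 1.0–1.1 and
1.2–1.3) are implemented as distance-from-soma bands at those offsets with
a floor of a few pixels — a literal sub-pixel ring on an 8–15 px soma
fragments on a noisy mask. Intersected with the foreground, the rings cut
each neurite into an inner and an outer stub; stubs are paired by mutual
nearest angle about the centroid, the inner→outer direction is the initial
orientation θ₀, and the S₀ boundary point nearest the inner stub is the
start point. Two gates drop stubs of *foreign* neurites passing near the
soma: an inner stub must touch the soma boundary (min distance ≤ 1.2 px)
and the paired direction must be within 60° of radial (a neurite leaves its
soma roughly radially; a tangential passer-by would otherwise seed a theft
trace).

**Seeding.** The Euclidean distance transform Df of the mask (exact; zero on
background) is convolved with the 3 × 3 sharpening kernel (center 2,
surround −1/8), the response is min–max normalized over the foreground and
thresholded at τ = 0.16. Candidates must also be ridge points (3 × 3 local
maxima with ties kept, so plateaus survive): the sought seeds are the local
maxima of Df along the centerline, and off-ridge pixels on wide structures
otherwise pass the threshold. Candidates are thinned greedily in decreasing
Df order under a symmetric clearance-ball rule (no seed within
max(Df(s), Df(t)) of another). Gaps are then repaired twice over: skeleton
stretches not covered by any ball, and consecutive chain seeds whose balls
fail to intersect, are re-seeded from locally renormalized responses
(ridge requirement dropped inside repair boxes — staircase transitions of
discrete diagonal tubes have no strict local maxima — with candidates held
near the local clearance level). After repair, consecutive seeds along
every skeleton path have intersecting balls up to one diagonal lattice
step, allowing multi-seed bridges at junctions where chain order is
ambiguous.

**Tracing.** All somas' neurite fronts advance simultaneously in round-robin
(one seed per front per round; somas ordered by descending area within a
round; ties broken deterministically by distance, then angular deviation,
then seed index). Simultaneous propagation is essential in multicellular
images: a sequential per-neuron loop lets an early tree wander onto and
fully consume a later neuron's neurite. Each step searches a rectangle of
length 10 px (growing by 2 px over up to 10 rounds) aligned with the
expected orientation — θ₀ at the first step, the direction of the last two
trace points afterwards — and width max(3, 2·Df) so the window spans the
local diameter. If the axis rectangle is empty, rectangle pairs sweep
outward at ±k·π/16 with 5% length decay per step, up to the hard fan limit
of 2π/5; a candidate deviating more than the limit is never accepted,
however close. This is the crossing-resolution mechanism. Seeds are
consumed by the first front that claims them; traces terminate when all
rounds fail.

Two extensions handle situations the basic step does not:

* **Corridor jump.** Where neurites run merged or parallel, only one seed
  chain exists and the first front through consumes it; the second front
  would terminate although its neurite continues. When the fan search fails
  — or finds only a seed deviating more than π/8 while a clean dead-ahead
  continuation exists — an established front (≥ 3 nodes) may connect to an
  alive seed in a narrow forward cone (half-angle π/8, ≤ 45 px) provided
  the straight path stays ≥ 90% on foreground.
* **Branch spawning.** When a search round finds alive seeds in disjoint
  angular sub-fans (separated by more than one fan step), the
  nearest-to-axis seed continues the neurite and each other seed spawns a
  child branch — unless alive seeds continue *behind* the candidate's
  direction, which marks an X-crossing (a through-going neurite) rather
  than a Y-bifurcation (which only extends forward).

Short soma-level traces (configurable, off by default) that duplicate
another tree's corridor can be pruned; contested assignments are recorded
in a conflict log (nodes within 2 px of another tree's nodes).

**Tiling.** For large stitched images, somas are grouped by single-linkage
proximity clustering (cutoff 150 px) and each group is processed in its own
rectangle (soma bounding box plus an overlap margin). Every soma belongs to
exactly one tile; results merge with globally unique ids, and trees
touching a tile border are flagged. Tiled and untiled runs agree exactly
when each tile holds its neurons' full extent, i.e. when the overlap margin
covers the neurite reach.

### Intensity profiles and AIS statistics

Each traced neurite is resampled at 1 px arclength steps; the raw value is
the bilinear interpolation of the target channel. Local background at each
sample is the mean of a pair of 3 × 3 windows centred on the perpendicular
to the local trace direction, 2 px beyond the segmented structure edge on
each side; a window overlapping foreground is pushed outward (≤ 15 px),
a single clear window is used if only one side clears, and the global
median background is the last resort. Corrected = raw − background, not
clamped at zero (clamping would bias the integrals; configurable).

AIS statistics use the first 70 px (19.6 µm) of the axon: the area `A_AIS`
(trapezoidal integral of the corrected profile), the variance `V_AIS`, and
the amplitude H of the least-squares fit of
g(x) = H·exp(−(x − µ)²/(2σ²)) (initialized at (max, argmax, interval/6),
σ bounded in [1, 70]). The axon is the neurite with the highest mean
corrected target intensity over its first 70 px (Na⁺-channel enrichment at
the AIS); neurons without a profileable axon are flagged and excluded. The
polarity ratio `R_AD = A_AIS / A_den` uses the mean integral of the two
non-axon neurites whose radius is closest to the axon's. Group differences
are tested per metric with a two-tailed two-sample t-test.

### Evaluation

A true neurite is a true positive when the predicted tree of the *same*
neuron (somas paired Hungarian-style on root distance, ≤ 20 px) covers
≥ 80% of its centerline within 3 px; uncovered true neurites are false
negatives; predicted neurites that mostly follow a different neuron's
neurite, or no true structure at all, are false positives. Sensitivity
TP/(TP+FN), precision TP/(TP+FP) and Dice 2TP/(2TP+FN+FP) follow. The
80%/3 px coverage proxy replaces expert visual assessment and is
configurable. Coverage is measured against the full tree polyline
including the root-to-neurite edges, which are part of the rooted-tree
topology. A recorded crossing is *solved* when the distal part of both
involved neurites (beyond the crossing arclength) is covered by the correct
neuron's prediction.

## Synthetic data

The phantom generator emulates MIPs of sparse cultures at 0.28 µm/px:
somas are filled ellipses (radius 8–15 px, aspect ≤ 1.5) placed with at
least 60 px of clearance (low-density plating), neurites are smooth random
curves (tangent-angle increments ≤ 0.03 rad/px) of half-width 1–3 px
emanating radially, rendered without anti-aliasing so the ground truth is
unambiguous. Background is a constant (20) plus a linear gradient
(amplitude 10); foreground intensity is 150 per channel; photon noise is
Poisson. Every image carries its exact truth: per-neuron centerline trees,
a label image, soma masks and the noiseless field.

Forced crossings add dedicated *crossing neurons*: a point on an existing
neurite is chosen, and the new neuron's soma is placed 60–110 px back along
the crossing direction so its first neurite runs straight through the point
at the sampled angle (45–90° by default) before resuming bounded curvature.
Crossing neurons are generated after, and independently of, the base
neurons, so adding crossings never changes the base trees — only the
rendered overlap.

Arclength-dependent signals for profiling tests are painted by assigning
each tube pixel the value of its *nearest centerline sample* (max-combining
disks would dilate the profile along arclength and bias the painted bell).

What the phantoms do **not** emulate: the microscope point-spread function
and anti-aliased tube boundaries, varicosities and spines, intensity
variation along a neurite, fasciculation, loops, and densities above ~6
neurons per 143 µm field. Passing the phantom suites therefore demonstrates
the geometric and algorithmic correctness of the pipeline under controlled
conditions, not its performance on any particular real dataset.

### Reference suites

* **Standard suite**: 12 images, 49 neurons in total (2–6 per image,
  matching a 12-image/49-neuron validation load), 8 forced crossings
  ≥ 45°, Poisson noise at high SNR.
* **Crossing suite**: single-host phantoms with one forced crossing each at
  controlled angles {45°, 60°, 90°}, three per angle. Shallow angles
  (< 20°) are exercised separately without a pass requirement — at grazing
  incidence the assignment is ambiguous even for a human annotator.
* **Group-regime study**: 12 + 12 single-neuron phantoms whose target
  channel carries either a Gaussian bell on the axon
  (H = 250, µ = 35 px, σ = 10 px; control-like) or a flat axon signal at
  the dendritic level (30; inhibitor-like), over background 15 with Poisson
  noise; the structural channel is traced by the full pipeline and the
  target channel profiled along the traced neurites. The painted amplitudes
  put the polarity ratio near 3 in the bell regime and near 1 in the flat
  regime by construction.

Problem sizes throughout (512 × 512 images, 12-image suites, n = 12 per
group) are the package's reference configuration; all are parameters.

## Numerical choices and degenerate inputs

* Coordinates are 0-based (row, col) internally; SWC output is (x, y, z=0)
  in µm at the configured pixel size, soma root type 1, axon 2, dendrite 3,
  unassigned 0. SWC has no neurite-grouping concept, so a neurite with a
  mid-chain branch point round-trips as two chained neurites with the same
  graph.
* The seed threshold τ applies to the *normalized* sharpened response (the
  raw response is in pixel units where 0.16 would be meaningless); the raw
  interpretation is available via configuration.
* Ties in the seed search resolve by distance, then angular deviation,
  then seed index; suppression visits candidates by decreasing Df with
  (row, col) tie order — extraction is fully deterministic.
* Empty masks yield empty seed lists; an all-foreground mask has no
  distance transform and is rejected; a blank image segments to an empty
  mask; a soma with no neurites yields a soma-only tree.
* Gaussian-fit non-convergence is flagged (`fit_ok=False`) rather than
  raised; `R_AD` is undefined (None) when the dendritic area is ≤ 0.

## Known limitations

* Tracing quality degrades with neuron density, as interleaved arbors make
  assignment ambiguous; the conflict log exposes contested nodes.
* Crossing resolution at angles below ~20° is unreliable by design of the
  angular-gate mechanism.
* Somas with minor radius below about half the directional-filter length
  may be missed at the default scale.
* Trees only: loops and anastomoses are not representable; 3D tracing is
  out of scope (the pipeline operates on projections).
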
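# Methods

This note records the models, numerical choices and known limitations
behind `gliamorph`, in the order data flows through the package.

## Image preprocessing (`imgprep`)

Z-stacks are reduced by maximum-intensity projection. Background is
estimated as the projection smoothed with a Gaussian of σ = 25 µm
(configurable) and subtracted with clipping at zero; an optional annular
FFT band-pass can then sharpen contours (both the band limits and the
on/off switch are configuration — the chain tolerates either order of
emphasis, and the default is off because the Gaussian subtraction alone
recovers synthetic ground truth to Jaccard ≥ 0.98). Binarization uses
Otsu's threshold; a 3×3 binary opening removes speckle before component
analysis.

Single cells are isolated as 8-connected components that (a) do not touch
the image border, (b) fall in a 50–5,000 µm² area window (defaults chosen
to exclude debris and merged clusters at typical 20–40× magnifications),
and (c) have bounding boxes that, after a 2-px margin expansion, do not
intersect any other component's box — the operational meaning of
"non-overlapping". When more survivors exist than requested, selection is
by descending area with a deterministic (row, col) tie-break. Each cell is
cropped with 2 px of padding into a `CellMask` carrying its pixel
calibration and offset.

## Morphometric profile (`morpho`)

Sixteen features per cell; lengths and areas are converted to µm via the
pixel size, so every feature is either physical (µm, µm²) or dimensionless.

**Box-size ladder.** Powers of two from 2 px up to min(h, w)/4, requiring
at least four ladder points; tight crops that cannot host four points
extend the ladder to min(h, w)/2. Both box-counting operations accept an
explicit ladder (e.g. powers of three for exactly self-similar fixtures).

**Fractal dimension** is the least-squares slope of log N(s) against
log(1/s), computed on the outline set (foreground minus its 4-connected
erosion) by default — the usual convention for contour complexity — with a
`filled` mode for sanity checks and space-filling fixtures. Whether the
original morphometric literature used outline or filled sets is rarely
stated; outline is the default here and the switch is exposed.

**Lacunarity** is the gliding-box statistic Λ(r) = var(m)/mean(m)² + 1
over all stride-1 r×r windows (exact window sums via an integral image),
aggregated as the unweighted mean over the ladder. A fully filled image
gives exactly 1 at every r.

**Hull and shape metrics.** Cell area is the foreground pixel count; the
cell perimeter is the length of the 0.5-level contour polygon after 1-px
Douglas–Peucker simplification — raw staircase contours overestimate the
perimeter of smooth shapes by ~4%, biasing disc circularity to ≈0.91,
while the simplified polygon restores it to 0.99 without distorting
squares (0.798 vs π/4 ≈ 0.785). Hull area and perimeter come from the
convex hull of the raw contour. Circularity is 4πA/P²; density and
roughness are the cell/hull ratios of area and perimeter respectively.

**Skeleton statistics.** The topology-preserving skeleton is decomposed
into branches — maximal paths between endpoints and junction pixels in the
8-connected pixel graph — with step lengths 1 px (axial) and √2 px
(diagonal). Leaf branches shorter than 2 µm hanging off a junction are
pruned as rasterization spurs (threshold configurable). Total, maximum and
mean branch lengths are the process-length features; straightness is the
unweighted per-branch mean of endpoint Euclidean distance over path
length. The per-branch mean is the one feature visibly sensitive to
discretization: thinning is not exactly rotation-equivariant near
junctions, so a 90° rotation can move `mean_process_length_um` by ~15%
while every other feature stays within 5%.

**Sholl profile.** Circles of radius step, 2·step, … (default step 2 µm)
are centred on the soma centroid; the count at radius r is the number of
8-connected runs of skeleton pixels in the annulus of half-width √2/2 px —
that width guarantees no 8-connected process can cross the circle between
ring pixels. `sholl_max_counts` is the maximum over radii.

**Cell body.** The soma is the largest component surviving a morphological
opening with a 2-µm disc (radius configurable; this automates a
delineation that is often manual). Its area is the Shoelace-formula area
of its outer contour polygon.

**Scale and units.** All computation happens in pixels and converts at the
end, so the profile is exactly equivariant under calibration changes when
the µm-valued processing parameters (Sholl step, pruning and opening
radii) are scaled with the pixel size — the physically meaningful
statement of unit consistency.

## Classification (`classify`)

The multimodality index of a feature is the Sarle-type bimodality
coefficient with bias-corrected sample skewness g₁ and excess kurtosis g₂:

    b = (g₁² + 1) / (g₂ + 3(n−1)² / ((n−2)(n−3)))

clipped to [0, 1]. Its asymptotic anchors: 1 for a symmetric two-point
distribution, 1/3 for a normal, 5/9 for a uniform. Features are min–max
scaled across the analyzed population; the amoeboid (ramified) index is
the MMI-weighted **mean** of the scaled features whose direction label is
amoeboid (ramified). A weighted mean rather than the raw weighted sum puts
the two indices on a common [0, 1] scale even though the direction sets
have 5 and 11 members — raw sums over sets of unequal size are not
comparable, which is what the label rule requires; `aggregate="sum"`
restores plain sums for sensitivity analysis. Ties go to ramified, the
conservative choice when the scientific question is whether a treatment
*reduces* amoeboid counts. The shipped reference MMI table is the default
for reproduction; `mmi_table="fit"` re-estimates weights from the data at
hand (direction labels are kept from the reference, since directions
encode biology, not the sample).

## Clustering and embedding (`cluster`)

Features with MMI ≥ 0.5 (five in the reference table) are z-scored
(min–max optional) and clustered agglomeratively under the Ward objective
with Euclidean distances. The tree is cut at every k in 2–8 (the scanned
range is configurable) and the cut with maximal mean silhouette wins. PCA
is centred, with the sign convention that each component's
largest-magnitude loading is positive; a warning fires when PC1+PC2
explain less than 70% of the variance, the conventional adequacy bar for a
two-component morphology map. Cluster centroids, when requested, are
computed in PC score space.

## Behavior (`behavior`)

Pose tables use the common 3-header-row CSV dialect (scorer / bodyparts /
coords with x, y, likelihood per bodypart). Frames with likelihood < 0.9
are dropped; gaps of ≤ 5 frames are linearly interpolated, longer gaps are
held at the last valid position. Distance and average speed come from the
filtered path — making them exactly invariant to rigid motions and linear
in the calibration — while the maximum speed is computed on 3-frame
median-smoothed positions, since a single-frame statistic is the one place
tracking spikes bite.

Straight-walk windows are 1-s spans with mean hip speed ≥ 3 cm/s and net
heading change ≤ 20°/s (the quantitative reading of "straight walking"),
ranked by net-displacement-over-path-length and greedily selected without
overlap, five per animal by default. The gait signal is the unsigned
interior nose–hip–tail angle in [0°, 180°]; each window is fitted with
A·cos(2πft + φ) + c, f bounded to [1, 8] Hz. Initialization does a coarse
0.05-Hz grid scan solving the conditionally linear subproblem at each
candidate frequency before the nonlinear refinement — a single
spectrum-peak start is unreliable on 30-sample windows, where the
likelihood surface in f is multimodal. |A| is the amplitude; per-mouse
amplitudes are averaged over windows. Grip strength is mean force over
trials divided by body weight in grams.

## Quantification (`quant`)

The ROI is axis-aligned, centred on a supplied pixel coordinate (injury
localization is deliberately out of scope), default 500 × 500 µm
(0.25 mm²). Boundaries are half-open (left/top inclusive) so tiled ROIs
partition points exactly. Density is centroids-in-ROI per mm²; coverage is
the percentage of ROI pixels above either a fixed recorded threshold
(emulating manual thresholding, which is otherwise unrecoverable) or Otsu.

## Expression (`expression`)

Replicate Cq values are averaged per sample and gene before
ΔCq = Cq(target) − Cq(reference); relative expression is 2^(−ΔCq) with
amplification efficiency fixed at 2, and fold change divides by the mean
relative expression of the control group — so the control mean is 1 by
construction, and adding any constant to all Cq values of a sample cancels
exactly. Whether fold change should normalize per-sample (ΔΔCq against a
paired control) or against the control-group mean is ambiguous in common
usage; the group-mean convention is implemented and documented here.

## Synthetic data (`synth`)

The generators emulate the *structure* of the study's raw data, not its
optics. Every generator is a pure function of its spec and seed.

**Cells.** Ramified: a 4-µm soma disc with 5 primary processes, each a
12-step random walk (2.5 µm steps, 18° heading jitter confined to a ±45°
sector of the launch angle so sibling processes cannot merge — this is
what guarantees each generated tip survives as a skeleton endpoint),
branching with probability 0.08/step to depth 2, rasterized at 1 px and
dilated to ~3 px. Amoeboid: an 11.5-µm soma with low-order radial
harmonics (lumpy but compact outline, elongation 1.05). Rod: a 5-µm soma
elongated 3.5× with two 4-step polar processes. Defaults were chosen once
so the generated classes embody the documented biology — activated
amoeboid cells have larger total area and cell-body area, ramified cells
carry the arbor — and with them all sixteen feature-direction contrasts
hold on batch means and per-class label recovery exceeds 90%. Image stacks
have three focal planes with different in-focus weights over a low-order
polynomial background plus Gaussian noise, so projection and background
correction do real work. Sections place bounding boxes by rejection
sampling with largest-remainder class rounding.

**Walks.** The hip advances speed/fps per frame along a heading with
Gaussian increments (SD turn_sd/√fps), reflecting specularly off the
walls; nose and tail-base are placed to realize a nose–hip–tail angle of
offset + A·cos(2πft + φ) (offset 150°, defaults A = 12°, f = 2.5 Hz).
Keypoint likelihoods are Beta-distributed near 1 with 1% dropouts to
exercise the confidence filter.

**Cq tables.** Per-gene baselines in 20–28 cycles, a per-sample RNA-input
offset applied to all genes (cancelling in ΔCq), a per-gene group effect
in cycles added to the treated group (the reference gene is never
shifted), and replicate noise.

**Feature blobs.** Isotropic Gaussian clusters with centres pushed apart
on a sphere by deterministic repulsion, standing in for well-separated
cell-type populations in feature space when the question is about the
clustering machinery rather than the image chain.

What the generators do *not* emulate: point-spread blurring and optical
sectioning, intensity heterogeneity within cells, touching/overlapping
cells, "jellyfish-like" or other intermediate morphologies beyond the
three classes, arena-wall rearing or grooming bouts, and qPCR efficiency
departures from 2. Passing tests therefore certify the measurement chain
on clean, structurally faithful inputs — not robustness to every
degradation of real microscopy or tracking.

## Study-scale defaults

The end-to-end synthetic study runs 2 groups × 4 mice × 20 cells per mouse
with 30-s walks — the per-animal cell count matches standard practice for
this assay, and the scale keeps a full run in seconds while every stage
still executes on its real code path. All stages write
deterministically-formatted CSVs; two runs at the same seed are
byte-identical.
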
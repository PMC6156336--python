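# Methods

## Scope and model

`hoxfish` quantifies higher-order chromatin folding of the Drosophila Hox
clusters (ANT-C: *lab*, *Scr*, *Antp*; BX-C: *Ubx*, *abdA*, *AbdB*) from
triple-label 3D DNA FISH, and nascent transcription from intronic RNA FISH,
binned by parasegment (PS) along the anteroposterior axis and by four
ordinal developmental-stage classes (3:50–4:50, 4:50–6:00, 6:00–7:20,
7:20–12:00 h after fertilization). Genotypes compared are wild type, the
cPRC1 null mutants *ph*^del^ and *Pc*^XT109^, and their sibling controls.

The measurement model is deliberately simple: each locus appears as a
diffraction-limited spot; folding is summarized entirely by pairwise 3D
centroid distances; transcription is a per-nucleus Bernoulli event observed
as a nascent-transcript spot. No chromatin polymer model is fitted.

## Spot detection

Two paths mirror how the signals are used.

*RNA (counts).* Per-slice Gaussian filter (σ = 1 px) → maximum-intensity
z-projection → 2D local maxima above a prominence threshold → 2D
point-in-polygon assignment to PS ROIs. The prominence default is 5× the
median absolute deviation of the projected image above its median — a
scale-free surrogate for an unspecified interactive tolerance. Absolute
counts depend on this free parameter; the analyses only ever compare
densities across PSs or genotypes measured with identical parameters.

*DNA (centroids).* 3×3×3 mean filter (median available) → global Otsu
threshold (fixed-value override available) → 26-connected 3D components →
components below `min_voxels` (default 4) dropped → intensity-weighted
centre of mass, converted to nm with the anisotropic voxel sizes
(73 nm xy, 300 nm z by default). On noiseless rendered spots the RMS
centroid error is below a quarter xy-voxel; detection is exact
(recall = precision = 1) at SNR ≥ 10 with ≥ 4σ spot separation.

## Triplet matching and the 1.5 µm rule

For each anchor spot (middle locus, A555) the nearest spot in each partner
channel is found; the trio is accepted only if both anchor-to-partner
distances are ≤ 1.5 µm. Accepted distance distributions therefore live on
[0, 1.5 µm] by construction. Partner spots are used at most once: candidate
trios are processed in ascending order of their larger anchor-partner
distance and a candidate whose partner is already consumed is dropped. This
greedy tie-break is a package choice (homolog pairing makes most nuclei
single-spot, so it rarely binds); it is asserted equivalent to an
exhaustive brute-force matcher on randomized instances.

## Chromatic aberration

A same-locus triple-label control (three dyes on one locus) gives, per
channel pair, a median apparent distance that is pure chromatic
displacement plus localization error: 130 nm (A488–A555), 120 nm
(A555–A647), 195 nm (A488–A647) in the calibration this package emulates.
Correction is scalar subtraction of the pair offset from *summary medians
only*, floored at zero; raw distributions are reported uncorrected. The
simulator applies one rigid translation per channel, so a vector-field
(field-dependent) correction is out of scope. On simulation the calibration
is unbiased to well under 15 nm per pair at 200 control nuclei.

## Statistics

Two presentations of distances are kept throughout, because they answer
different questions:

- *pooled* distributions (all embryos of a condition) feed box plots and
  two-tailed Mann–Whitney U-tests (stars at 0.05 / 0.01 / 0.001);
- *per-embryo medians* feed mean ± SEM curves (SEM reported as missing for
  a single embryo, never 0) and one-tailed Welch t-tests.

The Mann–Whitney p-value is exact (null enumerated) when
n_a·n_b ≤ 400 and the data are tie-free, otherwise the tie-corrected
normal approximation with continuity correction is used. Welch (unequal
variance) is the t-test form; two degenerate zero-variance samples with
equal means return p = 0.5 by convention. Derepression calls compare
per-embryo densities (the embryo is the replication unit, avoiding
pseudoreplication) at α = 0.01 two-tailed with no multiplicity correction
by default; Benjamini–Hochberg is available but off, matching per-cell
testing practice in this assay.

Derived series: difference of pooled medians (mutant − control) per
(pair, PS group, stage); per-PS percentage of gene spots within 400 nm of
the nearest Polycomb focus, averaged across embryos; min–max normalized
expression/distance Pearson correlation along the PS axis (expression of a
locus pair = summed relative densities of the genes between the two probes,
endpoints included); and mutant-differential scatter (ΔPh − ΔPc distance
early vs ΔPh − ΔPc expression later), with r withheld below 3 shared PSs.
Pearson is the default correlation; Spearman would be a one-line change and
was not needed for min–max normalized continuous series.

## Enrichment

Enrichment = local protein intensity / mean nuclear intensity, hence
invariant under global intensity scaling. Nuclei are segmented from DAPI
(Gaussian smooth → Otsu → 3D components → size filter). The nuclear mean is
computed inside the 3D mask *before* projection — the order of operations
is ambiguous in common practice, so it is fixed here and stated. Foci are
2D local maxima of the radius-1-smoothed, 3 µm-thick max projection centred
on the nucleus; locus enrichment samples the smoothed protein channel at
the DNA FISH spot position inside its containing nucleus.

A note on the "5× focus" anchor used in tests: because the enrichment path
smooths with a radius-1 Gaussian before reading the maximum, a
point-Gaussian focus of amplitude 5× background reads lower than 5×, and a
large focus inflates the nuclear mean. The anchor case is therefore
constructed as an intensity plateau wider than the smoothing kernel and
small relative to the nucleus, which the pipeline scores at 4.88 — the
honest reading of "a rendered 5× focus" under this estimator.

## Triangle embedding

Three (corrected) median distances are embedded canonically: A at the
origin, B at (d_AB, 0), C at the upper circle–circle intersection, so
identical inputs give identical coordinates and no reflection ambiguity.
Feasible triples are reproduced to 1e-9 relative. Floor-corrected medians
can violate the triangle inequality; such triples are projected to the
nearest collinear configuration and flagged `feasible = False` rather than
silently repaired.

## The simulator: what it emulates and what it does not

`simulate_embryo` renders, per channel, anisotropic 3D Gaussians
(σ_xy = 150 nm, σ_z = 400 nm by default) at true positions plus the
channel's rigid chromatic shift, on the acquisition grid, with Poisson shot
noise (optional photon scaling), additive background and Gaussian read
noise. Nuclei are non-overlapping spheres (default radius 1.5 µm — chosen
so that spec-scale fields pack by rejection sampling; embryonic nuclei at
these stages are of this order) packed into disjoint PS polygons tiled
along the A/P axis. Locus A is uniform in the inner half of the nucleus;
B and C sit at model-drawn radii on uniform random 3D directions — the
simplest isotropic geometry consistent with distance-only statistics.
Distance distributions (constant / truncated normal / lognormal / uniform,
support [0, 1.5 µm]) and per-PS, per-gene expressing fractions are
configurable; `simulate_distance_table` bypasses imaging for statistical
work.

Ground truth (positions, pairwise distances to 1e-9 internal consistency,
expression flags, applied shifts) makes every stage checkable. Deliberately
*not* modelled: embryo curvature, nucleus shape beyond spheres,
field-dependent chromatic aberration, probe hybridization efficiency,
transcription dynamics (stage classes are labels only), and background
structure (autofluorescence, yolk). Passing recovery tests therefore shows
the pipeline is correct under its own acquisition model, not that it is
robust to every real-microscopy artefact.

## Numerical choices and problem sizes

Tests and the acceptance script run on reduced but non-trivial problem
sizes chosen to keep sampling error well inside the stated tolerances:
fields of ~190×130×20 voxels, 6–20 nuclei per PS, 10–20 seeds per
recovery experiment, 200 control nuclei for calibration, 1000 replicates
for type-I calibration, 20 embryos per condition for differential-effect
recovery. Seeds are explicit everywhere (configs refuse to run without
one); sub-seeds are derived arithmetically and kept below 2³¹.

Known limitations: the greedy matcher is order-dependent in pathological
symmetric configurations (exact distance ties); Otsu thresholding assumes a
clearly bimodal histogram and will over-segment structured backgrounds; the
find-maxima prominence default is heuristic; chromatic correction is scalar,
so anisotropic aberration leaves a residual.
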
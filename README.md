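# hoxfish

Quantitative image analysis of higher-order chromatin folding at the
Drosophila Hox gene clusters, from triple-label 3D DNA FISH and
nascent-transcript RNA FISH — plus a synthetic-embryo simulator that gives
every stage of the pipeline a known ground truth.

## Who this is for

Labs measuring chromatin compaction with multi-colour DNA FISH in embryos
(or anyone reproducing that style of analysis): three loci of a gene
cluster are labelled in three dye channels, spots are detected per nucleus
in confocal z-stacks, and the three pairwise 3D centroid distances
d(A,B), d(B,C), d(A,C) quantify folding of the intervening chromatin.
Measurements are binned by parasegment (PS) along the anteroposterior axis,
by developmental-stage class, and by genotype (wild type vs Polycomb-group
mutants), so that compaction changes can be timed against ectopic
transcription.

## What it computes

- **RNA FISH expression** — Gaussian filter, max-intensity z-projection,
  2D find-maxima counting inside PS polygons; densities
  (spots/µm² = count / PS area) and min–max relative densities; ectopic
  expression / downregulation calls by two-tailed Mann–Whitney U on
  per-embryo densities (P < 0.01).
- **DNA FISH distances** — 3×3×3 filter, Otsu threshold, 3D connected
  components, intensity-weighted centroids in nm; triplet matching that
  keeps a trio only when both anchor-to-partner distances are ≤ 1.5 µm
  (so distance distributions live on [0, 1.5 µm]).
- **Chromatic aberration** — calibrated from a same-locus triple-label
  control as per-pair median apparent distances (e.g. 130 / 120 / 195 nm);
  subtracted from summary medians only, floored at zero.
- **Statistics** — pooled distributions (box plots, Mann–Whitney, exact
  null enumeration for small tie-free samples) and per-embryo medians
  (mean ± SEM, one-tailed Welch t-tests); difference-of-medians series
  mutant − control across stage classes; % of loci within 400 nm of the
  nearest Polycomb focus; expression/distance correlation maps; mutant
  differential-effect scatterplots.
- **Protein enrichment** — Pc/Ph intensity at nuclear foci or FISH-marked
  loci divided by the mean nuclear intensity.
- **Triangle layouts** — canonical planar embedding of the three corrected
  median distances (A at origin, B on +x, C in the upper half-plane).
- **Simulation** — embryo-like multi-channel stacks: spherical nuclei in PS
  polygons, locus triplets with configurable compact/open distance
  distributions, per-PS expressing fractions, rigid per-channel chromatic
  shifts, anisotropic Gaussian PSF, Poisson + read noise; fully seeded,
  with a ground-truth table per nucleus.

## Worked example

Simulate one noisy embryo with a compact anterior region (median pair
distance 350 nm) and an open posterior one (700 nm), run detection,
matching and a pooled comparison:

```python
import numpy as np
from hoxfish import *
from hoxfish.config import SimConfig, DistanceModel, NoiseModel, tiled_parasegments

cfg = SimConfig(
    seed=1, field_size=(192, 128, 20),
    parasegments=tiled_parasegments(["Head-PS0", "PS2-PS4"], 192, 128),
    nuclei_per_ps=8,
    distance_model={
        ("Head-PS0", "ab"): DistanceModel("normal", 350, 70),
        ("Head-PS0", "ac"): DistanceModel("normal", 350, 70),
        ("PS2-PS4", "ab"): DistanceModel("normal", 700, 70),
        ("PS2-PS4", "ac"): DistanceModel("normal", 700, 70)},
    noise=NoiseModel(photons_per_unit=1.0, background=10.0, read_sigma=2.0))

stacks, truth, rois = simulate_embryo(cfg)
by = {s.channel_label: s for s in stacks}
spots = {c: segment_dna_spots(by[c]) for c in ("A488", "A555", "A647")}
assign_spots_to_rois(spots["A555"], rois)
triplets = match_triplets(spots["A488"], spots["A555"], spots["A647"])
print(f"{len(triplets)} triplets accepted under the 1.5 um rule")
for ps in ("Head-PS0", "PS2-PS4"):
    d = [t.d_ab for t in triplets if t.ps_label == ps]
    true = truth[truth.ps_label == ps].d_ab_nm
    print(f"{ps}: measured median A-B = {np.median(d):.0f} nm "
          f"(truth {np.median(true):.0f} nm, n={len(d)})")
res = compare_pooled([t.d_ab for t in triplets if t.ps_label == "Head-PS0"],
                     [t.d_ab for t in triplets if t.ps_label == "PS2-PS4"])
print(f"Mann-Whitney U={res.statistic:.0f}, p={res.p_value:.2e} {res.stars}")
```

Output:

```
16 triplets accepted under the 1.5 um rule
Head-PS0: measured median A-B = 311 nm (truth 310 nm, n=7)
PS2-PS4: measured median A-B = 690 nm (truth 728 nm, n=9)
Mann-Whitney U=1, p=3.50e-04 ***
```

The detected medians track the simulator's stored truth to within a
fraction of an xy-voxel (73 nm), and the compact/open difference is highly
significant even at 8 nuclei per region.

## Command line

`hoxfish` exposes each stage as a subcommand over the same library:
`simulate`, `detect-rna`, `detect-dna`, `distances`, `expression`, `stats`,
`enrich`, `layout`, and `run-all` (one YAML config driving
simulate → detect → distances → expression → stats → layout, with a
manifest recording the config hash, seed and row counts; reruns are
byte-identical).

```sh
hoxfish run-all --config config.yaml --out results/
```

ROI files are JSON:
`{"voxel_size_xy_nm": 73.0, "rois": [{"label": "PS2", "polygon": [[x, y], ...]}, ...]}`
with vertices in xy pixel coordinates. Stacks are multi-page grayscale
TIFFs (one page per z-slice, axis order z, y, x); result tables are CSV
with physical coordinates in nm (x, y, z order).

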
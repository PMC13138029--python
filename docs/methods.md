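# Methods

This note documents the measurement procedures, the synthetic-data model,
the numerical choices and the limitations of `retclust`. Lengths are
micrometres throughout.

## Input model

One row per segmented nucleus/cell: 3-D coordinates in a right-handed μm
frame plus strictly boolean marker flags. Converting image intensities into
positive/negative marker calls (and pixels into μm) is upstream of this
package; the marker logic assumes the panel Otx2 (photoreceptor + bipolar
precursors), Rx2 (photoreceptors), Zpr1 (cones), Rhodopsin (rods), Prox1
(horizontal cells), Ath5::GFP (a ~20%-labeled subset of retinal ganglion
cells in chimeric preparations) and PKC-ζ (apical polarity).

## Cluster detection

"Close vicinity" between Otx2⁺ cells is operationalized as a proximity graph
with an inclusive edge threshold `linkage_radius_um` (default 10, roughly 1.5
nuclear diameters center-to-center): clusters are connected components of
size ≥ 2, singletons are discarded. Distance is isotropic Euclidean; no
z-anisotropy correction is applied, so anisotropic voxel spacing must be
resolved upstream. Components are computed on a KD-tree pair list; output is
sorted lexicographically by centroid and ids are assigned deterministically
(`<organoid>-c<k>`), so repeated runs diff cleanly.

Raising the linkage radius can only merge components (tested property). The
default was chosen so contact-packed cell groups (adjacent nuclei ≈ 7 μm
apart) are single components while clusters separated by the observed ≈ 45 μm
spacing never bridge.

## Composition

Marker logic is Otx2-anchored: PR iff Otx2 ∧ Rx2, BP iff Otx2 ∧ ¬Rx2; cone
and rod are disjoint PR sub-labels (co-labeled cells count as cone and are
logged); Prox1 → HC and Ath5::GFP → RGC only for Otx2⁻ cells, with conflicts
logged. Per-cluster ratios use the Otx2⁺ member count as denominator;
`bp_ratio` is computed as `1 − pr_ratio` so the pair sums to exactly 1 in
floating point (the integer counts satisfy n_pr + n_bp = n by definition).
Summaries are medians of per-cluster ratios — not ratios of pooled counts —
matching boxplot-style per-cluster reporting. RGC adjacency is the fraction
of clusters with ≥ 1 Ath5::GFP⁺ cell within `adjacency_radius_um` (default
25 = 2 × the nominal cluster radius; juxtaposition has no published distance).

## Spacing procedure

Mirrors how spacing is scored on confocal stacks:

1. **Sub-stacks.** Per organoid, clusters are partitioned by centroid z into
   contiguous slabs of `substack_depth_um` (default 60). A slab over the
   `max_clusters_per_substack` cap (default 30) is split at its median z;
   adjacent slabs are merged while their joint count stays under the cap.
   Every cluster lands in exactly one slab; an organoid with < 2 clusters is
   a single slab flagged distance-degenerate. At generator defaults (~92
   clusters on a 135 μm shell) this yields 4–6 sub-stacks per organoid;
   sparser preparations yield 2–3.
2. **Distances.** All unordered pairwise centroid distances within a
   sub-stack ("vector lengths"); each cluster's minimum is its
   nearest-neighbor distance.
3. **Band filter.** With m, s the mean and sample (n−1) SD of the sub-stack's
   minima, retain all pairs in [max(0, m − 3s), m + 3s]. When s = 0 the band
   collapses onto the common minimum and only exactly-equal distances
   survive. The sample SD is used because k per sub-stack is small. Each
   unordered pair is counted once; the alternative convention (two directed
   NN distances per retained pair) would also produce more distances than
   clusters but double-counts symmetric pairs and biases the pooled mean, so
   it was not adopted.
4. **Pooling, KDE, modes.** Retained distances are pooled across sub-stacks
   and organoids; the summary is their mean plus counts. The KDE is an exact
   Gaussian kernel sum on a 512-point grid over [0, max + 4h]; the default
   bandwidth is Scott's rule h = sd·n^(−1/5) (no published KDE parameters
   exist for this procedure, and Scott's rule is the common default for
   unimodal-to-mildly-multimodal length data). Modes are strict local maxima
   above `mode_prominence` (default 0.2) × the global maximum; plateaus
   collapse to one peak and grid endpoints never count.

Because the band is 3 SD wide, first neighbors and a fraction of second
neighbors survive, so the retained count exceeds the cluster count and the
pooled mean sits a few percent above the true center NN mean (≈ +8% at
generator defaults). That retention is the structural signature seen in real
preparations (more neighbor distances than clusters) and is why bimodality
can appear in the KDE: the second mode, when present, is the second-neighbor
shell, not a parameter of the generator.

## Architecture call

- **Apical fragmentation** = 1 − (largest PKC-ζ⁺ component / all PKC-ζ⁺
  cells) under the same linkage radius. 0 means a single continuous apical
  surface; one isolated focus per cluster drives it toward 1 − 1/k.
- **Radial order index** = 2·AUC − 1, where AUC is the Mann-Whitney
  probability that a random Ath5::GFP⁺ cell lies at larger radius than a
  random Otx2⁺ cell, radii measured from the centroid of all cells (no
  sphere fit; robust for near-spherical aggregates). +1 = RGCs strictly
  outside the Otx2 layer (laminated orientation), 0 = no ordering.
- **Clustered fraction** = fraction of Otx2⁺ cells inside detected clusters.

Label rule: `laminated` iff fragmentation < 0.5 and radial order > 0;
`clustered` iff fragmentation ≥ 0.5 and clustered fraction ≥ 0.5; otherwise
`indeterminate` (including any missing signal). The thresholds are
calibration parameters exposed in the config — the underlying phenotype was
scored by eye, so no quantitative thresholds exist to inherit; these defaults
sit midway between the two generated extremes, whose fragmentation
distributions do not overlap (≈ 0 vs. ≈ 0.99).

## Synthetic organoid model

The generator reproduces endpoint statistics, not morphogenesis. Defaults
are the study conditions: spherical organoid of outer radius 150 with a 30 μm
cortical shell; cluster centers on the mid-cortex sphere (r = 135); cluster
sizes 2 + Poisson(6) truncated at 22 (mean 8, range 2–22); target
nearest-neighbor spacing 45; P(PR | Otx2⁺) = 0.67 and P(cone | Otx2⁺) = 0.44
(cones ≈ 2/3 of PRs); one PKC-ζ⁺ point per cluster center; Poisson(12) RGCs
apposed to each cluster surface with a 20% Ath5::GFP label rate; Poisson(1)
horizontal cells per cluster adjacent to cone positions; 300 marker-negative
core cells.

**Center process.** Centers are a jittered Fibonacci spherical lattice
(tangential Gaussian jitter, sd 2) with a hard-core rejection floor at
`inhibition_radius_um` (default 0.8 × target spacing = 36); infeasible
requests raise a capacity error (hexagonal packing bound, or jitter retries
exhausted). A quasi-regular lattice was chosen over Matérn-style hard-core
thinning deliberately: at intensities where thinning is feasible, the
irregular pattern lets the ±3 SD band retain many distant-neighbor pairs,
inflating the filtered mean ≈ 20% above the NN mean, whereas the observed
pattern ("evenly spaced", filtered mean ≈ NN spacing, more distances than
clusters) is only reproduced by a near-lattice arrangement (+7–8%). The
default center count is derived from the target spacing via the measured
lattice relation NN ≈ 3.196·R/√n (n ≈ 92 at defaults, realized NN mean
≈ 45.9). The spacing/count/organoid-size triple is mutually constraining;
with the spacing and the organoid radius fixed, the per-organoid cluster
count follows from geometry.

**Cluster members.** Each cluster is a contact-packed blob: members grow one
step (7 ± 0.8 μm, clipped to [4.9, 9.1]) from a random existing member,
confined to the 12.5 μm cluster ball. Steps are bounded below the linkage
radius and the inhibition floor exceeds two cluster radii plus the linkage
radius, so detection recovers the generated clusters exactly — cluster-count
recovery is a construction guarantee, not a statistical one. Blob growth is
already stochastic, so no additional positional noise is applied to members;
all other cell classes receive 1 μm Gaussian jitter to avoid degenerate
exact-distance ties.

**RGC abundance.** Placed RGCs per cluster default to Poisson(12). The
reasoning: juxtaposition of RGCs was observed *consistently* under a labeling
scheme that marks only ~20% of RGCs; for a ≥ 90% per-cluster probability of
seeing a labeled RGC, the thinned count 0.2·λ must be ≥ 2.3, i.e. λ ≳ 12.
RGC shells are anchored on the realized member centroid so apposition holds
with respect to the centroid the pipeline measures from.

**Laminated mode.** Otx2⁺ cells fill a 10 μm band at the inner cortex radius
(apical-in), RGCs a band at the outer rim, and the apical surface is a
Fibonacci lattice at the inner radius with 7 μm spacing — dense enough that
it forms one connected component under the default linkage radius. Cell
budgets reuse the clustered-mode means so the two modes are comparable.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: segmentation and marker-call errors, anisotropic
z-resolution, non-spherical organoid shapes, partial/mixed architectures
within one organoid, amacrine cells and finer PR subtypes, cluster-size
correlation with local density, and any developmental dynamics. Recovery
results demonstrate internal consistency of the measurement chain under the
stated point-process model, not accuracy on microscopy-derived tables.

## Numerical and determinism choices

- Sample (ddof = 1) SDs everywhere a band or bandwidth is derived.
- `bp_ratio := 1 − pr_ratio` guarantees exact complementarity in floats.
- The s = 0 filter band uses the common minimum value itself, avoiding
  last-ulp misses from re-averaging identical values.
- KD-tree pair queries are inclusive (d ≤ r), matching the cluster
  definition; the brute-force test oracles use the same inequality.
- All randomness flows from one integer seed through
  `numpy.random.default_rng` / spawned `SeedSequence` streams (one per
  organoid in a cohort); tables serialize with fixed 6-decimal formatting, so
  identical seeds give byte-identical CSVs and reports. Reports contain no
  timestamps (those live in the run manifest).
- Problem sizes used by the test suite and the acceptance script (cohorts of
  10–40 organoids, ~3,000–6,500 cells each) were chosen to put Monte-Carlo
  sampling intervals well inside the asserted tolerances while keeping a full
  run in tens of seconds.

## Known limitations

- Whole-organoid 3-D analysis only; no per-region calls, so partially
  laminated organoids collapse into one label (often `indeterminate`).
- The sub-stack partition depends on slab boundaries: clusters whose true
  nearest neighbor falls in the adjacent slab inflate that slab's minima
  slightly, as in the original stack-based procedure.
- Basal (laminin-channel) signal is not part of the input schema; the
  architecture call rests on the apical marker and radial ordering alone.
- The laminated/clustered thresholds are calibrated on the generator's
  extremes; intermediate real phenotypes will need re-calibration against
  annotated data.
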
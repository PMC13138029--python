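# retclust

Quantification of **clustered vs. laminated retinal architecture** in 3-D
organoid cell tables.

Fish retinal organoids grown without extrinsic polarity cues do not build the
familiar laminated retina: differentiating retinal neurons self-organize into
discrete, evenly spaced multicellular clusters, each containing the cell types
of a retinal column (photoreceptors, bipolar precursors, adjacent horizontal
and ganglion cells) around a local apical focus. Supplying a basal ECM cue
(laminin) restores a laminated epithelium with a single apical surface.
`retclust` implements the spatial quantification behind that phenotype for
anyone working with segmented 3-D cell coordinates and boolean marker calls
(Otx2, Rx2, Zpr1, Rhodopsin, Prox1, Ath5::GFP, PKC-ζ):

- **Cluster detection** — a retinal cluster is a connected component of ≥ 2
  Otx2⁺ cells in the proximity graph with edges at Euclidean distance
  d(i, j) ≤ r_link (default r_link = 10 μm, center-to-center).
- **Composition** — per cluster with n Otx2⁺ members,
  `pr_ratio = n(Otx2⁺Rx2⁺)/n`, `bp_ratio = 1 − pr_ratio`,
  `cone_ratio = n(Otx2⁺Zpr1⁺)/n`; summaries are medians over per-cluster
  ratios.
- **Nearest-neighbor spacing** — per organoid, clusters are partitioned into
  axial sub-stacks (≤ 30 clusters each); within a sub-stack all unordered
  pairwise centroid distances are computed; with m and s the mean and sample
  SD of the per-cluster minima, the band [m − 3s, m + 3s] (clamped at 0) is
  applied to the all-pairs set to discard distances between non-adjacent
  clusters; retained distances are pooled and summarized by their mean and a
  Gaussian KDE with mode counting.
- **Architecture call** — per organoid: apical fragmentation
  (1 − largest PKC-ζ⁺ component fraction), a radial order index
  (2·AUC − 1 of RGC vs. Otx2⁺ radii), and the clustered fraction of Otx2⁺
  cells; thresholded into `laminated` / `clustered` / `indeterminate`.
- **Synthetic organoids** — a generator emulating both modes with known
  ground truth (hard-core jittered-lattice cluster centers on the mid-cortex
  shell, shifted-truncated-Poisson cluster sizes, the full marker logic, RGC
  juxtaposition, apical points), used for parameter-recovery testing.

## Worked example

```python
from retclust import AnalysisConfig, GeneratorParams, run_pipeline

cfg = AnalysisConfig(rng_seed=1)
report, manifest = run_pipeline(
    cfg, generator=GeneratorParams(mode="clustered"), n_organoids=10
)
print(report["clusters"]["size_distribution"]["mean"])   # 8.076
print(report["spacing"]["mean_um"])                      # 49.49
print(report["composition"]["median_pr_ratio"])          # 0.667
print(report["architecture"]["counts"])
# {'laminated': 0, 'clustered': 10, 'indeterminate': 0}
```

Ten simulated clustered-mode organoids yield 920 detected clusters with a
mean of 8.08 cells per cluster (range 2–17 in this cohort; the size law is
bounded at 2–22). The pooled band-filtered spacing is 49.5 μm against a
realized center nearest-neighbor mean of 45.9 μm — the band intentionally
retains first and some second neighbors (1091 distances from 920 clusters),
so its mean sits slightly above the pure NN mean. Median per-cluster
composition is 0.667 PR / 0.333 BP with a cone median of 0.43, and every
organoid is called `clustered`.

The same pipeline on `GeneratorParams(mode="laminated")` reports apical
fragmentation 0.0, radial order index 1.0 and the label `laminated`.

A command-line interface mirrors the library:

```sh
retclust simulate --mode clustered --seed 7 --out table.csv --truth truth.json
retclust detect --in table.csv --radius 10 --out clusters.csv
retclust composition --in table.csv --clusters clusters.csv --out composition.json
retclust spacing --clusters clusters.csv --out spacing.json
retclust classify --in table.csv
retclust run --simulate clustered --n-organoids 10 --seed 1 --out report.json
```

Cell tables are plain CSV with columns
`cell_id,x,y,z,otx2,rx2,zpr1,rhodopsin,prox1,ath5_gfp,pkc_zeta,organoid_id`
(coordinates in μm, flags as 0/1).

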
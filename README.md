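# gliamorph

Quantitative analysis of glial morphology and post-injury physiology in the
mouse brain: single-microglia morphometric profiling and amoeboid/ramified
classification, perilesional density and coverage quantification, open-field
and gait kinematics from pose-estimation tables, and relative qPCR
expression — together with seeded synthetic-data generators that provide
ground truth for every stage.

## Who this is for

After a brain injury, microglia shift from a *ramified* morphology (small
soma, long branched processes, surveillant) toward an *amoeboid* one (large
compact soma, retracted processes, activated). Quantifying that shift from
labeled-cell microscopy — and relating it to behavioral recovery and
inflammatory gene expression — is a standard read-out in neuroimmunology.
`gliamorph` packages that entire analysis chain as tested, reusable Python,
for groups that have image stacks, pose tables and Cq tables and want
reproducible per-cell, per-mouse and per-group numbers.

## The method

**Morphometry.** Z-stacks are max-projected, background-corrected
(large-scale Gaussian subtraction, optional FFT band-pass), Otsu-binarized,
and split into non-overlapping single-cell masks. Each mask yields a
16-feature profile:

- box-counting fractal dimension *D* (slope of log *N(s)* vs log (1/*s*) for
  the outline set) and gliding-box lacunarity
  Λ(*r*) = var(*m<sub>r</sub>*)/mean(*m<sub>r</sub>*)² + 1, averaged over the
  box-size ladder;
- convex-hull shape metrics: cell and hull area *A*, perimeter *P*,
  circularity 4π*A*/*P*², density (cell/hull area), roughness (cell/hull
  perimeter);
- skeleton statistics: total/max/mean process length, the straightness
  index (Euclidean over path length per branch), and the Sholl profile of
  process crossings with concentric circles;
- cell-body area via the Shoelace formula on the soma contour polygon.

**Classification.** Each feature carries a multimodality index (MMI) — the
Sarle-type bimodality coefficient
*b* = (*g*₁² + 1)/(*g*₂ + 3(*n*−1)²/((*n*−2)(*n*−3))) of its distribution
across the population — and a direction label (whether high values mark
amoeboid or ramified cells). Min–max-scaled features combine into
MMI-weighted **amoeboid** and **ramified indices**; a cell takes the label of
the larger index, and the percentage of amoeboid-labeled cells per sample is
the **amoeboid ratio**. A reference MMI table ships with the package;
weights can also be re-estimated from your own data.

**Structure discovery.** Features with MMI ≥ 0.5 feed Ward hierarchical
clustering (Euclidean distance), with the cluster count chosen by maximal
mean silhouette, plus a centred PCA embedding.

**Physiology.** Open-field pose tables (x, y, likelihood per bodypart) yield
distance/speed metrics, occupancy maps, and — on automatically selected
straight-walking windows — the amplitude of a cosine fit
*A*·cos(2π*f t* + φ) + *c* to the nose–hip–tail body-segment angle, an index
of locomotor coordination. Grip force is normalized by body weight. Cq
tables yield 2^(−ΔCq) relative expression and fold change against the
control-group mean.

## Worked example

Classify a synthetic two-condition cohort (4 mice × 20 cells, with 20% vs
70% ramified cells per condition):

```python
import numpy as np
import pandas as pd

from gliamorph import synth
from gliamorph.classify import AmoeboidRamifiedClassifier, amoeboid_ratio
from gliamorph.imgprep import CellMask
from gliamorph.morpho import MorphometricExtractor

rng = np.random.default_rng(0)
masks, mouse = [], []
for m, mix in enumerate([0.2, 0.2, 0.7, 0.7]):  # fraction ramified per mouse
    for i in range(20):
        cls = "ramified" if i < round(20 * mix) else "amoeboid"
        spec = synth.default_spec(cls, seed=int(rng.integers(2**31)))
        masks.append(CellMask(synth.make_cell_mask(spec), spec.pixel_size_um))
        mouse.append(f"mouse_{m + 1}")

features = MorphometricExtractor().fit_transform(masks)
clf = AmoeboidRamifiedClassifier().fit(features)
labels = pd.Series(clf.predict(features))

print(features[["cell_area_um2", "cell_circularity", "total_process_length_um"]].head(3).round(2))
print(amoeboid_ratio(labels, pd.Series(mouse)))
```

```
   cell_area_um2  cell_circularity  total_process_length_um
0         387.00              0.03                   219.22
1         363.25              0.04                   211.29
2         454.50              0.03                   275.01
    sample  n_cells  amoeboid_ratio_pct
0  mouse_1       20                80.0
1  mouse_2       20                80.0
2  mouse_3       20                30.0
3  mouse_4       20                30.0
```

The first rows are ramified cells: low circularity, long total process
length. The per-mouse amoeboid ratio recovers the generated mixes exactly —
80% amoeboid where 20% of cells were ramified, 30% where 70% were.

The same stages are scriptable from the shell via the `gliamorph` CLI
(`gliamorph synth …`, `prep`, `morpho`, `classify`, `cluster`, `quant`,
`behavior`, `expression`, `study`); `gliamorph study --seed 0 --out DIR`
runs the full synthetic study end to end and writes tidy CSVs.

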
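# coloc3d

Object-based colocalization and soma-size classification for two-channel 3D
fluorescence microscopy, built for the kind of question that arises in
thalamic circuit anatomy: *are all driver-type (VGluT2+) terminal boutons in
a nucleus retinal (tracer-filled) in origin, or does some lamina receive an
extra, unlabeled input?* Pixel-overlap coefficients answer this poorly when
the two markers label differently sized structures (tracer fills whole
boutons; immunolabel marks vesicle clusters inside them), so the analysis
here works on segmented **objects** and their geometry instead.

## The method

Each channel of a 3D stack is segmented into objects (Gaussian smoothing at
a physical scale, default 0.10 μm; fixed or between-class-variance
threshold; 26-connected components; objects smaller than 15 voxels
discarded as background). Every object is reduced to its volume *V*,
centroid, and equivalent-sphere radius

> r = (3V / 4π)^(1/3).

For each object, the nearest object in the *opposite* channel is found by
exact Euclidean search on centroids, and the **interbouton distance** is

> d_ib = ‖c₁ − c₂‖ − r₁ − r₂,

i.e. the gap between the two equivalent spheres; the pair is **colocalized
iff d_ib < 0** (strictly — touching spheres do not count). Per image, with
candidate channel *C* (e.g. VGluT2) and reference channel *R* (e.g. CTB),
the **colocalization index** is

> CI = (% of C objects colocalized with an R object) / (% of R objects colocalized with a C object).

The denominator absorbs false-positive objects under the biological
assumption that every reference bouton carries the candidate marker: CI = 1
means complete colocalization, CI < 1 quantifies the fraction of singly
labeled candidate boutons. Per-image CI values are compared between groups
(e.g. laminar pathways) with Welch's t.

Soma-size classification follows the companion workflow: a glia-exclusion
cutoff taken as the 1st percentile of GABA+ soma areas, then univariate
Gaussian mixtures fitted by EM for K = 1..9 with the component count chosen
by the **highest BIC** (2·logL − p·ln n convention), and maximum-posterior
classification of every cell.

Because such studies rarely deposit raw stacks, the package includes a
synthetic-scene generator: fields of paired reference/candidate spheres
plus a controllable fraction of unpaired candidates, rendered onto an
anisotropic voxel grid with Gaussian PSF blur and noise — every pipeline
stage can therefore be validated against exact ground truth.

## Worked example

Simulate ten images — five fully paired, five with 35% singly labeled
candidate boutons — segment them, and compare CI between the groups:

```bash
python analysis/02_segment_and_colocalize.py
```

```
paired_0                     group=fully_paired         CI = 1.021
mixed_0                      group=with_singly_labeled  CI = 0.653
...
Welch's t: t = 56.32, df = 7.0, p = 1.46e-10
  fully_paired: mean CI 1.004 ± 0.005 (n=5)
  with_singly_labeled: mean CI 0.649 ± 0.004 (n=5)
```

The fully paired group reads CI ≈ 1 (every candidate object contains a
reference object); the group constructed with 54 unpaired candidates among
154 reads CI ≈ 100/154 ≈ 0.65 — the pipeline recovers the constructed
singly-labeled fraction through rendering and re-segmentation, and Welch's
t separates the groups decisively.

The soma workflow on a synthetic interneuron/relay mixture:

```bash
python analysis/04_soma_mixture.py
```

```
glia-exclusion cutoff (1st percentile of GABA+ areas): 56.1 μm²
BIC-selected K = 2 components:
  component 0: weight 0.53, mean 124.5 μm², sd 27.7 μm²
  component 1: weight 0.47, mean 248.9 μm², sd 68.0 μm²
```

BIC recovers the two planted populations (125.2 and 251.7 μm²) and their
spreads from the pooled, truncated sample.

The other drivers: `01_simulate_scene.py` (render a demo stack),
`03_ci_recovery.py` (80-scene recovery sweep), `05_group_stats.py`
(MW-U/KS/Kruskal–Wallis+Dunn/ANOVA+Tukey battery). A `coloc3d` CLI exposes
the same stages (`simulate`, `segment`, `coloc`, `soma-mix`, `compare`,
`run`); see `coloc3d --help`.

## Layout

- `src/coloc3d/` — library: `synthetic`, `segmentation`, `coloc`,
  `mixture`, `stats`, `grid`, `pipeline`, `benchmarks`, `cli`
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — unit, property, and acceptance suites
- `docs/methods.md` — modeling and design notes
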
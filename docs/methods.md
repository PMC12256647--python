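# Methods notes

## The colocalization model

The analysis treats segmented boutons as equivalent spheres. Two objects in
opposite channels colocalize iff the distance between their centroids is
less than the sum of their equivalent radii (interbouton distance < 0,
strictly: an exactly-touching pair is *not* colocalized). Neighbor
selection is a two-step rule, deliberately: the nearest opposite-channel
object is chosen by **center** distance first, and radii are subtracted
afterwards. A non-nearest object with a large radius could in principle
overlap more than the chosen neighbor; this is an inherent property of the
statistic as defined, kept as-is rather than "corrected", and it is
irrelevant in the sparse-bouton regime the method targets (objects well
separated relative to their radii).

The colocalization index is directional — candidate over reference — and
is computed **per image**; group inference treats images, not objects, as
replicates (n = images). CI may exceed 1 by sampling noise when nearly all
objects in both channels are paired. The CI denominator requires at least
one colocalized reference object; a zero denominator raises rather than
returning an arbitrary value.

Nearest-neighbor search is an exact distance-matrix argmin over id-sorted
tables, which implements lowest-id tie-breaking for free. At the object
counts this analysis sees per image (10²–10³), the O(n²) matrix is faster
and simpler than a k-d tree and is bit-exact; the test suite additionally
pins it to an independent pure-Python scan.

## Segmentation surrogate

Commercial surface rendering is emulated as: Gaussian smoothing with
physical sigma 0.10 μm (the "surface detail" scale; converted per axis to
voxels, so anisotropic stacks smooth isotropically in physical space);
intensity threshold (fixed, or Otsu's between-class-variance maximization
when no value is known); 26-connected component labeling (the most
inclusive neighborhood, closest in spirit to meshed surfaces; 6 and 18
selectable); unweighted centroid of voxel centers at (index + 0.5)·spacing.
Centroids are geometric rather than intensity-weighted because
surface-derived centroids are geometry-derived; the original tooling's
convention is unknowable, and for compact blob-like objects the difference
is far below a voxel.

The minimum-size filter excludes objects *strictly smaller than* 15 voxels
by default (an exactly-15-voxel object survives). A physical-volume mode
(e.g. 0.0185 μm³) exists as an alternative because the voxel-count and
μm³ formulations of the same exclusion do not coincide at every voxel
spacing; the two modes are never combined.

## Synthetic scenes

`generate_coloc_scene` places `n_reference` reference spheres, each with
exactly one paired candidate sphere, plus `n_extra_candidate` unpaired
candidates, by rejection sampling (default cap 10,000 tries per object).
Radii are lognormal with median 0.5 μm and log-sd 0.3 — a right-skewed law
spanning roughly 0.25–1 μm, typical of terminal boutons; no empirical
bouton-size law was available, so this is a stand-in, not an estimate of
any particular dataset. A paired candidate center is offset from its
reference by a random vector of length ≤ min(0.3 μm, 0.5·min(r_ref,
r_cand)), which guarantees overlap under the interbouton criterion; all
other object pairs keep ≥ 0.5 μm surface-to-surface separation (so
unpaired candidates never overlap anything, across or within channels).
The ground-truth candidate colocalization fraction is therefore exactly
n_ref / (n_ref + n_extra).

Rendering paints each sphere as the set of voxels whose centers fall
inside it, at amplitude 100 over background 10 (arbitrary 8-bit-like
contrast; only the ordering matters to thresholding), blurs with an
anisotropy-aware Gaussian (default sigma 0.1 μm), and adds per-voxel
Gaussian noise clipped at 0. Default spacing is (z, y, x) = (0.3, 0.06,
0.06) μm — the acquisition step of the imaging this emulates. Poisson
photon statistics, Airy PSFs, spectral bleed-through, and fiber-like
structures are deliberately out of scope: the generator exists to exercise
the geometry of the statistic, not the optics, so passing tests certify
the measurement chain, not robustness to real microscope noise.

All randomness in a call flows from its single `seed` argument; fixed seed
⇒ bit-identical scene, render, and sample.

## Benchmark problem sizes

The benchmark/recovery scenes use 150 candidate objects per image in a
36 × 36 × 12 μm box, rendered noiselessly at (0.3, 0.12, 0.12) μm — the
study-like axial step with a 2×-coarsened lateral step. At this sampling a
median bouton still spans ≈120 voxels (the 15-voxel filter only removes
the rare smallest objects), and an 80-scene sweep (20 seeds × 4 pairing
fractions) completes in a few minutes on one CPU. Threshold 55 sits
mid-range between background (10) and blurred-peak (≈100) intensities.
Occasionally a very small rendered candidate falls under the 15-voxel
exclusion; this shifts a scene's CI by ≲0.01 and is part of the method's
honest behavior, not an error.

## Mixture modeling

Univariate normal mixtures are fitted by EM, with either unequal (default)
or equal component variances — the flexible family is the default because
the model family used in the original workflow is not recorded.
Initialization: component means at evenly spaced data quantiles, pooled
SD, uniform weights; plus five seeded random restarts (means drawn from
the data, SD scaled by U(0.5, 1.5)), keeping the best final
log-likelihood. Convergence: relative log-likelihood change < 1e-8 (or
1000 iterations). A component SD falling below 1e-6 of the data SD is
treated as collapse; the run is abandoned and, if every start collapses,
the fit errors rather than returning a degenerate solution.

Model selection maximizes BIC = 2·logL − p·ln n with p = 3K − 1 (unequal)
or 2K (equal) free parameters. The sign convention matters: this is the
form under which "highest BIC wins", matching model-based-clustering
practice; it is the negative of the minimized form common elsewhere.
Components are always reported sorted by ascending mean, posterior ties in
classification go to the lower-mean component, and the number of
components is always a data outcome — nothing in the package hard-codes an
expected K.

The glia-exclusion cutoff is the 1st percentile (linear interpolation) of
GABA+ soma areas — the size above which 99% of genuine interneurons lie —
applied as `area ≥ cutoff` before fitting; exclusion-then-fit order is a
design choice (the alternative, fitting first and discarding a glial
component, is not implemented).

## Group statistics

Welch's t (with p = 1 by contract when both samples are constant and
equal), Mann–Whitney U (exact when n ≤ 12 combined and tie-free, else
normal approximation with midranks and tie correction), two-sample KS
(asymptotic), Kruskal–Wallis with Dunn's z post hoc under Bonferroni
(the post hoc family is a choice; it is recorded in the result metadata),
and one-way ANOVA with Tukey's HSD. All p-values are two-sided.
Descriptives are mean ± SEM with t-based 95% CIs. The scipy primitives
stand behind these surfaces; Dunn's test is implemented here because no
installed package provides it.

## Known limitations

- One-to-one overlap resolution is not attempted: several candidates
  sharing one reference each count as colocalized (no deduplication), as
  in the original formulation.
- The equivalent-sphere reduction is blind to object shape; elongated
  objects can colocalize "through" their long axis.
- The synthetic generator's density and size laws are plausible defaults,
  not estimates; absolute CI values from real tissue depend on staining,
  threshold choice, and optics that the simulation does not model.
- 2D analysis, Manders/Pearson coefficients, deconvolution, and mesh
  export are out of scope.
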
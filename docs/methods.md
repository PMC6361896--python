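# Methods

## The filtration and its homology

An image is a function `f : I → [0, 1]` on an m×n pixel grid, with low
values marking hematoxylin-dense nuclei.  We compute persistent homology
of the **sublevel-set filtration** `L_τ = {x : f(x) ≤ τ}`: dark structure
enters first, so nuclei appear as early components, loops are born when
rings of nuclei close, and loops die when their bright interior (lumen)
finally enters.  The equivalent presentation in terms of super-level sets
of inverted intensities is a visualization convention only; the
computation here is sublevel throughout.

The grid carries the **Freudenthal triangulation**: vertices are pixels;
edges join each pixel to its right, lower, and lower-right neighbours;
each unit square holds two triangles.  Cells enter at the maximum of
their vertex values (lower-star rule), making the cell order a valid
filtration refinement of `f`.  A consequence of the single diagonal is
that dark sets are 8-connected along one diagonal direction and
4-connected along the other; this asymmetry is shared by any triangulated
grid and is irrelevant to the downstream statistics, which never compare
diagrams across connectivity conventions.

Two computations are implemented:

* **Fast path.**  H0 by union-find over edges in filtration order with the
  elder rule (the component with the older minimum survives a merge; ties
  break by vertex index).  H1 by planar duality: each loop of `L_τ`
  corresponds to a bounded component of its complement, so the H1 pairs
  are the 0-dimensional pairs of the dual graph — triangles plus the
  outer face — swept in decreasing value.  A dual merge at edge value `b`
  of a component born at triangle value `d` yields the loop `(b, d)`.
* **Oracle.**  A full Z2 boundary-matrix column reduction with no
  optimisations, restricted to ≤16×16 images.  The test suite enforces
  exact multiset equality between the two on hundreds of random images
  with deliberate ties and plateaus.  The diagram, as a multiset of value
  pairs, is invariant to how ties are refined, so the two paths must (and
  do) agree exactly.

Zero-persistence pairs are discarded — they carry weight zero in every
downstream representation.  The single essential component of a connected
image is kept with death pinned at 1.0 and an `essential` flag, so ranked
vectors include it; no removal rule is applied to H0.

## Stain model

Optical density is `OD = −log10(clip(I, 1, I0)/I0)` per channel with
`I0 = 255`; the one-level clamp keeps zero pixels finite while leaving
`OD(255) = 0` and `OD(25.5) = 1` exact.  Stain estimation follows the
angular-extremes procedure: pixels with OD norm ≤ β (default 0.15) are
discarded, the rest are projected onto the top-2 singular plane of the
(lexicographically sorted, hence exactly order-invariant) OD cloud, and
the stain vectors are the directions at the α and 100−α angular
percentiles (α = 1).  Hematoxylin is identified as the row with the
larger blue-OD component (hematoxylin is blue-purple).  Unmixing solves
the per-pixel two-variable non-negative least-squares problem in closed
form (unconstrained normal equations if feasible, otherwise the better
single-stain fit), vectorised over the image.  The hematoxylin
concentration is rendered as a transmission image `255·10^(−c_H)` and
rescaled by the *fixed* map `v/255` — never a per-image min–max stretch,
which would destroy cross-image comparability of filtration values.

Colour normalization transfers per-axis mean and SD in a decorrelated
space.  The original method's log-opponent `lαβ` space is the default;
CIELAB is available via `space="cielab"` since the literature often says
only "LAB".  Constant images raise an error naming the degenerate axis
(SD below 1e-8, the floating-point floor of a truly constant image).

## Representations

Ranked persistence vectors use persistence `|d − b|` uniformly (one
source writes the difference with the opposite sign in one place; the
magnitude is the only quantity ever used).  Part lengths are the minimum
H0 and H1 counts across the collection being featurized; a zero-H1 image
degrades the H1 part to empty with a warning rather than an error.

Intensity surfaces evaluate the persistence-weighted Gaussian kernel
density on a 128×128 grid over [0, 1]² by default (the resolution is a
rendering choice; analytics tests use finer grids extended 0.3 beyond the
unit square so that ~6σ of kernel mass is captured).  σ = 0.05 gives
minimal smoothing at unit-interval scale.  No boundary renormalization is
applied: the surface is an evaluation, not a density estimate.

## Discovery chain

* **Balanced bootstraps** subsample each larger class *without*
  replacement down to the smallest class size; the smallest class is held
  fixed by default (resampling it would discard information when it is
  included in full), with `resample_smallest=True` available.
* **PCA** retains six components and warns below 99% explained variance.
* **Ward/AC**: the agglomerative coefficient is the mean over points of
  `1 − h_first/h_final` (first-merge height over final merge height); a
  dendrogram of all-identical points has AC 1 by convention.
* **Gap statistic**: reference sets are uniform over the per-feature
  bounding box (the simplest reference distribution); dispersion W uses
  the Ward labels themselves, keeping model selection coherent with the
  clustering actually used.  Both selection rules are exposed: global
  max of the mean Gap curve, and the one-SE rule
  `min k : Gap(k) ≥ Gap(k+1) − s_{k+1}`, `s_k = sd_k√(1+1/B)`.
* **Within-bootstrap k**, when not fixed, is chosen by the max-mean rule
  on the Gap curve averaged over the first few bootstraps (balanced
  subsamples are exchangeable, so scanning all of them is redundant);
  the meta-level k is chosen independently by the one-SE rule over
  1..10.
* **Meta-clusters** are relabeled by composition-weighted mean grade
  (3·G3 + 4·G4 + 5·G5 fraction), G3-heavy first — a stable, interpretable
  ordering.
* **Jaccard stability** resamples composition vectors with replacement,
  re-runs Ward at the same k, and scores each original cluster by its
  best Jaccard match among resample clusters, membership measured on the
  drawn instances; resamples where a cluster is unrepresented are skipped
  rather than scored zero (they carry no information about that
  cluster).  The matching is maximum-over-clusters, the usual clusterwise
  stability convention.
* **t-SNE** uses the scikit-learn implementation; the KL divergence is
  the optimizer's converged objective, and pBIC uses the natural
  logarithm (the BIC convention), with base 10 switchable.  Perplexity
  selection averages pBIC over bootstraps and takes the argmin inside
  the 5–50 window, ties to the smallest p.

## Synthetic generator

The generator emulates the geometric skeleton of seven architectures:
loose and crowded gland rings (G3), cribriform masses with punched-out
lumina, fused chains, and incomplete ("poorly formed") arcs (G4), solid
nuclear sheets and scattered isolated nuclei (G5).  Nuclei are truncated
Gaussian bumps (support radius 2σ) subtracted from a bright background
(0.92) with optional Gaussian noise (SD 0.01); gland centres are placed
by rejection sampling with a pattern-specific minimum distance, failing
loudly when the requested geometry cannot fit.  Tuned defaults live in
`DEFAULT_GEOMETRY` at a 512-px reference scale: gland radius 55 ± 5 px,
nucleus radius 8 px, ring nucleus spacing 2.2σ with 2% radial jitter —
chosen so a ring reads as a closed dark annulus (one dominant loop per
gland, robustly across seeds) while nuclear-scale features remain
individually resolvable.  These are generator choices, not measured
histology.

Pseudo-H&E composition is the exact Beer–Lambert forward model
`RGB = 255·10^(−C·M)` with the canonical H&E stain matrix; the eosin
field is a smooth low-frequency texture depleted quadratically under
nuclei (stained chromatin displaces cytoplasm), which also guarantees
near-pure stain pixels so that angular-extreme stain estimation is
well-posed.  What the generator does **not** model: nuclear texture and
pleomorphism, stromal fibre structure, staining artefacts, out-of-focus
blur, tissue folds.  Passing tests therefore demonstrate correctness of
the computational chain and its discriminative behaviour on idealized
architecture — not clinical performance on real slides, whose class
overlap is far larger.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
oracle equivalence on ≤12×12 images, stain round-trips at 64², the worked
three-gland example at 256², and end-to-end recovery with 60 images per
class at 128² — sizes at which the planted classes are cleanly separable
and the whole suite completes in a few minutes.  Determinism is
end-to-end: one integer seed drives generation, bootstrapping, reference
sets, resampling, and t-SNE, and figure output pins the SVG hash salt and
drops timestamps so re-renders are byte-identical.  Tie-breaking is by
fixed row-major cell order in the filtration and by lowest id elsewhere
(representative bootstrap, perplexity ties).

## Known limitations

* H2 and higher homology are out of scope (meaningless on 2-D images).
* The complement-duality H1 path assumes a full rectangular (hence
  planar, contractible) domain — true for whole ROIs, not for masked
  tissue regions.
* The Gap statistic's uniform-box reference is the simplest variant;
  PCA-aligned references can shift the chosen k on strongly anisotropic
  score clouds.
* Stain estimation assumes exactly two stains; it flags near-single-stain
  fields as degenerate rather than guessing.
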
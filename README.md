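# histotda

Topological discovery of architectural subgroups in prostate-cancer
histology.

Prostate adenocarcinoma is graded by the *architecture* of its glands:
well-circumscribed rings of nuclei around a lumen (Gleason pattern 3),
cribriform and poorly formed glands (pattern 4), solid nuclear sheets and
infiltrating single cells (pattern 5).  Grading is semi-quantitative and
suffers from high inter-observer variability, and single patterns hide
prognostically distinct sub-architectures.  `histotda` quantifies that
architecture directly with **sublevel-set persistent homology**: the
hematoxylin (nuclear) channel of an H&E image, rescaled to a function
`f : I → [0, 1]`, induces a nested family of sublevel sets
`L_τ = {x : f(x) ≤ τ}`; tracking connected components (H0) and loops (H1)
across τ records each feature as a persistence pair `(b, d)`.  Small,
short-lived loops capture nuclear arrangement; large, persistent loops
capture glandular lumina — so the diagram encodes architecture across
scales without segmentation.

The library implements the full unsupervised pipeline:

1. **Stain processing** — Reinhard colour-statistics transfer (log-opponent
   `lαβ` or CIELAB) and Macenko optical-density deconvolution
   (`OD = −log10(I/I0)`, SVD-plane angular extremes, non-negative
   unmixing) to isolate the hematoxylin channel.
2. **Cubical persistence** — lower-star filtration on the Freudenthal
   triangulation of the pixel grid; H0 by union-find with the elder rule,
   H1 by complement duality; verified against an unoptimised Z2
   boundary-matrix reduction.
3. **Representations** — ranked persistence vectors (descending
   persistences, H0-part ++ H1-part, truncated to collection-wide minimum
   counts) and persistence intensity surfaces
   `K̂(x, y) = Σᵢ (dᵢ − bᵢ) σ⁻² K((x − bᵢ)/σ) K((y − dᵢ)/σ)` with Gaussian
   `K` and σ = 0.05.
4. **Subtype discovery** — class-balanced bootstraps (every class
   subsampled without replacement to the smallest class size), PCA to six
   components, Ward clustering with the agglomerative coefficient and the
   Gap statistic (max-mean and one-standard-error rules,
   `s_k = sd_k √(1 + 1/B)`), meta-clustering of per-cluster Gleason
   composition vectors in R³, representative-bootstrap selection, and
   clusterwise Jaccard stability under resampling.
5. **Visualization** — t-SNE with perplexity chosen by the pseudo-BIC
   `pBIC(p) = 2·KL(P‖Q) + log(n)·p/n`, plus deterministic figure
   rendering.

Because clinical H&E images are not redistributable, the package ships a
first-class **synthetic histology generator**: parametric gland, cribriform,
sheet, and single-cell architectures rendered as grayscale hematoxylin maps
and, through a known Beer–Lambert stain-mixing model, as pseudo-H&E RGB —
giving every stage, including deconvolution, an exact ground truth.

## Worked example

Three well-circumscribed glands produce exactly three dominant loops:

```python
import numpy as np
import histotda as ht
from histotda.synthetic import default_spec, Pattern

spec = default_spec(Pattern.LOOSE_GLANDS, 256, seed=7, n_glands=3)
image = ht.generate_roi(spec)                 # grayscale, nuclei dark
diagram = ht.compute_persistence(image)       # H0 + H1 sublevel persistence
pers = np.sort(diagram.persistences(1))[::-1]
print(f"H0 points: {len(diagram.points(0))},  H1 points: {len(diagram.points(1))}")
print("top five H1 persistences:", np.round(pers[:5], 3))
print("dominant cycles (> half max):", int((pers > 0.5 * pers[0]).sum()))
```

prints

```
H0 points: 8934,  H1 points: 8708
top five H1 persistences: [0.78  0.776 0.766 0.041 0.038]
dominant cycles (> half max): 3
```

The three persistences near 0.78 are the glands (loops born when each
nuclear ring closes, dying only when the bright lumen fills); the long
tail of ~0.04 features is nuclear-scale texture.  Feeding the ranked
vectors of a labeled collection into `ht.run_discovery` returns
per-bootstrap Ward assignments, their agglomerative coefficients,
meta-clusters of composition vectors with Gap-selected k, the
representative bootstrap, and per-cluster Jaccard stability.

A command-line interface mirrors the stages
(`histotda synth | stain | persist | featurize | discover | embed`).

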
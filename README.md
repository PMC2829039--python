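# colonymorph

Morphometric subtyping of multicellular colonies grown in 3D
laminin-rich-ECM culture, and association of the resulting phenotypes with
gene expression.

Breast cell lines cultured in 3D form colonies whose shape reflects their
pathobiology: compact **round** acinus-like colonies, clusters of loosely
adherent **grape-like** lobes, and invasive **stellate** colonies with
radiating processes. `colonymorph` implements the computational protocol
that goes from phase-contrast images of such cultures to ranked lists of
genes that predict the morphological phenotypes:

1. **Segmentation** — colonies are delineated from the background by
   texture, not intensity. A bank of Gabor filters at `S = 4` scales and
   `K = 6` orientations (center frequencies `U_l = 0.05` to `U_h = 0.4`
   cycles/pixel, scale factor `a = (U_h/U_l)^(1/(S-1))`, Gaussian widths
   chosen so adjacent half-peak iso-curves in the frequency plane are
   tangent) is accumulated over orientation into one rotation-invariant
   kernel per scale. Two-class K-means over the per-pixel response
   magnitudes, initialized at the lowest and highest responses, separates
   textured foreground from smooth background; segmentation is exactly
   invariant to contrast reversal, so bright-on-dark and dark-on-bright
   colonies segment identically.
2. **Morphometry** — each colony is fingerprinted by a 33-dimensional
   vector: log10 area plus the magnitudes of 32 Zernike moments
   `A_nm = (n+1)/π Σ f · V*_nm(ρ, θ) ΔA` of the gradient-magnitude image over
   the colony's minimal enclosing disk, normalized by `|A_00|`. The
   representation is invariant to translation, rotation, contrast reversal
   and shading.
3. **Consensus clustering** — cell lines are grouped by repeatedly (100
   iterations) drawing 6 colonies per line, k-means clustering the pooled
   fingerprints, and scoring each pair of lines by the exact two-sample
   Kolmogorov–Smirnov p-value between their cluster-assignment samples.
   The averaged consensus matrix is computed for `k = 2 … 7`, and the
   number of subpopulations is selected from the peak proportional
   increase Δ(k) of the area under the consensus-entry CDF.
4. **Association** — genes are ranked one-vs-rest per morphological cluster
   by the moderated t-statistic (empirical-Bayes variance shrinkage,
   Benjamini–Hochberg FDR), and against per-line median colony size by
   linear and logistic (logit-transform) correlation with sign-taxonomy
   permutation p-values.

A seeded synthetic-data generator produces textured colony images of the
three archetypes with ground-truth masks, plus expression matrices with
planted differential and size-linked genes, so the entire pipeline is
testable end to end without any external data.

## Worked example

```python
from colonymorph.pipeline import run_synthetic_study

result = run_synthetic_study(seed=0, n_permutations=2000)
print(f"selected k* = {result.k_star}")
print(f"adjusted Rand index vs planted archetypes = {result.ari:.2f}")
print(f"mean segmentation IoU = {result.mean_iou:.2f}")
print(result.model.cdf_.table.round(3).to_string(index=False))
print("top stellate-cluster genes (moderated t):")
print(result.de_table[["t", "p_value", "fdr", "direction"]].head(4).round(3).to_string())
```

prints (a few minutes; 24 lines × 12 colonies):

```
selected k* = 3
adjusted Rand index vs planted archetypes = 1.00
mean segmentation IoU = 0.89
 k  area  delta
 2 0.463  0.463
 3 0.692  0.495
 4 0.701  0.013
 5 0.710  0.013
 6 0.716  0.008
 7 0.713 -0.005
top stellate-cluster genes (moderated t):
              t  p_value  fdr direction
gene_id
G0011    24.712      0.0  0.0         +
G0018    22.499      0.0  0.0         +
G0003    21.113      0.0  0.0         +
G0009    20.417      0.0  0.0         +
```

The Δ column peaks sharply at `k = 3`, so three subpopulations are
selected; they coincide exactly with the three planted archetypes
(adjusted Rand index 1.0). The top-ranked genes are all from the planted
differentially expressed set, with positive direction (up in the stellate
cluster).

The same chain is available as a CLI over file artifacts (TIFF images,
PNG masks, CSV/TSV tables, PNG heat maps):

```sh
colonymorph all -c config.yaml          # simulate → … → report
colonymorph cluster -c config.yaml      # re-run a single stage
```

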
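# tickniche

Curation and climate-niche analysis of tick occurrence records in the
western Palearctic.

Compiled occurrence records of ticks of medical and veterinary importance
(Ixodes, Dermacentor, Haemaphysalis, Hyalomma, Rhipicephalus) are noisy:
published reports mix precise coordinates with province-level localities,
outdated synonyms, and species groups that cannot be reliably separated.
`tickniche` is a pipeline for surveillance analysts and spatial
epidemiologists who want to go from such raw records to quantitative,
comparable descriptions of each species' climate niche:

1. **Record curation** (`records`) — parse delimited records, reject
   genus-only / administrative-division / ambiguous localities with a
   per-rule tally, harmonize names (e.g. *R. turanicus* and *R. sanguineus*
   collapse into the *R. sanguineus* group; *Hy. detritum* → *Hy. scupense*),
   and tabulate counts and host-order cross-tabs.
2. **Environmental attachment** (`rasters`) — attach monthly LST/NDVI (and
   optionally rainfall, Tmin/Tmax) grid values to each record by
   nearest-cell lookup on co-registered single-band rasters exchanged in a
   plain-text grid dialect.
3. **Climate space** (`climate`) — PCA of the correlation matrix of the 24
   monthly LST+NDVI variables over the background environment; records are
   projected into the retained axes (default 3).
4. **Niche overlap** (`overlap`) — the retained axes are gridded (default
   r = 100 bins per axis); per species, a Gaussian-kernel-smoothed
   occurrence density `o`, an availability density `e`, and the normalized
   occupancy `z` (by default `z ∝ o/e`) are computed. Overlap between two
   species is **Schoener's D**

       D = 1 − ½ Σ_cells |z₁ − z₂|,     D ∈ [0, 1],

   and the **niche equivalency test** re-partitions the pooled occurrences
   at random (keeping the two sample sizes), recomputes D per replicate,
   and reports the one-sided lower-tail permutation p-value
   `(1 + #{D_null ≤ D_obs}) / (N + 1)`.
5. **Habitat classification** (`habitat`) — unsupervised k-means on the
   standardized 24-month seasonal profiles yields categories with unique
   seasonal LST/NDVI patterns, plus per-category statistics and
   record-by-category cross-tabs (also usable with an external biome
   raster).
6. **Geographic summaries** (`hexgrid`) — per-species record percentages on
   a lattice of 0.5° pointy-top hexagons.
7. **Synthetic data** (`simulate`) — seasonal raster fields with sinusoidal
   monthly structure and occurrence samples drawn from Gaussian niches, so
   every estimate above can be checked against construction (including a
   numerically integrated true D).

## Worked example

Two synthetic species with a known mid-range niche overlap (isotropic
Gaussian niches 1.349 σ apart, for which the true D is 0.5), 500 records
each, analysed on a 100 × 100 grid over two climate axes:

```python
import numpy as np
import tickniche as tn
from tickniche.simulate import (separated_gaussian_pair, sample_niche_scores,
                                true_schoener_d)

rng = np.random.default_rng(0)
a, b = separated_gaussian_pair("mid", n_records=500)
sa, sb = sample_niche_scores(a, rng), sample_niche_scores(b, rng)
bg = rng.uniform(-6, 6, size=(3000, 2))          # background climates

grid = tn.make_grid(bg, np.vstack([sa, sb]), d=2, r=100)
da = tn.niche_density("warm-adapted", sa, bg, grid=grid,
                      correct_by_availability=False)
db = tn.niche_density("cool-adapted", sb, bg, grid=grid,
                      correct_by_availability=False, e=da.e)
print("estimated D :", round(tn.schoener_d(da, db), 3))
print("true D      :", round(true_schoener_d(a.mean, a.cov, b.mean, b.cov), 3))
res = tn.equivalency_test(sa, sb, bg, labels=("warm-adapted", "cool-adapted"),
                          n_permutations=99, seed=0)
print("equivalency : D = %.3f, p = %.2f" % (res.D, res.p_value))
```

This prints:

```
estimated D : 0.501
true D      : 0.5
equivalency : D = 0.496, p = 0.01
```

The kernel-density estimate of D lands on the construction-known overlap to
two decimals, and the equivalency test rejects niche interchangeability at
the minimum attainable p (= 1/(N+1) with N = 99 permutations) — the two
niches are genuinely distinct even though they overlap halfway.

A shell workflow over CSV/grid files is available through the `tickniche`
CLI (`simulate`, `validate`, `attach-env`, `pca`, `overlap`, `equivalency`,
`classify`, `crosstab`, `hexbin`); run `tickniche --help`.

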
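# karstbeta

Abundance-based beta-diversity partitioning for gridded forest-dynamics
plots, with Mantel tests against topographic drivers and environment/space
variation partitioning.

`karstbeta` is aimed at community ecologists working with stem-mapped census
plots (and, more generally, anyone analysing site × species abundance
matrices — the same machinery applies directly to microbiome or metagenomic
beta diversity).  It answers three linked questions about a plot: how much
do quadrats differ in composition, is that difference made of *balanced
substitution* of individuals or of *abundance gradients*, and how much of it
is explained by measured environment versus pure spatial structure?

## The statistics at the core

For two quadrats *m*, *n* with species counts *x*, let
A = Σₛ min(x_ms, x_ns) be the individuals shared, and B, C the individuals
unique to *m* and *n*.  The Bray–Curtis (percentage-difference)
dissimilarity splits additively into a balanced-variation and an
abundance-gradient component:

    β_BC     = (B + C) / (2A + B + C)
    β_BC.BAL = min(B,C) / (A + min(B,C))
    β_BC.GRA = |B − C| / (2A + B + C) · A / (A + min(B,C))
    β_BC     = β_BC.BAL + β_BC.GRA          (exact)

β_BC.BAL is the abundance analogue of species turnover (individuals of some
species at one site substituted by equally many individuals of other
species); β_BC.GRA is the nestedness analogue (one assemblage an
abundance-depleted subset of the other).  `karstbeta` computes all three for
every quadrat pair at a series of sampling grains (10–60 m cells at fixed
extent, with the conventional far-margin discard when a grain does not
divide the plot), then:

* **Mantel tests** (Spearman, seeded permutations) of each component
  against standardized Euclidean distances of eight topographic variables —
  elevation, slope, convexity, sin/cos of aspect, topographic wetness
  index, altitude above channels, rock bareness — singly and jointly;
* **dbMEM/PCNM spatial eigenvectors** from truncated inter-centroid
  distances (Moran's I > E(I) retention);
* **variation partitioning** via distance-based RDA on the square-rooted
  dissimilarities: forward-selected environmental polynomials (20 terms)
  and dbMEM axes give the classic fractions a (pure habitat),
  b (spatially structured habitat), c (pure space), d (undetermined),
  with Ezekiel-adjusted R².

Because stem-mapped census data are rarely redistributable, the package
ships a first-class synthetic generator: a fengcong-depression (clustered
karst peaks around a funnel) elevation model, a niche × neutral Poisson
community with a tunable `niche_weight`, and a second census linked to the
first by elevation-biased birth–death dynamics.

## Worked example

```python
from karstbeta import (SyntheticConfig, generate_dem, generate_community,
                       aggregate, decompose, simplex_summary,
                       env_table, env_distance, mantel)
from karstbeta.synthetic import generate_rbr, aggregate_rbr

cfg = SyntheticConfig(seed=42, x_extent=200, y_extent=100,
                      n_species=40, n_stems_target=4000)
dem = generate_dem(cfg)
census = generate_community(dem, cfg)
ab = aggregate(census, cfg.geometry(), 20)          # 20 m quadrats
comp = decompose(ab)
s = simplex_summary(comp)
print(f"mean beta_bc  = {1 - s.mean[0]:.3f} (SD {s.sd[0]:.3f})")
print(f"mean beta_bal = {s.mean[1]:.3f} (SD {s.sd[1]:.3f})")
print(f"mean beta_gra = {s.mean[2]:.3f} (SD {s.sd[2]:.3f})")

rbr = aggregate_rbr(generate_rbr(dem, cfg), cfg.geometry(), 20)
env = env_table(dem, cfg.geometry(), 20, channel_threshold=3, rbr=rbr)
res = mantel(env_distance(env[["ELE","SLO","CON","TWI","ACH","RBR","SIN","COS"]]),
             comp.matrix("bc"), n_perm=999, seed=1)
print(f"Mantel (env vs beta_bc): r = {res.r:.3f}, p = {res.p:.4g}")
```

prints

```
mean beta_bc  = 0.555 (SD 0.187)
mean beta_bal = 0.464 (SD 0.201)
mean beta_gra = 0.091 (SD 0.076)
Mantel (env vs beta_bc): r = 0.572, p = 0.001
```

Read: the 50 quadrats differ on average by 55% of their individuals, and
five sixths of that difference is balanced substitution (`beta_bal`), not
abundance loss (`beta_gra`); compositional difference tracks environmental
difference strongly (Mantel r ≈ 0.57 at the permutation-test floor
p = 1/1000, i.e. no permuted layout did better).

The same analysis runs from a shell — `karstbeta simulate`, `partition`,
`topo`, `mantel`, `dbmem`, and `run-all` for the whole pipeline with a YAML
config; `karstbeta run-all --seed 7 --outdir out/` writes a `report.json`
plus CSVs in which every seed and parameter is recorded.

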
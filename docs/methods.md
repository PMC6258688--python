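# Methods notes

This note records the models, conventions and numerical choices behind
`karstbeta`, in the spirit of a statistical appendix: what is computed, what
is assumed, and what the synthetic tests do and do not demonstrate.

## Bray–Curtis decomposition

For each quadrat pair the shared/unique individual counts (A, B, C) are
accumulated in 64-bit integer arithmetic and divided only at the last step,
so the additivity identity β_BC = β_BC.BAL + β_BC.GRA — an exact rational
identity — holds to machine precision in floating point.  Pairs in which at
least one quadrat is empty make β_BC.BAL a 0/0 form; such pairs are stored
as NaN, counted, and excluded from summaries rather than silently zeroed
(field data never contain empty quadrats, synthetic data can).  On 0/1
matrices β_BC collapses to Sørensen dissimilarity and β_BC.BAL to Simpson
dissimilarity; the test suite asserts both collapses against their direct
formulas, plus exact agreement with a brute-force per-species oracle and
invariance to uniform count scaling and species permutation.

Pairs are held as condensed upper triangles (scipy `pdist` ordering) with an
explicit site-order manifest, and the all-pairs computation streams in row
chunks: the finest grain (10 m, 1,500 sites, 1,124,250 pairs) never
materialises a dense pairs × species intermediate.

## Quadrat conventions

Coordinates are metres from the plot's SW corner (x east, y north).  Cells
are half-open, `[k·g, (k+1)·g)`: a stem exactly on the upper plot boundary
is invalid input, and no stem can fall in two cells.  Grains that do not
divide the extent use the largest origin-anchored sub-plot that does, so the
far (east/north) margin is the one discarded — on 500 × 300 m this gives
480 × 300 for 30 and 60 m cells and 480 × 280 for 40 m cells.  Stems below
the 1 cm dbh inclusion rule are dropped with a counted warning; dead/new
status between censuses is inferred from tag presence (a status column, if
ever supplied, would be cross-checked, not trusted).  Per-cell and
per-species dynamics tallies are both restricted to the grain's sub-extent
so their totals agree.

## Topographic variables

The published conventions for forest-plot terrain statistics leave several
details open; the ones fixed here are:

* **ELE** — mean of the cell's four corner elevations.  Corners that fall
  between lattice nodes (25 m cells on a 10 m lattice) are interpolated
  bilinearly.  Note this corner-based coarse ELE re-reads the node grid; it
  equals the mean of the constituent fine-cell ELEs only on (piecewise)
  planar terrain.
* **SLO** — mean slope, in degrees, of the four planes through three of the
  four corners (the classic plot-survey convention); an inclined plane of
  gradient 1 gives exactly 45°.
* **Aspect** — direction of steepest ascent of the least-squares plane
  through the corners, measured clockwise from north and reported as
  SIN/COS.  (The sign convention is immaterial downstream because SIN/COS
  enter only through distances; a plane rising eastward has SIN = 1,
  COS = 0.)  Cells flatter than 1e-6° report SIN = COS = 0 and a flag.
* **CON** — focal ELE minus the mean ELE of the 8 neighbouring cells;
  border cells use centre-point elevation minus own ELE.  At the base grain
  the centre interpolates to the corner mean, so border convexity is 0
  there by construction.
* **TWI / ACH** — deliberately *simplified* single-flow-direction (D8)
  stand-ins: flow accumulation `a` counts upslope cells (ties in the
  steepest-descent direction broken in a fixed E, NE, N, NW, W, SW, S, SE
  order), TWI = ln(a·g / tan(max(SLO, 0.1°))), channels are cells with
  `a ≥ channel_threshold`, and ACH is focal ELE minus the ELE of the
  Euclidean-nearest channel cell.  Real hydrological TWI/ACH (multi-flow
  direction, stream burning) differ; externally computed TWI/ACH — like the
  field-surveyed rock-bareness rate RBR — can be supplied as per-site
  columns that override the internal computation.

Environmental distance z-scores each variable (n−1 denominator) before
Euclidean distance; zero-variance columns are excluded with a warning.
Whether to z-score per variable or jointly is a genuine ambiguity in common
practice; per-variable scaling was chosen so each driver contributes
comparably, and single-variable distances use the same path.  The
third-degree polynomial expansion centres each of ELE, SLO, CON, TWI, ACH,
RBR and emits (v, v², v³), keeping SIN/COS linear — 20 predictors in a
fixed, documented column order; constant columns yield zero polynomial
terms (with a warning) rather than silently shrinking the design matrix.

## Mantel tests

The statistic is the Spearman correlation of the two condensed triangles
(diagonal excluded, average ranks); the null permutes site labels of the
second matrix.  Since relabelling only permutes the multiset of off-diagonal
entries, ranks are permutation-equivariant and can be computed once — each
permutation is then a gather plus a dot product, which is what makes 9,999
permutations affordable at several hundred sites.  p = (#{r* ≥ r} + 1) /
(n_perm + 1), never below 1/(n_perm+1); the default alternative is
one-sided "greater" (the convention of the standard implementations), so
negative correlations report large p unless the two-sided switch is used.
A small-n exhaustive mode enumerates all n! relabellings exactly.  The
grain-trend test (Spearman of component mean vs grain size) uses the exact
two-sided permutation distribution of rho for ≤ 9 tie-free grains — seven
strictly decreasing means give rho = −1, p = 2/5040 ≈ 0.0004 — and the
large-sample approximation otherwise.

## dbMEM and variation partitioning

Spatial eigenvectors: Euclidean distances between cell centroids are
truncated at t = the longest minimum-spanning-tree edge (which provably
keeps the ≤ t neighbour graph connected; on a full grid t is one lattice
step), distances above t are set to 4t, and −½D*² is double-centred and
eigen-decomposed.  Positive axes (λ > 1e-9·λ_max) are candidates; Moran's I
is computed per axis with binary ≤ t connectivity weights (row-unstandardised
— the classic PCNM practice; no distance-decay weighting), and axes with
I strictly greater than E(I) = −1/(n−1) are retained.  Eigenvector sign is
fixed by making the largest-magnitude loading positive so output is
identical across linear-algebra backends.

Response matrices: Bray–Curtis and its components are square-rooted before
principal-coordinate analysis.  For β_BC this renders the matrix
Euclidean-embeddable (asserted in tests); the BAL/GRA components carry no
such guarantee, and their occasional negative eigenvalues are discarded
with a warning — a correction method (Lingoes/Cailliez) is deliberately out
of scope.  Axes are scaled to √λ so ordinary least squares on the axes is
db-RDA.

Forward selection follows the double-stopping protocol: a permutation test
of the *global* all-candidate model gates the whole procedure (without this
gate the best-of-k selection bias inflates null selections well above the
nominal level; with it the null selection rate sits at ~α, which the test
suite checks by simulation), then candidates enter greedily while their
residual-permutation p ≤ α and the cumulative adjusted R² stays below the
global model's.  The per-step test permutes the response residualised on
the already-selected predictors (permutation-of-residuals); implementations
that permute the raw response differ only beyond step 1.  Saturated global
models (as many candidates as sites, R² ≡ 1) make the gate uninformative,
so it is bypassed with a warning; each predictor set is additionally capped
at half the available model degrees of freedom so the combined model stays
estimable at coarse grains with few cells.

Fractions use Ezekiel's adjustment, adjR² = 1 − (1 − R²)(n−1)/(n−m−1), with
m the column count of the selected set: a = adjR²(E+S) − adjR²(S),
c = adjR²(E+S) − adjR²(E), b = adjR²(E) + adjR²(S) − adjR²(E+S),
d = 1 − adjR²(E+S); a+b+c+d = 1 by construction, and slightly negative
individual fractions are legitimate adjusted-R² arithmetic.  Permutation-
based R² adjustment would be the main alternative and is the one place
results can deviate slightly from other software.

## The synthetic plot

The generator emulates the study conditions of a 15-ha karst
fengcong-depression census: a 500 × 300 m plot, 10 m elevation lattice,
relief 190 m above a 180 m base, ~220 species and a 68,000-stem target, and
per-census-interval mortality/recruitment fractions of 0.144 and 0.057 (the
observed plot-wide rates of the system being emulated).

* **DEM** — sum of K Gaussian hills (default 6), one broad negative
  Gaussian bowl (the depression), and low-frequency smoothed noise,
  affinely rescaled to span exactly [base, base + relief].  Degenerate
  configs (relief 0) give a flat grid.
* **Community** — expected abundance of species s in 10 m cell c is
  `exp(α_s + w·niche_s(ELE_c, SLO_c) + (1−w)·GRF_s(c))`, scaled so the
  expected total hits the stem target; counts are Poisson and stems are
  placed uniformly within their cell (cell-level placement, not a point
  process — downstream analyses only ever use per-cell counts).  α_s is a
  lognormal species-abundance effect; the niche is Gaussian in elevation
  (tolerance 0.18 of the relief) with a weaker slope term; the neutral
  component is a per-species Gaussian random field built by kernel-smoothing
  white noise to correlation length `neutral_range` (default 40 m) and
  standardising.  `neutral_range ≤ 0` is defined as *no* neutral
  heterogeneity, so `niche_weight = 0` with zero range yields exactly
  independent Poisson counts — the test suite checks the variance/mean
  ratio there.  The default `niche_weight` of 0.6 encodes a
  deterministic-leaning mix.
* **Second census** — a stem in a cell with relative elevation e dies with
  probability 1 − (1 − mortality_base)^g(e), g(e) = exp(bias·(0.5 − e)),
  bias 1.5, concentrating turnover in depressions while keeping the
  plot-wide fraction near the base rate (Jensen's inequality pushes the
  realised fraction somewhat above it); recruits are Poisson per cell with
  intensity ∝ N_cell·g(e) and species drawn from the cell's composition.
  No quantitative turnover-vs-elevation model exists for the emulated
  system, so this form is a modelling choice, not an inference.  There is
  no growth, no size-structured mortality, and dbh is a formatting field
  (lognormal ≥ 1 cm) only.

What passing the synthetic tests shows: the pipeline recovers *known*
structure — a pure-niche plot yields (a+b) > c and a pure-neutral,
spatially autocorrelated plot yields c > a in ≥ 95% of seeded replicates,
and mean β_BC declines strictly and monotonically over the 10→60 m grain
series.  What it does not show: anything about the magnitudes of real-plot
fractions, which depend on unmeasured environment, true dispersal, and
sample sizes of the field system.

## Determinism and problem sizes

Every random stage draws from a stream derived from one master seed
(SeedSequence spawn keys; per-stage labels CRC-32-hashed, all derived seeds
< 2³¹ and recorded in the report), so identical configurations give
byte-identical reports.  The pipeline default of 9,999 permutations matches
standard practice for both Mantel and forward selection.
`scripts/acceptance.py` runs the full 500 × 300 m plot over all seven
grains for the component means and grain trend, and concentrates the
permutation-heavy stages at the focal 20 m grain (375 cells, 70,125 pairs)
with 999 Mantel and 199 forward-selection permutations — the grain series'
pair counts, not the permutation counts, dominate its run time.  Unit tests
run on a 200 × 100 m plot (~4,000 stems) and 99–199 permutations.
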
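# Methods

`landgen` re-implements, as a tested pipeline, a landscape-genetics
analysis of mtDNA haplotype samples from habitat patches embedded in a
mosaic of land uses: per-patch diversity, pairwise differentiation with
permutation significance, and a three-way comparison of genetic distance
against straight-line geography, least-cost paths, and circuit-theory
resistance on a conductance raster. This note records the statistical
conventions, numerical choices, and the design of the synthetic-data
generator, in enough detail to reimplement every number the package
prints.

## Sequence statistics

All diversity statistics operate on *retained sites*. The default filter
is complete deletion: every alignment column containing a gap (`-`) or an
IUPAC ambiguity code in any record is removed before analysis, the
convention of the standard diversity software for population tables.
Pairwise deletion (each sequence pair scored on the sites where both carry
an unambiguous base) is available for π. Haplotype identity is exact
sequence equality over retained sites; ambiguity codes never match
anything, which is moot under the default filter since they are removed
first.

* **S** — retained columns with ≥ 2 distinct bases.
* **Hd** — Nei's unbiased haplotype diversity,
  `Hd = n(1 − Σ p_i²)/(n − 1)`; its variance is the sampling formula of
  Nei (1987, eq. 8.12),
  `V = 2/(n(n−1)) · [2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²]`.
* **π** — mean over all sequence pairs of the per-site proportion of
  differing retained sites. Two standard deviations are implemented: the
  analytic *total* (stochastic + sampling) variance of Nei (1987,
  eq. 10.7), `V = (n+1)π/(3(n−1)L) + 2(n²+n+3)π²/(9n(n−1))`, and a seeded
  bootstrap over sequences estimating the *sampling* spread only. The
  sampling SD is the default for tables: the total variance includes the
  evolutionary variance of the coalescent and is several-fold larger than
  the tight SDs conventionally printed beside sample π values. Output
  metadata records which was used.
* **γ_ST** — Nei's haplotype-frequency analogue of F_ST between two
  populations: `γ = (H_T − H_S)/H_T`, where `H_S` is the unweighted mean
  of the two populations' unbiased diversities and `H_T` is the unbiased
  diversity of the pooled counts (pooled `n/(n−1)` correction). Because
  the within-population (n) and pooled (2n) corrections differ, identical
  equal-n samples give a γ slightly *below* zero, of order 1/(2n); this is
  a property of any bias-corrected estimator of this form. Negative
  estimates are reported as computed with a flag, never clamped. If both
  populations are monomorphic for the same haplotype, `H_T = 0` and the
  result is flagged "no variation" (NaN), not 0.
* **Snn** — Hudson's (2000) nearest-neighbour statistic. For sequence j,
  `x_j` is the fraction of j's nearest neighbours — minimum Hamming
  distance over all other sequences, equidistant ties sharing weight
  equally, self excluded — that belong to j's own group; `Snn = mean x_j`.
  Significance permutes group labels; the add-one rule
  `p = (1 + #{Snn* ≥ Snn})/(B + 1)` keeps p in `[1/(B+1), 1]`. Pairwise
  patch tables test each patch pair on the subset of sequences sampled in
  those two patches. Singleton groups are allowed.

## Landscape graph

A class raster plus a class → conductance map yields a conductance
surface (no-data → 0), then a sparse symmetric transition graph: every
cell is joined to its 8 neighbours with transition value
`t_ij = (c_i + c_j)/2` (arithmetic mean, the convention of the raster
connectivity tooling this mirrors; geometric mean available). Cells of
conductance 0 are removed from the graph rather than given infinite cost,
so connectivity failures are explicit errors (strict mode) or flagged
infinities.

Two geometric distortions of a lon/lat grid are corrected:

* **LCP correction** — each transition is divided by the great-circle
  distance between the two cell centres (haversine on a sphere of radius
  6 371 000 m). Least-cost distances then accumulate edge costs `1/t_ij`
  along Dijkstra shortest paths.
* **IBR correction** — north–south transitions are multiplied by the
  cosine of the mean latitude of the two centres, weighting the random
  walk by the surface area reached. The correction's usual statement
  covers only the N–S case; diagonal transitions here receive the same
  cosine factor (they have a N–S component) and east–west transitions are
  unchanged — an implementation convention, documented because the choice
  is invisible at the latitude spans the package targets.

Corrections do not compose; correcting an already-corrected graph is an
error. A `planar` correction (divide by Euclidean centre distance in cell
units) supports unit-grid work and the exhaustive graph oracles in the
test suite.

Resistance (IBR) distances are expected random-walk commute times,
`C(i,j) = vol(G) · R_eff(i,j)`: `R_eff` comes from grounded-Laplacian
sparse LU solves (one factorization per connected component, one solve per
query cell), `vol(G)` is the sum of weighted degrees. Mantel inference is
invariant to the `vol(G)` scaling; it is kept so the matrix reads in
"expected steps". Corridors are single optimal Dijkstra paths with ties
broken deterministically by predecessor order; each corridor reports its
land-use composition as the fraction of path cells per class.

Raster I/O is the ESRI ASCII grid text dialect, with the `dx`/`dy` header
extension for non-square cells; projected rasters are rejected with a
pointer to reprojection. Point-in-cell lookup uses half-open intervals
`[x, x + Δ)` with a 1e-10-cell epsilon against float cancellation; a query
point on an impermeable cell is snapped to the nearest permeable cell
centre with a warning recording the snap distance. Block aggregation to
coarser cells is modal for class rasters (ties to the smallest class
code) and mean for conductance rasters.

## Mantel tests and model comparison

Mantel r is the Pearson correlation of the lower triangles; the null
permutes patch labels jointly over rows and columns of one matrix. With
k ≤ 5 patches all k! relabelings are enumerated — for k = 5 the identity
plus 119 permutations, the maximum a 5 × 5 matrix allows — giving an
exact, seed-independent p (the identity plays the role of the add-one
term). Monte-Carlo permutation with the add-one rule handles larger k.
The alternative is one-sided ("greater") by default, matching the
prediction that genetic distance increases with landscape distance.
`compare_models` runs IBD, LCP and IBR against the γ_ST matrix and flags
the model with the highest r among those with p ≤ α (default 0.05), or
none. A constant matrix (zero variance in the lower triangle) makes r
undefined; the result is flagged rather than coerced.

## Synthetic-data generator

The generator emulates the study design end to end: a multi-class
lon/lat raster built from a declarative geometry spec (background class,
rectangles, 8-connected Bresenham polylines; contradictory overlaps are
rejected naming the first conflicting cell), k patch cells, a conductance
map, and a forward-in-time finite-island demography:

* k haploid demes of fixed size (Wright–Fisher multinomial resampling);
* each offspring draws its parental deme with probability proportional to
  `exp(−LCP_ij/λ)` for j ≠ i, rows normalized to a total migration rate m,
  so gene flow decays with the least-cost distance computed from the very
  raster the pipeline will later analyse — the simplest monotone kernel;
  any monotone decreasing kernel induces the same rank structure;
* per-site substitution to a uniformly chosen different base
  (Jukes–Cantor-like) at rate μ per site per generation; no indels, no
  rate heterogeneity;
* after T generations, n_k sequences are sampled per deme without
  replacement. Identical config + seed reproduce byte-identical FASTA.

### The `corridor5` preset

Mirrors the shape of the study system: five patches, per-patch sample
sizes {12, 18, 9, 24, 10} (73 sequences), 527-bp sequences, five land-use
classes (native forest, grassland–shrubland, farm, plantation forestry,
mixed forest) with conductances {1.0, 0.6, 0.05, 0.2, 0.5}. The corridor
chain FR1–FR2–FR3–FR4–FR5 zigzags between the north and south edges of a
60 × 60 grid, so chain neighbours are geographically far apart while
chain-distant patches sit close together: across the ten patch pairs the
straight-line and least-cost matrices are essentially uncorrelated
(Pearson r ≈ −0.03). This is the property the preset exists to provide —
a landscape in which geography alone carries no information about
connectivity, so recovering the corridor structure from the genetic data
is a real test, not a restatement of isolation by distance.

Demographic defaults: deme size 60, μ = 3 × 10⁻⁵ per site per
generation, total migration rate m = 0.05, kernel scale λ = 6 400 cost
units (about a quarter of the median patch-pair least-cost distance, so
chain neighbours exchange migrants readily while chain-distant pairs are
effectively isolated), T = 600 generations (≈ 10 deme-coalescent times,
enough to reach quasi-equilibrium from the monomorphic start). These were
chosen so the sampled data land in the empirically realistic regime for a
hypervariable mtDNA fragment in a patchy rodent population: per-patch
Hd ≈ 0.8–0.95, π ≈ 0.005–0.015, pairwise γ_ST ≈ 0.02–0.13.

### What the generator does *not* emulate

Real control-region data carry indels, strong among-site rate
heterogeneity and tandem repeats; real populations have fluctuating sizes,
sex-biased dispersal and seasonal structure; and the single mtDNA locus
the generator (like the study design) relies on is one draw from a
high-variance coalescent. Passing tests therefore demonstrate that the
pipeline recovers landscape structure *when the island-model assumptions
hold at these effect sizes*, not that any single empirical dataset would
yield an unambiguous answer — indeed, in roughly half the corridor
replicates no model reaches significance at α = 0.05 even though the
ranking favours LCP, a faithful reflection of the power available from
one locus and five patches.

## Problem sizes

Desk-scale defaults keep every stage interactive: the corridor scenario
is a 60 × 60 grid (3 600 graph nodes), simulations run in ~0.1 s, the
replicate experiments use 50 fixed-seed replicates, permutation tests use
B = 1000 (Snn) and the exhaustive 120 relabelings (Mantel, k = 5). The
acceptance script re-runs the full chain plus the 50-replicate experiment
in well under a minute.

## Known limitations

* γ_ST uses haplotype frequencies only; with very high haplotype
  diversity it saturates toward 0 and loses resolution — an intrinsic
  property of the estimator, visible in both synthetic and published
  tables.
* The γ_ST bias corrections follow the documented estimator above;
  third-decimal agreement with other software's tables depends on their
  (unpublished) correction details and is treated as calibration.
* Raster support is geographic (lon/lat) ESRI ASCII grids only; projected
  rasters and native-R grid files must be converted externally.
* The IBR correction's treatment of diagonal edges is a documented
  convention (see above); alternatives change commute distances by well
  under the Mantel-relevant scale at small latitude spans.
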
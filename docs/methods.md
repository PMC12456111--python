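# Methods

This note documents the models, estimators and numerical choices behind
`landgen`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the workflow left room.

## Data model

Genotypes are biallelic diploid dosages (alternate-allele counts 0/1/2)
with a dedicated missing sentinel (−1); 0 is a legal homozygote and never
doubles as "missing". The locus-group identifier for the first-SNP-per-locus
rule is the VCF CHROM field, which is where de-novo RAD assemblers put the
tag id. VCF positions are 1-based; everything internal is 0-based
half-open. Rasters are ESRI ASCII grids sharing one geotransform and a
nodata mask equal to the union of the per-layer masks; row 0 is the north
edge and a point belongs to the cell whose half-open interval contains it.
GeoTIFF is deliberately not supported: the ASCII grid covers the gridded
inputs the pipeline needs while keeping every artifact plain text.

## Estimators

* **Gene diversity / π.** At a variant site with alternate-allele frequency
  p estimated from n sampled alleles, the unbiased gene diversity is
  2p(1−p)·n/(n−1), which equals the mean pairwise allele difference. π for
  a population is the mean over the variant sites of the filtered matrix —
  a site monomorphic within the population contributes 0. Because an SNP
  matrix carries no invariant sites, this is a per-variant-site π (the
  convention of SNP-matrix pipelines), roughly an order of magnitude larger
  than genome-wide per-site π; comparisons should stay within the package.
* **F_IS** = 1 − mean(H_O)/mean(H_E), means taken before the ratio.
* **F_ST.** Weir & Cockerham (1984) variance components with per-locus
  sample sizes; multilocus values combine loci by ratio of sums (not a mean
  of ratios), the stable choice for RAD data. Small negative estimates are
  kept: the estimator is unbiased around zero. Loci with fewer than two
  populated samples, or with no data in either member of a pair, are
  skipped. Tests pin all of this to an independent loop-transcription of
  the published formulas at 1e−10, and to the parametric truth: on
  Balding–Nichols simulations at F = 0.15 (27 populations, 5,000 loci) the
  mean pairwise multilocus θ lands within ±0.02 of F.
* **Genotype PCA.** Dosages centred by 2p̂ and scaled by √(2p̂(1−p̂)) (the
  GRM convention); missing cells are mean-imputed per locus, monomorphic
  loci dropped. Population-mean scores on the first three axes are the
  structure proxies used downstream.

## Outlier scans and the partition

The **PC-deviation scan** regresses each scaled dosage column on the first
K principal-component score vectors, collects the K z-scores per locus,
and measures a robust Mahalanobis distance (minimum covariance determinant)
across loci. Distances are rescaled by the genomic inflation factor
(median distance over the χ²_K median) and converted to χ²_K p-values with
BH correction; flag = q < 0.05. K defaults to 3, the number of genetic
groups.

The **envelope scan** reproduces the F_ST-vs-heterozygosity logic of
coalescent outlier software with a parametric null: loci are simulated
under a Balding–Nichols island model whose F is the 5 %-trimmed mean of the
observed per-locus θ ("neutral mean F_ST"), with genotype counts drawn at
the observed per-population sample sizes under Hardy–Weinberg. Observed and
simulated loci are binned on pooled expected heterozygosity (20 equal-width
bins on [0, 0.5]; bins with fewer than 100 null draws are widened
symmetrically and the widening logged). The per-locus p-value is the
upper-tail fraction of null θ in the bin; a locus is flagged when it falls
in the top-1 % tail *and* its BH q is below 0.05 — the conjunction of the
two published criteria, each also reported separately. The default null
size is 1,000,000 draws; tests and the acceptance script use 10⁵–3×10⁵,
at which the flag set is already stable (checked by a Monte-Carlo
stability test at 10⁵ vs 2×10⁵).

On hierarchically structured data the envelope scan flags far more loci
than the PC scan — the island-model null cannot express between-group
variance — which is exactly the behaviour of its coalescent ancestor (the
emulated study flagged ~30 % of loci with it). The **partition** therefore
requires every configured method to agree: outliers are the intersection
of the per-method flag sets (an externally produced flag file may join as
a third method), and the complement is the neutral set used for diversity,
structure and IBD/IBE.

## Spatial predictors, Mantel tests, variance partitioning

dbMEMs truncate the great-circle distance matrix (haversine, R = 6371.0088
km) at the longest minimum-spanning-tree edge, replace larger distances by
4× the truncation, double-centre the squared distances and keep the
positive-eigenvalue eigenvectors; the construction reproduces `vegan::pcnm`
to machine precision (a test feeds both the same matrix). Each vector gets
a positive-tail Moran's I permutation test against binary
within-truncation connectivity; the pipeline uses the first three
significant vectors, matching the emulated design.

The Mantel statistic is the Pearson correlation of strictly-lower-triangle
entries; the one-sided p permutes rows and columns of the second matrix
jointly, p = (1 + #{r* ≥ r})/(B + 1) at B = 999, so the floor is 0.001.
Genetic distance defaults to raw pairwise θ (a linearised θ/(1−θ) switch
exists); IBD/IBE are directional hypotheses, hence the upper tail.

RDA fits centred population × locus frequencies on standardised
predictors; the headline fraction is Ezekiel's adjusted R², identical to
`vegan::RsquareAdj` (tested). Partial fractions are differences of
adjusted R² between nested models. Permutation tests follow Freedman–Lane:
the conditioned response is re-formed from the Z-fit plus permuted
residuals, re-residualised, and compared on a pseudo-F with the proper
residual degrees of freedom — naive residual permutation is anticonservative
here and fails the null calibration test that guards this. The variance
partition reports, for {environment, geography, structure}, the full
model, each set conditioned on the others, each marginal fraction, and the
confounded remainder; small negatives are expected of adjusted R².

## GEA

The **ridge LFMM** is the deterministic alternating solver: latent factors
from a truncated SVD of the residual Y − x·bᵀ, effects from ridge
regression of Y − UVᵀ on x, to convergence (tol 1e−5, ≤ 200 iterations);
final z-scores come from the per-locus OLS refit on [1, x, U], calibrated
by the genomic inflation factor (median z² over the χ²₁ median) and BH
corrected per variable. With K = 0 the scan reduces exactly to per-locus
simple regression (tested). Null p-values on structured Balding–Nichols
frequencies pass a Kolmogorov–Smirnov uniformity check at 3,000 loci.

The **RDA loading scan** takes locus loadings on the first
min(3, available) constrained axes and flags |loading − mean| ≥ 3 SD per
axis (the boundary is inclusive). The fit is conditioned on the first K
principal components of the response — the structure-corrected RDA of the
emulated protocol; without the correction the axis-score spread is inflated
by neutral structure and the scan loses most real clines. **Core
candidates** are the intersection of the two hit sets, with each core
locus's associated variables taken from its significant LFMM variables;
the same operation runs within each genetic group (groups come from a
supplied assignment, else k-means with k = 3 on the first two genotype-PCA
population scores).

## Gradient forest and offsets

Each locus with variance gets a random-forest regression of its population
frequencies on the predictors: 500 trees by default ("regressions per
SNP"), mtry = ⌈P/3⌉, unlimited depth, bootstrap over populations, all
seeded. Loci with positive out-of-bag R² are retained. Predictor importance
is the mean over retained loci of out-of-bag permutation importance (in R²
units, computed per tree on its held-out samples with all shuffles batched
into one predict call — in-sample importance would credit noise predictors
that deep trees overfit) times locus R². Every split's weighted impurity
decrease is credited to its predictor at the split value; improvements are
accumulated into 201 equal-width bins over the predictor's observed range,
scaled so the total equals the predictor's weighted importance, and
cumulatively summed. F_p is evaluated by interpolation over the bin edges,
so F_p(min) = 0 and F_p(max) = importance exactly; outside the training
range values are clamped — extrapolated turnover is undefined by the
method. Density standardisation of split improvements is omitted (the
offsets depend on the relative turnover shape); a coarser or finer binning
is a constructor argument.

Variable pruning is greedy: while any pair exceeds |r| = 0.75, drop the
lower-importance member of the most correlated pair (oracle-tested against
an independent transcription).

Offsets are Euclidean distances in composition space. Forward offsets
search *grid cells*, not only sampled populations, using the pairwise
great-circle matrix of valid cell centres; the searched set always contains
the cell itself, so forward ≤ local and forward is monotone non-increasing
in the radius by construction (both identities are asserted, and a 3×3 grid
is checked against an exhaustive double-loop oracle). "Unlimited" is any
radius at least the grid diameter. The RGB composite min–max scales
local/forward/reverse to [0, 255] and records the bounds so the scaling is
invertible up to quantisation.

**RONA**: for each variable and each core locus associated with it, an OLS
fit p = a·v + b across populations (kept when the slope p-value < 0.05);
RONA(pop, v, locus) = |a·v_fut + b − p_obs|, averaged over loci with R²
weights (uniform weighting is a flag) and reported with the weighted
standard error. Exact-linear loci give RONA = |a|·Δv identically.

## The synthetic generator

The generator emulates the sampling design and statistical structure the
analysis assumes: 27 populations of 2–17 diploids in three longitudinal
groups on a 40 × 72 half-degree grid (an East-Asia-sized extent with a
masked "ocean" wedge); 19 bioclimatic layers built from four shared latent
gradient fields (temperature level, diurnal range/isothermality,
precipitation totals, precipitation seasonality — within-family
correlations ≈ 0.9, as in real WorldClim layers, so the |r| > 0.75 pruning
step has real work to do) plus five independent smooth soil fields; four
future epochs adding a spatially structured shift that grows with emission
scenario and horizon (soils unchanged). Neutral allele frequencies follow
a hierarchical Balding–Nichols model (group level F = 0.25, population
level F = 0.05) coupled within groups through a Gaussian copula with an
exponential spatial kernel (range 800 km), which produces both the
three-group structure and isolation by distance. Thirty adaptive loci are
logistic clines in one standardised driver variable each (|β| ∈ [1, 3],
drivers cycling over bio2, bio5, bio15, bio18); a truth table records
locus, driver and β. Genotypes are Binomial(2, p) with 5 % uniform
missingness, and 5 % of RAD tags carry a second linked SNP to exercise the
first-SNP rule. `final_env_variables` exposes the ten-variable registry the
emulated study retained (driver climate variables + isothermality + five
soil factors).

What the generator does **not** emulate: linkage disequilibrium along
chromosomes, non-equilibrium demography, selection dynamics through time,
genotyping-error structure, or missingness that correlates with depth.
Passing tests therefore demonstrate the statistical machinery under the
assumed generative model, not performance on any particular empirical
dataset.

Two pipeline-level behaviours are worth knowing. First, GEA runs on the
non-outlier loci (as in the emulated workflow), and strong planted clines
are often flagged by the F_ST scans — about a third of them leave the GEA
input this way, so end-to-end recovery is necessarily below the recovery of
the scans run on the full filtered matrix. Second, the data-driven pruning
step may retain a correlated family member instead of the nominal driver;
detection then runs through a proxy at r ≈ 0.9 and loses some power. Both
are properties of the workflow being reproduced, not defects of the scans.

## Problem sizes and determinism

Defaults are chosen so a full synthetic study runs in minutes on one core:
3,000 neutral + 30 adaptive loci, 10⁵–3×10⁵ envelope-null draws in tests
and the acceptance script (10⁶ remains the config default), 500 trees per
SNP with the gradient forest fitted to a 120–150 locus subsample for
ranking and mapping, 999 permutations for Mantel/RDA/Moran tests. Every
stochastic step takes an explicit seed; two pipeline runs with the same
seed produce byte-identical CSV outputs (tested), and the stage graph
caches on content hashes, so re-running a finished directory is a no-op and
deleting an intermediate recomputes exactly its descendants.

## Known limitations

* The envelope scan's parametric null understates between-group variance on
  hierarchical data; it is deliberately used only inside the intersection
  rule.
* Population-level responses (27 rows) bound the resolution of all
  regressions; individual-dosage modes exist but are not the tested path.
* The adjusted-R² fractions can be small negatives; the variance partition
  reports them as computed.
* Future rasters on a coarser grid are bilinearly resampled onto the
  current grid before offsets (logged when it happens); nodata is carried
  over by nearest neighbour, so mask edges can shift by up to one coarse
  cell.
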
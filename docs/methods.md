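# Methods

This note documents the statistical model behind `lakescape`, the
parameter choices and their rationale, the design of the synthetic
landscape generator, and the numerical conventions. Everything here is
implemented in `src/lakescape/` and exercised by the test suite.

## Data model

A study consists of an OTU count table (lakes × OTUs, with a
seven-rank lineage per OTU) and per-lake metadata: coordinates, basin
membership, seven chemistry variables (`temperature`, `pH`, `DO`,
`turbidity`, `chl_a`, `TP`, `NO23`) and six land-use fractions
(`urban`, `hetero_agri`, `pasture`, `arable`, `forest`,
`water_wetland`) at two scales, whole drainage basin (`basin_`) and
local buffer (`local_`). Land-use fractions must sum to 1 (±10⁻⁶ per
scale); they are compositional, which matters below.

## Preprocessing

1. Drop OTUs with fewer than 5 reads across all lakes (sequencing-noise
   floor).
2. Rarefy every lake to a common depth of 25,000 reads by sampling
   without replacement (multivariate hypergeometric). Lakes below the
   depth are dropped with a logged warning rather than silently
   up-weighted. Rarefaction is seeded and reproducible.
3. Abundance models for Euclidean methods use log₁₀(1 + x).

## Community description

Shannon diversity uses natural logs. Dissimilarity is Bray–Curtis on
counts or Jaccard on presence/absence. Occupancy categories (fractions
of lakes occupied): unique = exactly one lake, rare < 10%,
intermediate 10–50%, common > 50%, cosmopolitan > 90%, core = all
lakes; precedence is core > cosmopolitan > common > intermediate >
rare > unique.

## Distance decay

Geographic distances are great-circle (haversine, Earth radius
6371 km). The statistic is Spearman's ρ between geographic and
community distance over lake pairs (optionally restricted to within- or
between-basin pairs). Because pairs sharing a lake are dependent, the
permutation p-value is Mantel-style: lake labels of the community
matrix are permuted jointly and ρ recomputed, p = (hits + 1)/(n + 1).
The analytic Spearman p is also reported but should be treated as
anticonservative.

## Land use → chemistry: multimodel inference

For each chemistry response, all 2⁶ = 64 subsets of the six land-use
fractions are fit as Gaussian linear models. AIC counts the residual
variance as a parameter, AIC = −2·logL + 2(p + 1), so a k-predictor
model pays for k + 2 parameters. Akaike weights are
wᵢ ∝ exp(−Δᵢ/2) with Δᵢ = AICᵢ − min AIC; predictor importance is the
summed weight of models containing the predictor; model-averaged
coefficients use shrinkage averaging (absent predictors contribute 0).

Because the six fractions sum to 1, the full 7-column design (with
intercept) is exactly singular. Aliased subsets are skipped from the
ensemble (logged), and all R²-only quantities use a rank-tolerant
projection R² computed from the SVD of the centered design, which
depends only on the column space. Independent contributions use
hierarchical partitioning: the R² gain of adding a predictor, averaged
within each model size and then across sizes — equal to the Shapley
value of R², so contributions sum exactly to the full-model R²
(verified against the all-orderings oracle in the tests). It is
tractable to k = 12 predictors.

## Chemistry → community: CCA and permutation inference

CCA operates on Q = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2), where P is the
table normalized to sum 1 and r, c its margins; total inertia equals
Pearson χ²/N (an identity the tests enforce). Constraints are
row-weight centered and standardized, Q is projected onto their
weighted column space, and the SVD of the projection gives the
canonical axes; eigenvalues are squared singular values. Reported
scores use scaling 2 (OTU scores scaled by singular values, linear
combination site scores); biplot scores are row-weighted correlations
between constraints and axes. Output matches R `vegan::cca` exactly
(cross-checked in the tests when `Rscript` is present).

Significance uses permutation of rows of the constraint matrix:
pseudo-F = (constrained inertia/q)/(residual inertia/(n − 1 − q)),
p = (hits + 1)/(n_perm + 1). Marginal tests for one constraint permute
only that column and use the full-minus-reduced constrained inertia.

## Variation partitioning

Three predictor sets — basin land use, local land use, chemistry —
partition the variance of the log-abundance matrix. Each of the 7
subset models gets an Ezekiel-adjusted redundancy R²,
R²_adj = 1 − (1 − R²)(n − 1)/(n − q − 1) with q the effective rank.
The 7 unique/pairwise/three-way fractions solve the 7×7 linear system
mapping fractions to subset R²s; fractions plus residual sum to 1.
Results match `vegan::varpart`.

## Clade tests on the ordination plane

For each clade with ≥ 5 OTUs at a rank (phylum to family), on the
first two CCA axes:

- **Clustering.** The statistic d_p is the sum of pairwise Euclidean
  distances between the clade's OTU scores. The null draws random OTU
  sets of the same size from the pool of OTUs belonging to any tested
  clade at that rank. p = #{d_p ≥ d_random}/n — a pure upper-tail
  count without the +1 correction, with ties (within 10⁻¹²) counted
  toward the tail; with n = 1000 the attainable floor is p = 0.
- **Association.** d_p,v is the sum of scalar projections of the
  clade's OTU scores onto the unit biplot vector of one chemistry
  variable. The null simulates same-size clades from a bivariate
  normal centered at the ordination origin with the clade's own
  per-axis variances (the same draws are reused across vectors for one
  clade). With u the fraction of null statistics below d_p,v, the
  two-sided p is 2·min(u, 1 − u); a signed verdict ("positive"/
  "negative") requires u ≥ 0.975 or u ≤ 0.025.

Both families are BH-corrected within rank. Both nulls are verified to
produce uniform p-values by the calibration experiments (below).

## Synthetic landscape generator

Defaults are the study conditions: 46 lakes in 5 basins, 2000 OTUs,
25,000 reads per lake.

- **Land use.** Each basin draws its composition from a Dirichlet with
  basin-specific means (concentration 8.0, chosen so basins are
  distinct but overlapping); local fractions jitter the basin ones.
- **Chemistry.** chem = base + scale·(landuse·B + ε), with realistic
  base/scale units (e.g. TP in µg/L, temperature in °C). The
  coefficient matrix B plants the causal structure: urban → NO23 (12.0),
  arable → TP (2.0) and turbidity (1.5), forest → chl_a (−1.2),
  pasture → temperature (1.0). The urban → NO23 coefficient was sized
  a priori from the generator's own geometry: the measured SD of the
  urban fraction is ≈ 0.137, so a coefficient of 12 against unit noise
  gives an expected R² ≈ 0.74 — a strong but not deterministic driver.
- **Community.** Each OTU has a log-linear niche: logit-scale loading
  γ on standardized chemistry, softmax across OTUs per lake, then a
  multinomial draw at the fixed depth. Planted clades: a *clustered*
  phylum (niche dispersion 0.05, so members respond almost
  identically), an *associated* phylum (γ_TP = +2, dispersion 0.5) and
  a *neutral* phylum (γ = 0, dispersion 1.0); remaining OTUs belong to
  background phyla with phylum-level niche centers. The planted truth
  (clade names, membership, B) is returned alongside the data.
- **Realism and limitations.** There is no spatial autocorrelation by
  default (an optional `distance_decay_strength` adds a
  distance-structured loading), so the generator's truth for distance
  decay is "none" — matching surveys where basin chemistry, not
  geography, structures communities. Sequencing depth is fixed at the
  rarefaction depth, so the low-abundance filter can push a few lakes
  below depth; they are dropped, mimicking the discard of shallow
  samples in real studies. Richness is less skewed than real surveys
  (few very rare OTUs), and lineages are single-chain (one class per
  phylum, etc.), so ranks below phylum re-test nested sets.

## Validation experiments

`lakescape.evaluation` implements the package's guarantees; problem
sizes are the package's own choices, balancing statistical resolution
against minutes-scale runtime:

- **Oracle equivalence** — 10 random 8×12 tables; CCA eigenvalues vs
  an independent normal-equations eigensolver (< 10⁻⁸ required,
  ~10⁻¹⁶ observed) and CA inertia vs χ²/N (< 10⁻¹⁰ relative).
- **Null calibration** — 300 replicates per test (clade clustering,
  clade association, CCA permutation ANOVA, Mantel), each on
  signal-free data; the p-value distribution must pass a KS test
  against uniform at the 0.01 level. 300 replicates resolve
  miscalibration of a few percent while keeping each family under a
  minute.
- **Ground-truth recovery** — 50 independent default landscapes; per
  replicate: is urban the top-importance NO23 predictor, is the planted
  clustered phylum flagged (BH q ≤ 0.05), is the planted associated
  phylum signed positive on TP, does chemistry get the largest unique
  variation fraction. Each rate must be ≥ 0.9 (binomial SE ≈ 0.03 at
  50 replicates).
- **Closed forms** — Shannon of a uniform 4-vector = ln 4, a hand
  Bray–Curtis value, the Akaike weight ratio e at ΔAIC = 2, the 64
  model count, and hierarchical partitioning vs the all-orderings
  oracle.

## Numerical conventions

- Randomness uses NumPy `Generator`s; independent streams come from
  `SeedSequence.spawn`, and seeds passed to libraries are reduced
  mod 2³¹.
- Rank decisions use a relative singular-value tolerance of 10⁻¹⁰;
  permutation-statistic ties use an absolute tolerance of 10⁻¹².
- Permutation p-values use the (hits + 1)/(n + 1) convention except the
  clade clustering test (see above, deliberately a raw tail count).
- All pipeline stages record their derived seed in the report;
  identical configurations produce byte-identical reports.
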
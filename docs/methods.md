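# Methods

This note records the models behind each stage, the defaults and why, the
numerical choices, and what the synthetic test bed does and does not show.

## Data model

The pipeline's currency is a dense samples × OTUs matrix of non-negative
integer read counts (`OtuTable`), validated on construction (unique ids,
integral counts). On disk the common amplicon dialect is used: OTUs as rows,
samples as columns; BIOM v1.0 JSON (dense or sparse) is also read. Sample
metadata requires habitat ∈ {skin, gill, stomach, hindgut, water}, body
weight in grams for every non-water sample (water may be missing), site and
month. Phylogenies are rooted newick trees whose tips cover the OTU pool;
all phylogenetic quantities derive from cophenetic (tip-to-tip path-length)
distances.

## Rarefaction

Library sizes are equalised by subsampling each sample to a fixed depth
without replacement (multivariate hypergeometric draw), default 23,875
reads. Samples below depth are dropped with a warning rather than resampled
with replacement, preserving count semantics. Every stochastic operation
takes an explicit seed; the pipeline master seed is split into per-stage
sub-seeds with `numpy.random.SeedSequence`, so a rerun is byte-identical.

## Diversity statistics

* **Chao1** uses the bias-corrected form
  `S_obs + F1(F1−1)/(2(F2+1))`, defined for all inputs including F2 = 0.
* **Bray–Curtis** is computed on (rarefied) counts, not relative
  abundances; rarefaction already equalises depth. A pair of all-zero
  samples is assigned distance 0 with a warning.
* **PCoA** double-centres the squared distances (Gower) and
  eigendecomposes; axes with eigenvalue > 1e-10 are retained and variance
  proportions use the sum of positive eigenvalues as denominator, so
  non-Euclidean matrices with negative eigenvalues do not inflate the
  denominator.
* **PERMANOVA / ANOSIM** delegate to scikit-bio; PERMANOVA additionally
  reports R² = SS_among/SS_total recovered from the pseudo-F. Permutation
  p-values are `(hits + 1)/(permutations + 1)` throughout the package, so
  p = 0 is impossible and the floor is 1/(permutations + 1).
* **Mantel** (default 10,000 permutations) correlates upper-triangle
  entries, permuting rows and columns of the first matrix simultaneously;
  the partial variant uses the first-order partial correlation
  `(r12 − r13·r23)/√((1−r13²)(1−r23²))`. Implemented in-package because no
  installed library provides the partial form; the simple case is
  cross-checked against scikit-bio's Mantel in the test suite.
* **Feature–weight correlations** are Spearman rho of per-OTU relative
  abundance against body weight with Benjamini–Hochberg q-values; constant
  features are reported as missing and excluded from the correction.

## Distance-based weight regression

Response: upper-triangle community dissimilarities; covariate: |w_i − w_j|.
OLS slope/intercept in closed form; F = (SS_reg/1)/(SS_res/(n_pairs − 2)).
Because the n(n−1)/2 pairs are not independent, the p-value permutes the
*sample-level* weight vector (default 1,000 permutations) and rebuilds the
covariate each time; pairs are never shuffled independently. Per-habitat
fits subset the distance matrix first; the pooled fit uses every weighed
(non-water) sample — water samples carry no body weight and cannot
contribute a weight difference.

## Core taxa

An OTU is core to a habitat when its relative abundance exceeds the
abundance threshold (default 1%) in strictly more than the prevalence
threshold (default 80%) of the habitat's samples. Both inequalities are
strict. A stricter literal mode (`mode="strict"`) additionally demands the
abundance gate in every sample where the OTU is detected at all; the
prevalence reading is the default because it uses both thresholds
non-redundantly and matches common core-microbiome practice. The Venn
partition assigns every core OTU to exactly one habitat-combination cell.

## Rao diversity partition

Rao quadratic entropy `Q(p, d) = Σᵢⱼ dᵢⱼ pᵢ pⱼ` is the expected
dissimilarity between two randomly drawn reads; with the taxonomic distance
(dᵢⱼ = 1, i ≠ j) it is Gini–Simpson. Phylogenetic mode uses cophenetic
distances divided by their maximum so Q stays in [0, 1] and comparable
across modes.

Pooling is by **unweighted means**: each sample counts equally within its
habitat and each habitat equally within the ecosystem, because habitat
sample sizes are typically unequal and the habitat is the unit of interest.
A consequence accepted deliberately: splitting one habitat into two
identical copies changes the ecosystem mean (habitats are re-weighted), so
cross-dataset comparisons should hold the habitat set fixed.

Uncorrected chain: ᾱ_h = mean Q over samples; γ_h = Q of the habitat's
mean profile; β_intra,h = γ_h − ᾱ_h; γ_eco = Q of the mean of habitat
means; β_inter = γ_eco − mean γ_h. Additivity
γ_eco = β_inter + β̄_intra + ᾱ is exact by telescoping.

The `equivalent_numbers` correction (default) applies T(Q) = 1/(1−Q) to the
*averaged* Q at each level: L0 = T(mean ᾱ_h), L1 = T(mean γ_h),
L2 = T(γ_eco), with ᾱ = L0, β̄_intra = L1 − L0, β_inter = L2 − L1.
Transforming after averaging (the q = 2 Hill-number alpha) rather than
averaging transforms is what guarantees non-negative β whenever Q is
concave — which holds for taxonomic and ultrametric phylogenetic
distances; a mean-of-transforms chain admits counterexamples with strongly
unequal habitat diversities. Per-habitat corrected
β_intra,h = T(γ_h) − T(ᾱ_h) is reported for each habitat; being a
nonlinear transform it does not average to the pooled corrected β̄_intra.
Percentages are each component over γ on the reported scale.

## Assembly processes

**βMNTD** (abundance-weighted):
`½[Σᵢ fᵢˣ·min_{j∈y} d(i,j) + Σⱼ fⱼʸ·min_{i∈x} d(j,i)]` over nonzero taxa;
taxa present in both communities contribute zero. **βNTI** standardises the
observed βMNTD against a null that shuffles tip labels uniformly across
*all* tips of the regional tree (default 999 shuffles) — deviation from the
regional phylogenetic expectation, not from the pair. When the null has
zero spread (e.g. star trees, or both communities occupying every tip) βNTI
is reported as 0 with a warning. For batch runs the same shuffle set is
shared across pairs, which is statistically equivalent and much faster.

**RC_Bray**: null pairs preserve each sample's observed richness and total
reads. Taxa are selected without replacement with probability proportional
to occupancy frequency across the reference table; each selected taxon
receives one read and the remainder are allocated by a multinomial with
probabilities proportional to metacommunity-wide relative abundances.
`RC_raw = (n_below + ½·n_ties)/n_null` with tie tolerance 1e-10, rescaled
to `2·RC_raw − 1 ∈ [−1, 1]`.

**Classification** (total function): βNTI > +2 heterogeneous selection;
βNTI < −2 homogeneous selection; otherwise RC < −0.95 homogenizing
dispersal, RC > +0.95 dispersal limitation, else undominated. Boundary ties
(|βNTI| = 2, |RC| = 0.95) fall to the non-selection/undominated side —
measure-zero events that need a deterministic rule. Habitat profiles
classify every within-habitat pair, pooled over sites and months, and
report exact count fractions.

## Source tracking

A collapsed Gibbs sampler assigns each sink read a latent source. For read
n of taxon t: P(z_n = v) ∝ (m_tv + α_v)/(m_·v + α_v·T) · (n_v^{−n} + β),
where m counts the source's reads plus currently assigned sink reads for
known sources (α_known = 0.001) and only assigned sink reads for the
Unknown source (α_unknown = 0.1); β = 10 is the prior on the mixing
proportions; T is the number of taxa. Defaults: 10 restarts, 100 burn-in
sweeps, 10 retained draws per restart at delay 10. Proportions are
posterior means over pooled retained draws with central 95% credible
intervals. Sinks are rarefied to 1,000 reads by default (sampler cost is
linear in sink reads); source profiles pool each habitat by summed counts.
The per-read sweep is inherently sequential and is numba-compiled.

## Synthetic metacommunities

The generator emulates the statistical structure the analyses assume:

* a Kingman-coalescent ultrametric phylogeny over the regional pool;
* a Brownian trait along the tree (standardised to unit variance), making
  habitat filtering phylogenetically conserved — the signal βNTI needs;
* per-habitat trait optima at evenly spaced trait quantiles; OTU pool
  weight ∝ exp(−selection_strength · (trait − optimum)²);
* communities as multinomial draws from
  (1 − dispersal_rate)·filtered pool + dispersal_rate·flat pool;
* body weights uniform on `weight_range_g` (default 50–400 g, an
  adult-rabbitfish range); a per-OTU random log-linear trend in weight,
  Z_i ~ N(0, σ_z²) with perturbation Z_i·(w − w_min), makes the
  log-abundance difference between two fish exactly proportional to their
  weight difference while the marginal perturbation variance grows with
  weight — so within-habitat Bray–Curtis rises ≈ linearly at
  `weight_slope` per gram without confounding the habitat signal.

σ_z is calibrated numerically: the expected-BC-versus-Δw regression slope
(over the triangular |Δw| density of uniform weights, including multinomial
read noise, which otherwise absorbs part of small systematic differences)
is matched to the nominal slope by bisection. The calibration uses
surrogate pools built from a fixed internal seed, so it depends only on the
generative conditions and is cached across replicate seeds without breaking
per-seed determinism. The first-order delta-method value
σ_z = √(2π)·weight_slope serves as the bisection bracket.

Defaults (5 habitats × 20 fish, 300-OTU pool, 5,000 reads/sample,
selection 10, dispersal 0.1, slope 0.001/g) are a desk-scale analogue of a
multi-habitat host survey. When five habitats are requested the fifth is
water: no body weight, no weight-dependent dispersion.

What the generator does **not** emulate: taxonomy, realistic rank-abundance
tails, site/month effects (labels are assigned cyclically but carry no
signal), read-level sequencing error, or compositional drift with age
beyond the dispersion trend. Passing recovery tests therefore shows the
estimators detect the modelled structure, not that real data satisfy these
assumptions.

## Problem sizes and tolerances

Additivity is verified to 1e-10 on random tables; βMNTD against a
double-loop oracle to 1e-12; βNTI null moments against exhaustive 120-
permutation enumeration on 5-tip trees within 3 Monte-Carlo standard errors
at 10,000 shuffles. Recovery studies use desk-scale replicates: 20 seeds
for assembly-regime recovery (2 habitats × 4 fish, 200-OTU pool, 199
nulls — chosen so per-sample richness ≪ pool, since nearly saturated
communities share all taxa and degenerate βMNTD toward zero), 50 + 100
replicates for weight-slope recovery and null calibration (30 fish, 150-OTU
pool), 50 replicates per permutation-test calibration, 20 seeds for 70/30
source-mixture recovery at 5,000-read sinks. Classification is exercised on
a 100 × 100 grid of (βNTI, RC).

## Known limitations

* RC_Bray's null is one of several in use (richness-and-abundance
  preserving); results are comparable only under the same null.
* The Rao partition's unweighted pooling treats a 13-sample habitat and a
  108-sample habitat symmetrically — intended, but it means γ is not the
  Q of the pooled read mass.
* Source-tracking proportions are exchangeable only across runs with the
  same source set; the Unknown fraction absorbs both genuinely novel taxa
  and undersampled source tails.
* The partial Mantel permutes the first matrix only (raw-matrix
  permutation), the common default; residual-permutation variants can
  differ slightly in edge cases.
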
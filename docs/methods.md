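# Methods

`refugia` re-implements, as a tested pipeline over synthetic data with known
truth, the population-genomic analyses used to study a native freshwater
gastropod metapopulation distributed along a water-calcium gradient in which
the high-calcium habitats are occupied by an invasive predatory fish
(the round goby) and the low-calcium habitats act as physiological refugia.
The questions the pipeline addresses are the study's: which loci respond to
the calcium gradient and which to predation, how structured the
metapopulation is, whether invaded populations lost diversity, and how much
gene flow connects refuge and invaded populations.

## The synthetic study system (`synthpool`)

A forward Wright–Fisher simulation generates truth. Twelve demes form two
habitat clusters (six refuge-river demes, six invaded-river demes) that
split from a panmictic ancestor `split_gen` generations ago and then
exchange migrants island-style: each deme sends a fraction `m_within` of its
gametes to the other demes of its cluster and `m_between` to the other
cluster (rows renormalized in the panmixia limit). Two demes invert the
habitat/predator pattern — a low-calcium deme the predator reached and a
high-calcium wetland it did not — mirroring the field system's layout and
making the two covariables imperfectly confounded.

Covariables: predator presence is binary; calcium (mg/L) is constructed as
`rho_env * goby_z + sqrt(1-rho_env^2) * e_z` with `e` a fixed pattern
orthogonal to the predator indicator, rescaled to a 10–40 mg/L gradient.
The Pearson correlation between the covariables is therefore exactly
`rho_env` (default 0.71, the confounding measured in the field data).

A fraction `p_selected` of loci (default 2%) is under genic divergent
selection (`w_alt = 1 + s`, default s = 0.1), half tied to each covariable,
with the favored allele's habitat drawn at random. Invaded demes pass
through a bottleneck 12 generations before sampling (one generation per
year since the invasion) to a fraction `bottleneck_severity` (default 0.1)
of the census size, with optional exponential recovery to the present.

Pooled sequencing is a two-stage sampler: 2×40 haploid genomes drawn
binomially from the deme frequency, then Poisson depth (mean 35×, inside
the study's expected 30–40× band) with alternate reads binomial from the
pool frequency perturbed by a symmetric per-read miscall probability
(default 10⁻³; errors flip between the two alleles of this biallelic
world). Sites sit every 16 bp on one synthetic scaffold by default, an
assayable-site density (0.0625) chosen so the windowed-diversity coverage
filter retains windows; the simulated "genome" is a polymorphic tract, so
absolute per-site diversity is much higher than in real data — ratios and
contrasts between habitats are the meaningful quantities.

Free desk-scale choices, fixed once and documented here rather than tuned:
deme census 500 diploids, `split_gen` 200, `m_within` 0.05, `m_between`
0.005, 5000 loci in the default pipeline run. They are conditions for the
synthetic experiments, not estimates of the real system.

What the generator does not emulate: linkage and recombination maps (sites
are exchangeable), multi-nucleotide variants, base-quality structure,
reference bias, and indel/paralog artifacts. Passing tests therefore
validate estimator logic and calibration under the two-stage sampling
model, not robustness to alignment artifacts.

## SNP filtering (`poolio`)

Sync files (per-population `A:T:C:G:N:del` counts) are reduced to biallelic
sites by taking the two most frequent nucleotides over all pools; N and
deletion reads never count toward depth. Filters mirror the study pipeline:
minimum read count per allele 2 (summed over pools), per-population depth
in [5, 300], pooled minor allele frequency ≥ 0.0125 (= 1/80, removing
pool-level singletons), indel sites dropped. All thresholds are inclusive;
the MAF is computed on pooled counts across populations because 1/80
corresponds to one chromosome of one pool. The effective sample size of a
pooled depth d over n haploids is n_eff = (n·d − 1)/(n + d).

## Genome scans (`genomescan`)

All scans are deterministic, built on the scaled covariance matrix Ω of
standardized allele-frequency deviations x_lj = (p̂_lj − p̄_l)/√(p̄_l(1−p̄_l)),
estimated as the moment average Ω̂ = (1/L)Σ x_l x_lᵀ with a doubling ridge
until positive definite.

Because p̄ is the sample mean across populations, the deviations sum to
zero: Ω̂ has rank J−1 and the ridge direction (the ones-vector) is
orthogonal to every x, so statistics do not depend on the ridge size. For
the same reason the neutral reference for XtX = xᵀΩ̂⁻¹x is χ²(J−1), not the
χ²(J) quoted for hierarchical Bayesian implementations whose latent
ancestral frequency restores the lost degree of freedom; `xtx_scan`
defaults to J−1 (calibrated; verified on neutral simulations) and exposes
`df` for users who want the J-df reference against an external Ω. The test
is bilateral: the low tail flags balancing-selection-like homogeneity.
Group contrasts are mean-zero, so C2 = (cᵀx)²/(cᵀΩ̂c) and the GLS slope
statistic z² = (kᵀΩ̂⁻¹x)²/(kᵀΩ̂⁻¹k) keep exact χ²(1) calibration.

The continuous-covariable association is this Ω-corrected GLS regression —
the same per-SNP regression-coefficient model family that the Bayesian
importance-sampling machinery evaluates — applied at a stringent default
(recalibrated q < 0.001) to emulate a "decisive evidence" cut-off. MCMC and
Bayes factors are deliberately out of scope.

The complementary scan is a per-SNP quasibinomial GLM of allele frequency
on a binary covariable, fit by IRLS (vectorized across SNPs) on counts
rescaled to n_eff with +1 added to zero cells; the slope is tested against
t(J−2) using the Pearson dispersion. Residual structure is absorbed by
empirical-null recalibration: λ = median(z²)/median(χ²₁) and p_recal =
upper tail of z²/λ. Under exchangeable structure the recalibrated p-values
are uniform; when drift is aligned with the tested contrast (clusters =
predator presence), λ-rescaling corrects the scale but not the shape of the
null, leaving the tail conservative — a known limit of median-based
genomic control, and one reason the study's design intersects the GLM with
the Ω-aware scans rather than trusting either alone.

q-values use the fixed-threshold estimate π̂₀ = min(1, #{p > 0.5}/(0.5 m));
with π₀ = 1 the procedure reduces exactly to Benjamini–Hochberg.

Candidates per covariable are SNPs significant in both the Ω-based scan
(C2 at q < 0.01 for the binary covariable; GLS regression at q < 0.001 for
calcium) and the GLM (q < 0.01 on recalibrated p), uniquely associated with
that covariable (SNPs in both intersections are removed from both), and
direction-consistent. The consistency rule is a declared convention, since
the original analysis removed "inconsistent" SNPs without a formula: the
two methods' effect signs must agree, and at least ⌈5/6·J_g⌉ populations in
each covariable group must lie on the model-implied side of the
across-population mean frequency.

Power at desk scale: with J = 12 populations the GLM's t(10) reference and
the within-group dispersion contributed by the two inverted demes cap the
attainable recalibrated p near 10⁻⁴, which cannot clear q < 0.01 over tens
of thousands of tests; the predator-covariable intersection is therefore
usually empty in the synthetic runs even though C2 alone recovers
essentially all planted predator loci. The field study saw the same
asymmetry (its GLM branch returned far fewer predator outliers than C2).

## Diversity (`diversity`)

Per-site heterozygosity uses the double correction
ĥ = [d/(d−1)]·[n/(n−1)]·2p̂(1−p̂), unbiased for the deme heterozygosity
under the two-stage model; window π sums ĥ over all covered sites (no
minor-count threshold, so the expectation is exact under error-free
reads; with the default 10⁻³ error rate π gains ≈ 2e per site).

Watterson's θ inverts the SNP-detection probability: a site with pool
minor-allele count k among n chromosomes is called a SNP (minor reads ≥ b,
default 2) with probability P(b ≤ X ≤ d−b), X ~ Bin(d, k/n), so
E[S per site] = θ·Σ_{k=1}^{n−1}(1/k)·P(detect|k) and θ̂_W divides the
observed S by that sum accumulated over covered sites. This estimator is
unbiased by construction under the generating model and replaces both the
published tool-internal corrections and the simpler a(n_eff) rescaling,
which under-corrects the depth-dependent loss of singleton-frequency sites.

Tajima's D = (π − θ̂_W)/√(e₁S + e₂S(S−1)) with the standard constants at
ñ = ⌊median n_eff⌋ of the window, computed on its own laxer coverage
filter (minimum 13 ≈ pool size/3, following the study's stated constraint);
windows report missing values — never zero — when the covered fraction is
below 0.05 or S = 0. The covered fraction is judged against the scaffold
extent when a scaffold ends inside a window, as happens throughout a
fragmented assembly. The D variance normalization is approximate under
pooling, so D is used for contrasts and signs, not as an absolutely
calibrated statistic; its mean is within ±0.1 of zero at neutral
equilibrium (verified against coalescent simulations).

Habitat contrasts use Welch's t-test and Hedges'
g = [1 − 3/(4(n₁+n₂)−9)]·(m₁−m₂)/s_pooled with the usual large-sample CI.

## Population structure (`popstructure`)

Pairwise F_ST is the identity-probability ratio-of-sums estimator:
per SNP, Q1 = 1 − ĥ within pools and Q2 = 1 − [p̂ᵢ(1−p̂ⱼ) + p̂ⱼ(1−p̂ᵢ)]
between, F̂ST = Σ(Q̄1 − Q2)/Σ(1 − Q2) over the non-outlier SNPs. The pool
correction inside ĥ makes the estimator consistent for the
true-frequency value (checked against a brute-force oracle).

The UPGMA tree is scipy's average-linkage agglomeration (ties resolved by
scipy's deterministic merge order); node support is the frequency of each
full-data clade across SNP bootstrap resamples. Mantel tests (one-sided for
positive association, matching the directional hypotheses) relate
linearized genetic distance F_ST/(1−F_ST) to log river-path distance
(isolation by distance) and to the squared Mahalanobis distance in the
(calcium, predator) plane (isolation by environment); the permutation
engine is seeded for reproducibility. The Förstner–Moonen distance
√(Σ ln²λᵢ) over generalized eigenvalues compares covariance matrices.

## Demographic inference (`demography`)

The data object is the folded joint SFS of one invaded/refuge pair: read
counts are projected to small haploid samples (default 20 + 20) by
binomial downsampling of read frequencies, restricted to the interquartile
coverage band of both pools, scan outliers excluded, folded (minor-allele
configurations), and masked for the monomorphic corners plus all cells
with minor-allele total ≤ 5, where pooled low-frequency estimates are
unreliable.

Seven competing histories are fitted (population split with no/symmetric/
asymmetric migration; bottleneck in the invaded population or both, with
or without exponential recovery; free-parameter counts 3/4/5/7/8/8/10),
plus an eighth — bottlenecks in both populations with recovery only in the
invaded one — available behind a flag but excluded from the default
comparison. Sizes are relative to the ancestral reference N_ref, times in
2N_ref generations, and migration M = 2N_ref·m per direction. The
bottleneck age is known (12 generations), so bottleneck models carry
θ = 4μL_eff·N_ref explicitly and convert T_B = g_B/(2N_ref) at every
evaluation, with μ = 7.6×10⁻⁹ per site per year (a caenogastropod
estimate) and L_eff = total length × SNPs used / SNPs total; split-only
models profile θ analytically. Parameters stay dimensionless (only the
2N_e·m summaries are reported, classified as negligible < 0.05, low
0.05–5.5, high above), since converting to individuals and years would
inherit the mutation-rate uncertainty.

The expected SFS comes from a Monte-Carlo structured coalescent (a numba
kernel): lineages carry descendant counts per population, epochs support
exponential size change (handled by thinning against the epoch's maximal
coalescence rate), and the expected entry is (θ/2)·E[branch length
subtending (i, j)]. Two unbiased variance reductions operate once all
lineages are ancestral: interval lengths are replaced by their conditional
expectations (interval and topology are independent in the Kingman
coalescent) and the last two merges are averaged analytically over the
three equiprobable pair choices. A fixed seed gives common random numbers
across likelihood evaluations, making the surface deterministic; the noise
floor scales as 1/n_reps. The engine was checked against the θ/i panmictic
closed form and against msprime's branch-mode joint spectrum.

Fitting maximizes the Poisson composite log-likelihood over unmasked cells
by repeated Nelder–Mead in log-parameter space from randomly perturbed
starts until three runs agree within 1% of the best likelihood (30-run
cap; an unconverged result is returned flagged, not hidden). Because the
surface has a weakly anchored time-rescaling ridge (sizes and times up,
migration down — pinned only by the ancestral reference size) and
competing basins, the runs are seeded from several well-separated
low-objective points of a Latin-hypercube scan, each run is followed by a
line search along the ridge, and a final polish re-optimizes at ~10× the
genealogy budget to push the Monte-Carlo floor below the local curvature.
Models are ranked strictly by composite log-likelihood — AIC is invalid
for composite likelihoods over linked SNPs — with exact ties reported, not
broken. Parameter uncertainty comes from block-bootstrap refits (10⁵-bp
chunks resampled with replacement, reduced optimizer budget, percentile
intervals), replacing curvature-based (Godambe) intervals that the
Monte-Carlo likelihood surface would make unstable.

Problem sizes: the default pipeline projects to 12+12 haploids with 3000
genealogies per likelihood evaluation; the recovery experiments use 20+20
haploids, 1.5×10⁴ genealogies per evaluation during the search, a
1.2×10⁵-genealogy polish and a 3.6×10⁵-genealogy migration refinement, on
an SFS from 10⁶ sites of sequence at θ = 0.01/site (≈5×10⁴ folded SNPs,
corners-only masking since exact Poisson draws carry no pooled
low-frequency unreliability). The signal-to-Monte-Carlo-noise ratio of
the composite likelihood depends only on the per-evaluation genealogy
budget — both the parameter signal and the evaluation noise scale
linearly with the SNP total — which bounds how finely weakly-curved
directions can be resolved (see limitations).

## Orchestration (`pipeline`, `analysis/`)

One config drives simulate → filter → scan → diversity → structure →
demography; scan outliers feed the F_ST and SFS exclusion lists; every
stage seed derives from the run seed; stages are cached on section hashes
and a machine-readable summary (plus a markdown report) embeds the config
hash. The numbered scripts under `analysis/` are thin drivers over the
same library code the tests import.

## Known limitations

- No linkage: block bootstraps and composite-likelihood caveats are
  exercised mechanically, not against realistic LD.
- The GLM branch is power-limited at J = 12 (see above); candidate recall
  at desk scale is dominated by the Ω-based scans.
- Genomic control corrects the null's scale, not its shape, under
  cluster-aligned drift.
- The Monte-Carlo likelihood cannot resolve parameters whose profile
  curvature is below its evaluation-noise floor. Both that noise and the
  profile signal scale linearly with the number of SNPs, so the floor is a
  property of the per-evaluation genealogy budget alone: weak migration
  directions (scaled flow near the 0.05 "negligible" boundary) are
  recovered only up to roughly ±35–50% at desk-scale budgets. Bootstrap
  intervals inherit the reduced refit budget and should be read as
  approximate.
- Tajima's D under pooling is sign-calibrated, not variance-exact.
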
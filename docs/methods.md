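# Methods

This note documents the models and procedures `strainflow` implements,
the defaults and why, what the synthetic cohort generator does and does
not emulate, and the numerical choices that matter.

## Strain typing

Typing starts from per-sample, per-position nucleotide counts over a
signature-gene catalog (0-based, half-open coordinates within genes;
bases encoded A=0..T=3, −1 = uncalled).

**Consensus calling.** A position is called to base *b* iff depth ≥
`min_depth` and count_b/depth ≥ `af_threshold`. The threshold default is
0.90 and is inclusive; `min_depth` defaults to 4 reads — below that an
allele-frequency estimate is meaningless. Heterogeneity is summarized as
the fraction of covered positions (depth ≥ `min_depth`) whose
major-allele frequency falls below the threshold.

**Filters.** A sample enters typing when ≥ 250 reads map to ≥ 10
signature genes (both inclusive). Because the pipeline starts at allele
counts rather than alignments, the read count is estimated as total base
observations divided by a nominal read length (100 bp, configurable).
Genes are excluded per sample when more than 20% of their covered
positions are low-AF (strictly greater excludes; a gene with 20/100 such
positions is retained); zero-coverage genes are excluded with a
"no-coverage" flag. Excluded genes remain in coordinates as uncalled so
profiles stay alignable by catalog position.

**Distances and tree.** Pairwise distance between two profiles is the
count of positions called in both and differing, normalized by the
number of shared called positions; fewer than `min_shared` (default
1000) shared positions flags the pair undefined (never zero). The tree
is neighbor joining (scikit-bio) on normalized distances, rooted on the
*B. longum* subsp. *longum* outgroup, with any residual negative branch
lengths clamped to zero. Maximum-likelihood inference with per-gene
model selection is intentionally out of scope: branch lengths
proportional to SNV differences are the operative signal here, and NJ
reproduces them at desk scale.

**Categorization.** Rules apply in order: `NotDetected` when
*B. infantis* is absent from the taxonomic profile; `UntypedLow` when
detected but below 0.16% relative abundance (strict less-than, so a
sample at exactly 0.0016 is typed); `UntypedHet` when the typing filter
failed, the heterogeneity fraction exceeds `het_max`, or too few
positions are shared with the probiotic reference; otherwise `LMG11588`
iff the normalized distance to the probiotic reference is within
`probiotic_radius` (default 0.001 — motivated by the negligible internal
variability of the probiotic clade), else `OtherInfantis`.

`het_max` defaults to 0.002 (0.2% of covered positions). The choice is
tied to the generator's strain divergence: two autochthonous subclades
differ at ≈ 0.5% of sites, so a 50/50 two-strain mixture produces a
heterogeneity fraction of ≈ 0.005, while sequencing noise at error
rates ≤ 0.005 and depth ≥ 25 contributes < 1e-4. The threshold sits an
order of magnitude above the noise floor and safely below the mixture
signal. Analyses of strains with larger divergence can raise it.

## Synthetic cohort generator

The generator emulates the trial design so that every downstream stage
can be scored against planted truth: three arms (placebo CG plus
low/high-dose experimental arms, default 76 infants each, or explicit
arm sizes), four visits, feeding-mode mix 58/26/16 (EBF/mixed/formula),
per-visit missing-sample probability 0.008.

**Strain genomes.** One probiotic reference (identical to the catalog
sequence) plus variants at pairwise divergence 1e-4 (the "negligible
variability" clade), eight autochthonous subclades at pairwise
divergence 5e-3, and a distant outgroup at 2e-2. Divergence parameters
are *pairwise*: each genome receives Binomial(L, rate/2) substitutions
from the shared ancestor. All planted SNV positions are recorded.

**Colonization dynamics.** Autochthonous carriage is an absorbing state
with one subclade per infant (stable across visits): 16% carry at
baseline and non-carriers acquire with probability 0.01 per later visit,
reaching ≈ 18% by V4. The probiotic colonizes experimental-arm infants
during supplementation; residents block it (they out-compete the
supplemented strain), so the per-infant win probability is inflated such
that the configured `probiotic_col_prob` (0.787) is the *marginal
observed* detection rate. Persistence at V4 is a per-infant coin —
0.88 for exclusively breastfed infants, 0.54 otherwise. These coin
values are chosen so the *observed* persistence, after the ≈ 5% of
colonized infants lost downstream to low-abundance sampling (2.3%),
mixture flags (0.7%), and replacement by newly acquired residents
(≈ 2%), pools to ≈ 0.70 overall and ≈ 0.84 in EBF. Control-arm
probiotic "leakage" (horizontal transmission) occurs at 0.02 per
supplementation visit. Rare samples (0.007) carry a 50/50 two-subclade
mixture, the minimal mechanism that triggers the heterogeneity rule.

**Abundance and depth.** Colonized samples draw log10 relative abundance
from N(−1.7, 0.55²) truncated at 50%; non-colonized samples carry a
trace-level detection (log-uniform below the 0.16% threshold) with
probability 0.10, else none. Mean per-position depth is
`depth_per_unit_abundance × abundance` (default 5000, i.e. 50× at 1%
abundance), scaled by a per-sample log-normal library factor (σ = 0.25)
and Poisson-dispersed per position; substitution errors are uniform over
the three alternatives. The abundance distribution is a realistic
default for infant-gut *B. infantis*, not a calibrated fit to any
measured per-visit distribution.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: read-level artifacts (mapping bias, indels,
strand effects, non-uniform error profiles), within-subclade strain
evolution, delivery-mode or antibiotic effects, compositional coupling
between *B. infantis* abundance and the genus table (community-type
labels are coupled to colonization, but genus counts are drawn from the
mixture, not from the strain model), and real biomarker distributions
(synthetic biomarkers are Gaussian with signed monotone coupling —
acetate/AAT/calprotectin/sIgA up, IL-1β/IL-8/IFN-γ/butyrate down).

## Community typing (Dirichlet-multinomial mixture)

EM on the DM mixture likelihood: responsibilities ∝ π_k·DM(x|α_k);
π updated by responsibility means; α by Minka's fixed point on the
responsibility-weighted DM log-likelihood (three inner iterations per
EM step — each fixed-point step is monotone, so the EM trace is
non-decreasing, which the tests assert). Initialization is k-means++
seeding plus up to 10 Lloyd iterations on the proportion vectors,
followed by moment matching to Dirichlet parameters; best of
`n_restarts` (default 10) by final log-likelihood. α is floored at 1e-6
to avoid boundary divergence; convergence when the log-likelihood gain
drops below 1e-4 (max 400 iterations, flagged if not converged).

Relative-abundance tables are converted to counts by multiplying by a
per-sample library size (default 10,000) and rounding, since the DM
needs counts.

**Model selection.** With p = K·G + (K−1) free parameters:
AIC = −2logL + 2p, BIC = −2logL + p·log n, and a Laplace approximation
to the negative log evidence −logL − (p/2)·log 2π + ½·Σ log h, where h
are diagonal observed-information terms in log-α space computed from the
responsibility-weighted per-component curvature (polygamma form), plus
multinomial information n·π_k for the free weights. The diagonal
per-component form is deliberate: near-duplicate components at overlarge
K create flat coupled directions in the full Hessian that would make the
raw Laplace integral diverge rather than penalize complexity.

A documented behavior: because this standard Laplace form carries no
prior-density term, its marginal penalty is ≈ 1 nat per parameter, and
on synthetic data at n ≈ 865 samples and 10 genera it plateaus beyond
the true component count and can select K+1 or K+2, while BIC recovers
the planted K = 6 in every replicate. Laplace remains the primary
reported criterion; all three are always computed, and disagreement is
reported, not resolved silently.

Components are relabeled 1..K by ascending mean visit index of member
samples (ties by descending prevalence; empty components last, warned)
before any transition or comparison table is built, so community types
are numbered from early to late and all reported quantities are
invariant to label switching.

## Ecology statistics

Bray–Curtis via scipy `pdist`; PCoA by direct eigendecomposition of the
Gower-centered matrix (negative eigenvalues reported as-is; their axes
carry zero coordinates). PERMANOVA partitions squared dissimilarities
with marginal (type-III-like) sums of squares — each term's SS is the
drop from the full model when the term is removed — and permutes raw
sample labels with the add-one rule, so p-values are reproducible given
a seed and never exactly zero; the implementation is cross-checked
against R vegan's `adonis2(by="margin")` in the test suite. Procrustes
association uses the symmetric disparity m² after centering/scaling,
reporting PrC = √(1 − m²) with a row-permutation p; the biomarker-side
ordination is a z-scored Euclidean PCA — there is no field convention
for ordinating assay panels, so this is the package's own choice. Alpha diversity reports observed richness and Shannon (natural
log); richness is the headline. Taxon–biomarker association is Kendall
tau-b (tie-corrected) on taxa with mean abundance ≥ 1% plus nominated
*Bifidobacterium* taxa, BH-adjusted across the whole matrix, significant
at adjusted p < 0.1.

## Trial statistics

ANCOVA fits outcome ~ group + baseline + sex by OLS; adjusted means are
predictions at covariate grand means (averaging over the observed sex
distribution). Pairwise differences carry an unadjusted t CI and a
Tukey CI using the studentized-range quantile at residual df
(Tukey–Kramer for unbalanced groups). Non-inferiority holds iff the
lower bound of the two-sided 95% CI strictly exceeds the margin
(−3.6 g/day default); the attached p is the one-sided test of
H0: difference ≤ margin from the same fit. Coverage calibration uses
the unadjusted per-comparison CI — simultaneous Tukey intervals are
deliberately conservative per pair.

Sample size uses the normal approximation
n0 = 2(z_{1−α} + z_{power})²·sd²/margin², ceiling, then inflation by
1/(1 − attrition) and ceiling again. At margin 3.6, sd 7.7, one-sided
α = 0.025, power 0.80, attrition 3% this gives 72 → 75 per group; power
is a required argument with no silent default in reports, since planning
conventions differ across trials.

The Freeman–Halton test enumerates all tables with the observed margins
when feasible (two-sided p sums probabilities of tables no more probable
than observed, with a 1e-9 relative tolerance for float ties), else
fixed-margin Monte Carlo with the add-one rule; it reduces exactly to
two-sided Fisher on 2×2 tables. Biomarker censoring: < 10% of values
below the LLD → substitute the LLD and model; > 50% below the LOD → no
model; the in-between regime passes through unmodified with a "caution"
flag rather than imputing — the least-surprise default where no standard
rule applies.
Benjamini–Hochberg is the step-up adjustment, NaNs propagated with a
warning.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds carried in
the configuration; identical config + seed reproduces outputs byte-for-
byte (manifests carry a config hash and output hashes). The test suite
and the acceptance script use desk-scale sizes chosen to keep full runs
comfortable on one CPU: a 30-gene catalog (300–600 bp, ≈ 13.6 kb of
sequence — the statistical behavior of consensus calling and distances
depends on total length, and ≥ 10 kb leaves every threshold far from its
noise floor), 218-infant cohorts matching the analyzed population, DMM
selection over K ≤ 8 with 3 restarts, and 99–199 permutations inside
calibration loops (1,000 remains the pipeline default for single
analyses). Trees for large cohorts are built on a deterministic
subsample of placed profiles (`tree_max_tips`, default 150) plus all
references.

## Known limitations

- The consensus caller is haploid and biallelic by construction; indels
  and multi-allelic genotypes are out of scope.
- PERMANOVA assumes complete metadata and exchangeable samples under
  permutation; repeated measures per infant are not blocked.
- The Laplace criterion's plateau beyond the true K (above) means
  component-count claims on real data should always be read alongside
  BIC and the component profiles themselves.
- The generator's trace-detection model places all sub-threshold
  detections below 0.16% by construction, so `UntypedLow` recovery is
  easier than in real data where abundance estimation error straddles
  the threshold.
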
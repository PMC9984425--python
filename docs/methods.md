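# Methods

This note records the statistical models behind each `pleioscan` module,
the defaults that matter, the choices made where the design was open, and
what the synthetic generators do and do not emulate.

## Summary-statistic standardization

Records are standardized to beta per copy of the reference panel's alt
allele.  SE recovery from a two-sided P value uses
se = |β| / Φ⁻¹(1 − p/2); it is undefined for β = 0 or p ∉ (0, 1), and such
records are dropped with a named reason.  Odds ratios become β = ln(OR),
with SE from log-scale 95% confidence bounds when available, otherwise
from P.  Harmonization matches records to panel sites by (chrom, pos):
swapped alleles flip the sign of β, complementary-strand matches are
complemented first, and palindromic variants (A/T, C/G) are dropped
unconditionally — allele-frequency information needed to resolve them is
often absent, so no frequency-based rescue is attempted.  The
harmonization report satisfies kept + dropped = input by construction.
Coordinates are 1-based inclusive internally; BED I/O converts to and
from 0-based half-open.  Genome-build liftover is out of scope; inputs
are assumed to be on one build.  Monomorphic panel sites are excluded
throughout (pairwise LD is undefined at them).

## Fine-mapping

Under a single-causal-variant assumption the multi-variant fine-mapping
model reduces to per-variant evidence: the Wakefield approximate Bayes
factor ABF = √(V/(V+W)) · exp(z²W / 2(V+W)) with V = se² and z = β/se,
and a uniform prior over which variant is causal, giving
PP_i = ABF_i / Σ_j ABF_j.  The 95% credible set is the shortest
PP-descending prefix with cumulative PP ≥ 0.95, ties broken by input
variant order for determinism.  The prior effect variance defaults to
W = 0.04 (prior SD 0.2 on a quantitative-trait effect, a conventional
choice) and is exposed in `ABFConfig` rather than hard-coded, since no
single canonical value exists.  All BF arithmetic is in log space with
log-sum-exp normalization: |z| beyond ~38 overflows the linear scale.
Blocks enter fine-mapping only if they contain a genome-wide significant
variant (P ≤ 5×10⁻⁸, inclusive).

## Pairwise pleiotropy

For one LD block and a trait pair, five block-level models compete:
no association (0), trait-1 only (1), trait-2 only (2), one shared
causal variant (3), two distinct causal variants (4).  With per-variant
Bayes factors bf1, bf2 (marginal) and bf_joint (shared), the
unnormalized scores are

    S0 = 1
    S1 = π1 Σ_i bf1_i          S2 = π2 Σ_i bf2_i
    S3 = π3 Σ_i bfj_i          S4 = π4 Σ_{i≠j} bf1_i bf2_j

normalized to pp0..pp4 in log space.  A genome-scale analysis would fit
the per-variant priors empirically; a desk-scale analysis of one or a
few blocks cannot, so fixed configurable defaults are used:
π1 = π2 = 10⁻⁴, π3 = 10⁻⁵, π4 = 10⁻⁶ (shared causality rarer than
single-trait causality, coincident distinct causality rarer still).
The shared-effect call is pp3 ≥ 0.9, inclusive.

Cohort overlap: when two GWAS share samples, their Z scores are
correlated under the null.  The expected correlation C is taken from
disease relatedness in the MeSH tree — relationship level = length of
the longest common prefix of the dotted tree numbers (capped at 5),
C = 0.09 × level for same-cohort pairs (the ladder 0.09 … 0.45, e.g.
level 4 → 0.36), C = 0 for distinct cohorts.  C enters only the
shared-model Bayes factor, as a bivariate normal density ratio: under
the null (z1, z2) ~ N(0, Σ) with Σ = [[1, C], [C, 1]], under the shared
alternative N(0, Σ + diag(W1/V1, W2/V2)).  With C = 0 this factorizes
into the two marginal ABFs.  Trait-wise BFs are left unadjusted; this is
an approximation to a full joint treatment of overlap, not a claim of
equivalence, but it is the part of the model where null correlation
changes the density ratio, and under a correlated null it demonstrably
lowers the false shared-effect weight relative to ignoring C.

## RTC colocalization

For a sentinel/eQTL pair within a recombination-hotspot interval of
N_int variants: for every interval variant s, expression is residualized
on the covariates plus dosage(s), and the eQTL lead variant's squared
t statistic is computed against the residuals.  Variants are ranked
ascending by that statistic (a better extinguisher ranks earlier; ties
broken by genomic position), and with Rank the sentinel's 0-based
position, RTC = (N_int − Rank)/N_int ∈ (0, 1]; RTC ≥ 0.9 is called
colocalized.  Expression is rank-inverse-normal transformed by default
(toggleable), standard eQTL practice that stabilizes the rank statistic.
Genotype principal components are computed by SVD of the centered dosage
matrix, sign-fixed by making each component's largest-magnitude loading
positive.  Expression-factor covariates (PEER-style) are accepted as a
user-supplied matrix rather than estimated; the sample-size rule used at
cohort scale (15 factors for N < 150, 30 for N < 250, 45 for N < 350,
60 otherwise) is recorded here for reference only.

## Causal inference test

For a triplet (L dosage, G cis expression, T trans expression), the
causal direction L→G→T requires four conditions simultaneously
(intersection-union): (1) L associated with T; (2) L associated with G
given T; (3) G associated with T given L; (4) L independent of T given
G.  Conditions 1–3 are 1-df partial F tests with L coded as an additive
numeric dosage.  Condition 4 is an equivalence test whose null is
conditional *dependence*: surrogate outcomes T\* = b_marg·L\* + resid(T ~ L)
are generated with L permuted within tertile bins of G (preserving the
L–G association coarsely) and a direct effect equal to the observed
marginal slope b_marg; p4 is the add-one-smoothed proportion of
surrogate F statistics (for L\* in T\* ~ G + L\*) at or below the
observed F.  Small p4 therefore supports conditional independence, the
same orientation as p1–p3, and the omnibus P is max(p1, p2, p3, p4).
An alternative orientation — plain within-stratum permutation with the
omnibus using 1 − p4 — was considered and rejected: under a true
mediation chain the observed F is exchangeable with plain permuted F, so
that omnibus is uniform under the causal model and the test has no
power.  The equivalence construction is the one with usable operating
characteristics (≈94% recovery of strong chains at n = 500, false
causal calls at or below the nominal rate under the no-mediation model).

Triplets are prefiltered by a Pearson correlation test between G and T
(kept iff P ≤ 0.05) to reduce the testing burden; the Bonferroni level
is α = 0.05 / (number of triplets passing the prefilter).  A triplet is
causal iff p_causal < α ≤ p_reactive, reactive for the mirror case, and
independent otherwise (including both-significant).  Permutation seeds
derive from the pipeline seed and the mediator's id, which makes
swapping G and T swap p_causal and p_reactive exactly.  B = 1000
permutations by default, so the smallest attainable p4 is ≈ 10⁻³; with
very many triplets the Bonferroni level can undercut that floor, a known
resolution limit of permutation components.

## Evidence aggregation

All four flags use inclusive thresholds: pp3 ≥ 0.9 for at least one
trait pair; membership in a 95% credible set for at least one trait;
RTC ≥ 0.9 against at least one eQTL dataset; and regBase PHRED ≥ 15 AND
cepip combined ≥ 0.6 AND RegulomeDB category at least as strong as 2c on
the fixed ladder 1a…7.  External scores are consumed from user-supplied
tables — the scoring tools themselves are external resources; this
module owns only thresholding and aggregation.  The flags are computed
per variant across any trait (the credible-set trait need not be the one
driving the pleiotropy flag).  A variant missing from an upstream table
fails that flag rather than erroring.  Candidates (all four flags true)
are ranked by shared-disease count descending, ties broken by
(chrom, pos) ascending — a deterministic convention, since no tie rule
is canonical.  Target genes: bait genes of overlapping interaction
regions with score strictly > 5, colocalized eGenes, and genes whose
protein product or splicing the variant alters, each tagged by source.

## Networks

The variant–gene bipartite network deduplicates edges and accumulates
disease labels per variant; disease-level compression produces a
disease–gene edge iff some variant of that disease targets the gene,
weighted by the number of such variants (weights are an extension — a
convenient support count, not a calibrated quantity).  The shared-gene
summary reports the percentage of genes with disease-degree ≥ k (default
3), rounded to two decimals.  The force-directed layout is a plain
Fruchterman–Reingold iteration (repulsion k²/d, spring attraction d²/k,
linear cooling, seeded initial positions, no rescaling — an isolated
connected pair settles near separation k).  It is decorative: no
inference rests on coordinates, only the qualitative property that
diseases with overlapping gene sets land nearer than disjoint ones.

## Transcript usage

Transcripts are classified long/short relative to a breakpoint position
(typically the chromatin-contact locus with the highest interaction
frequency in the gene's promoter region), strand-aware: long iff the TSS
is upstream of the breakpoint in the gene's strand sense (+: TSS <
breakpoint; −: TSS > breakpoint).  This reduces to the plus-strand rule
for IRF5 while staying gene-general.  A TSS exactly at the breakpoint is
classified short (the downstream-promoter side) with a warning; the
breakpoint itself is a parameter, since contact peaks are regions rather
than single bases.  Group TPM is a per-sample sum, so long + short
equals the gene TPM exactly.  Association is ordinary least squares of
group TPM on alt-allele dosage with a two-sided t test; TPM values are
used as given, without re-quantification.

## Synthetic data

Generators are pure functions of (inputs, seed); a top-level seed
expands into per-stage child seeds by fixed offsets.

**Genotypes.**  Haplotype alleles are thresholded latent Gaussians: each
block shares a common factor, and the latent correlation is found by
inverting the tetrachoric relation so the realized allele (and hence
dosage) Pearson correlation matches the requested within-block LD.  MAF
is drawn once per block, uniform over `maf_range` (default 0.05–0.5),
and shared by the block's variants: strongly correlated binary alleles
require comparable frequencies, so a per-variant MAF spread would
silently cap the attainable LD below the target.  Ref/alt pairs exclude
the strand-ambiguous A/T and C/G combinations so harmonization never has
to discard a synthetic site.  Monomorphic columns (possible at small n)
are repaired to polymorphic.  This emulates block-constant LD with clean
block boundaries — not realistic human haplotype structure, decaying LD,
or recombination-map detail; recovery results on this structure bound
what to expect on real panels from above.

**Paired GWAS.**  Quantitative phenotypes y_t = Σ effect·dosage + noise
with unit-variance noise; effects are per-allele on the trait scale.
Cohort overlap is modeled as fully shared samples with noise correlation
C, which makes the null per-variant Z-score correlation equal C — the
quantity the overlap correction consumes.  Case-control liability models
are out of scope; the downstream statistics operate on β/se/z, which the
linear model supplies directly.  Marginal per-variant regression gives
β, SE and two-sided t-test P values.  Default study conditions used in
the recovery suites: N = 2000, per-allele effect 0.35 (|z| ≳ 6 at common
MAF), within-block LD 0.3, blocks of ~10 variants.

**eQTL, triplets, usage.**  Expression = effect·dosage + covariate
effects + unit noise, with the covariate matrix (default 3 standard
normal columns, effects ~ N(0, 0.5²)) returned explicitly.  Mediation
triplets follow the generating equations of the causal, reactive and
independent models with independent unit noises and default unit path
coefficients.  Promoter-usage TPM moves `usage_effect` TPM per alt
allele from the long to the short group around baselines of 50 TPM with
noise SD 5 (floored at zero; defaults keep flooring negligible so the
reciprocal slopes are interpretable).

**What passing tests show.**  Calibration and recovery hold under the
generators' idealized structure (Gaussian noise, linear effects, clean
blocks, no confounding, no sample relatedness).  They demonstrate the
estimators are implemented correctly and have the intended operating
characteristics in their assumed regime — not that those rates transfer
to real cohorts, where LD structure, stratification and assay artifacts
degrade them.

## Problem sizes

The test and acceptance suites run simulations at N = 200–2000 samples,
blocks of 5–12 variants, 100–300 seeds per recovery claim, and 500–1000
permutations per CIT component — sizes chosen so every claim recomputes
from scratch in seconds to a few minutes on one CPU while keeping
Monte-Carlo error well inside the asserted margins.

## Known limitations

* Single-causal fine-mapping only; multi-causal configurations within a
  block violate the model and dilute posteriors.
* Pleiotropy priors are fixed, not empirically fitted; posteriors shift
  with π, though the recovery margins here are wide.
* The overlap correction adjusts only the shared-model BF.
* RTC is re-implemented from its ranking definition, not a wrapper
  around an external implementation.
* Permutation p values have a 1/(B+1) floor.
* The evidence layer consumes external annotation scores as given; it
  cannot validate them.
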
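# Methods

## Synthetic study design

The generator produces the data a multi-cohort metabolomics GWAS
consumes, with ground truth recorded in a machine-readable table.

**Genotypes.** Hard additive dosages in {0, 1, 2} under Hardy-Weinberg
equilibrium. LD follows a Gaussian copula: each haplotype's allele
indicator derives from a latent standard normal, and latents of variants
within one block (default 10 consecutive variants) share a single
exchangeable correlation (default 0.8); blocks are independent. This is
deliberately simple — no recombination maps, no population structure —
but yields the two properties the downstream methods rely on: realistic
within-region correlation for clumping/conditional analysis/
colocalization, and exact independence across blocks for planting
separable signals. Variants are placed every 20 kb on one chromosome;
allele frequencies are uniform on a configurable range (default
0.1–0.5 in the reference study so no planted QTL is endangered by the
minor-allele-count filter).

**Metabolites.** Natural-scale abundance
`10 ** (baseline + Σ beta·dosage + cohort_shift + N(0, noise_sd))`, i.e.
additive genetic effects, batch shifts and noise all on the log10 scale,
matching the pipeline's log10 transform. Defaults: baseline 1.0,
noise SD 0.25, batch shift +0.2 for the second cohort. Planted per-allele
effects of 0.26–0.35 on ~0.1–0.5-frequency variants give cis
heritabilities around 0.3–0.5 — the high end of what strong mQTLs show,
chosen so the two-stage design at n = 1,000 per stage has essentially
full power and structure recovery is exact rather than probabilistic.

**Missingness** is applied in a fixed order: (1) below-detection-limit
censoring — values under the metabolite's lower-tail quantile (an MNAR
mechanism); (2) completely-at-random dropout; (3) disease-linked dropout
for designated metabolites, with case missingness set by an odds ratio
against a base rate. Disease labels are Bernoulli draws independent of
genotype, which isolates the QC recovery rule from genetic confounding.

**Trait.** `mediated`: trait = causal_effect × standardized metabolite
log10 level + N(0, 1), so the metabolite's QTL is the trait's causal
variant (colocalization H4 truth) and the true MR slope on the
estimation scale is causal_effect / SD(log10 level). `independent-
signal`: the trait is driven by a different variant in the same region
(H3 truth). `null`: pure noise. The reference study uses causal_effect
0.5 per SD.

**Seeding.** One master seed; per-stage child seeds derive from it by
fixed offsets (`syndata.child_seed`), so each component is reproducible
in isolation and all seeds stay below 2^31.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: imputation-quality variation, population
stratification and relatedness, non-Gaussian abundance distributions,
metabolite-metabolite correlation beyond shared QTLs, platform-specific
batch artifacts beyond additive shifts, and trans-QTL networks. The
pipeline's statistical machinery is validated; its robustness to those
real-data features is not.

## Quality control

Metabolomics QC runs seven ordered stages: sample missingness > 50%;
non-xenobiotic metabolite missingness > 80% with a disease-recovery
check; per-cohort half-minimum imputation of non-xenobiotics only;
log10 transform (non-positive values masked, not fatal); removal of
near-constant metabolites (IQR = 0 or variance < 0.001); per-cohort
masking of values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; and removal of
metabolites with < 50 observed values (per analysis stage when a
discovery/replication split is declared, and counted after masking so
the count reflects analyzable values). Xenobiotics are never imputed and
never missingness-filtered; their missing values are dropped case-wise
at analysis time.

Two points were genuinely open and resolved as package design choices:

* **Outlier masking runs to a fixpoint.** The IQR fences are recomputed
  and re-applied until no further value is masked (convergence is fast —
  each pass masks well under 1% of remaining values). This makes the
  whole QC pipeline idempotent: applied to its own output it changes
  nothing, which in turn makes audit trails replayable. The cost is a
  slightly more aggressive trim than a single pass (≈3–4% of values on
  Gaussian data versus ≈0.7%).
* **The recovery rule** (for metabolites above the missingness cut) is
  operationalized as: some disease group shows a Fisher-exact-significant
  missingness difference from controls AND a significant abundance
  regression, with opposite directions (e.g. more missing and lower
  abundance), so that disease plausibly explains the missingness. Both
  tests at alpha 0.05.

Genotype QC removes variants failing call rate ≥ 95%, minor allele count
≥ 5, then Hardy-Weinberg exact p ≥ 1e-6, in that order, on hard calls
rounded from dosages (the data are dosage-typed). The HWE test
enumerates heterozygote counts conditional on allele counts and sums
probabilities no larger than the observed configuration's.

## Association and meta-analysis

Per-metabolite scans use ordinary least squares with case-wise deletion
of missing phenotype values, vectorized via Frisch–Waugh–Lovell
residualization; p-values use the t distribution at the per-test
residual degrees of freedom rather than the normal, which matters for
small cohorts. Meta-analysis is fixed-effect inverse-variance weighting
(the STDERR scheme); no heterogeneity-based model switching. Allele
harmonization across studies: direct match kept, swapped alleles flip
the effect sign, strand flips resolved by base complement when
unambiguous, palindromic (A/T, C/G) variants aligned by frequency when
|eaf − 0.5| > 0.08 and dropped otherwise. The study-wide threshold is
`5e-8 / n_independent_metabolites`, taking n as an input (the effective-
test count behind any given n is a property of the dataset, not of this
code). Genomic-control lambda is reported per metabolite; a configurable
cut (default 1.2) flags inflated analytes.

## Regions, loci and conditional signals

Coordinates are 1-based inclusive; a lead at position p claims
[p − 1 Mb + 1, p + 1 Mb], and windows that touch or overlap merge
(merged regions may exceed 2 Mb). Ties in p-value break lexicographically
by (chrom, pos, allele), making region construction order-invariant.

Independent signals use summary-statistics conditional analysis in the
style of stepwise conditional-and-joint selection: X'X is reconstructed
as n·D·R·D from the reference LD correlation R and per-variant dosage
SDs D = √(2f(1−f)), the phenotypic variance from the median of
n·se²·2f(1−f) + beta²·2f(1−f), and candidates join the model when their
conditional p passes the study-wide threshold and their squared multiple
correlation with the selected set stays below 0.9. Degenerate (singular)
LD submatrices skip the candidate as collinear.

Cross-tissue sharing is the raw-effect sign/two-fold definition: at
factor 0 the fraction of aligned effects with equal sign, at factor 0.5
additionally requiring the magnitude ratio within [0.5, 2]. The
empirical-Bayes shrinkage model that usually precedes this statistic is
intentionally out of scope; sharing is computed on the meta-analysis
estimates directly and documented as such.

Novelty calls take a reference catalogue as input: a region is reported
when a matched-metabolite catalogue variant falls inside the window, and
a reported region's signal is still novel when colocalization with the
catalogue study gives PP.H4 ≤ 0.6. Catalogue matching is by exact
metabolite identifier (a synonym table can be supplied); no fuzzy
matching.

## Colocalization

Standard single-causal-variant colocalization from summary statistics.
Effect-scale prior SDs are 0.15 (quantitative) and 0.2 (case-control);
configuration sums run in log space (log-sum-exp) — H1/H2/H4 over single
variants, H3 over ordered distinct pairs computed as the all-pairs sum
minus the diagonal, with a guard for regions where the diagonal carries
all the mass. Priors default to p1 = p2 = 1e-4 and p12 = 1e-5. When a
trait file lacks standard errors, varbeta is approximated as
1/(2·n·f(1−f)) on the unit-variance scale (divided by s(1−s) for
case-control), and the signed z is recovered from the p-value and the
effect direction.

## MWAS

Cis heritability per association region uses a REML-style variance
component on the region genetic relationship matrix: the likelihood is
profiled over the total variance on the GRM eigenbasis and maximized
over h² in [0, 1]; the likelihood-ratio p against h² = 0 uses the
boundary mixture ½χ²₀ + ½χ²₁. Regions with p ≥ 0.01 are gated out.
Predictors are `top1` (single best marginal variant, weight = its
marginal effect) and ridge over all region variants on the
covariate-residualized phenotype, with the penalty chosen by inner CV on
a 13-point logarithmic grid (1e-2 to 1e4) and the winning model chosen
by seeded 5-fold cross-validated R²; regions where no model predicts out
of sample (cv R² ≤ 0) are dropped. The association statistic is
Z = wᵀz/√(wᵀRw) against the reference LD, two-sided normal p, BH-FDR
over the metabolite × trait grid. Lasso/elastic-net candidates are
omitted: the selection logic between a sparse and a dense candidate is
the behavior under test, and ridge covers the dense case.

## Mendelian randomization

Greedy clumping by ascending p (r² cut 0.001 within 10 Mb against the
reference) selects instruments from study-wide-significant exposure
variants; instruments inside pleiotropic loci (≥ 5 member metabolites in
the main analysis, ≥ 2 in the stringent sensitivity mode) or supplied
exclusion windows (e.g. a FADS-region BED) are removed. Harmonization
keeps matched alleles, sign-flips swapped ones, and drops palindromic
variants with |eaf − 0.5| ≤ 0.08. Single instrument: Wald ratio with
first-order delta-method SE (beta_out/beta_exp, se_out/|beta_exp|).
Multiple: IVW slope through the origin weighted by 1/se_out², with the
SE inflated by the residual SD when it exceeds 1 — multiplicative random
effects that never deflate below the fixed-effect SE. `se_from_p`
recovers |beta|/Φ⁻¹(1 − p/2) for outcome files without standard errors.
FDR spans the full grid of attempted tests. MR-Egger/weighted-median
sensitivity estimators are out of scope.

## Triangulation and annotation

Evidence tiers are a pure function of three flags: MWAS FDR < 0.05, MR
FDR < 0.05, PP.H4 > 0.6 (strict inequality); three-way/two-way/one-way/
none by count, with missing analyses counted as non-support and flagged.
Effector-gene nomination is a fixed decision tree over precomputed
annotation tables (consequence prediction itself is out of scope):
protein-sequence-altering variant → its gene, preferring genes
overlapping the signal's LD region; else a gene supported by both
proximity/eQTL and metabolic-pathway membership; else the nearest gene
with an overlapping eQTL; else the nearest gene — with a curated
metabolite→gene knowledge table overriding the tree when it names a
different gene among the ten nearest (the override is recorded). "Nearest"
is by distance with ties broken by identifier, so nomination is
deterministic and row-order invariant. Cell-type specificity assigns a
gene to the cell type carrying strictly more than half its summed
expression; enrichment of nominated genes per cell type uses Fisher's
exact test on the 2×2 nominated × specific table with
log2FC = log2(proportion specific among nominated / proportion specific
in the background) — the exact test is a package choice and labeled as
such in output metadata.

## Problem sizes and numerical choices

The reference end-to-end study is two cohorts × 1,000 samples, 5,000
variants, 40 metabolites — large enough that every planted structure is
recovered exactly, small enough to run in about half a minute.
Simulation-based checks use 50–100 replicates at n = 1,500–2,000 and
60–200 variants per region. Ill-conditioned joint fits fall back by
skipping the offending candidate; p-values are floored at the smallest
positive double; the BH step-up is delegated to statsmodels and verified
against a literal step-up implementation in the tests. All randomness
flows from explicit seeds.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multi-causal
extension); fixed-effect meta-analysis only; no mixed-model/relatedness-
aware association (inputs are assumed unrelated, as after upstream IBD
pruning); the effective-metabolite count for the study-wide threshold is
an input, not estimated; the cross-tissue sharing statistic omits
empirical-Bayes shrinkage; gene nomination consumes precomputed
annotation and eQTL tables rather than running predictors.
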
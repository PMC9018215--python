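# Methods

## The system being modelled

Plasma Lp(a) is determined almost entirely by the *LPA* locus. Each allele
encodes an apo(a) isoform whose size follows the KIV-2 copy-number repeat;
isoform size correlates inversely with expression, and rare regulatory or
coding SNPs (rs186696265 near the upstream enhancers, the intronic
rs140570886, the missense rs3798220, the KIV-2 splice-site change 4925G>A)
move expression beyond the size effect. The package models a
cascade-screened, three-generation family in which one short allele — 21
total KIV domains, carrying rs3798220 + rs186696265 + rs140570886 —
segregates with the high-Lp(a) phenotype, and provides the machinery to ask
the study's questions on synthetic data: does an *LPA*-region polygenic
score discriminate affected relatives, does exome-wide dominant-model
filtering isolate the causal site, and how much of a genome-wide CAD score
is attributable to the *LPA* interval?

## Pedigree template and gene dropping

The packaged template has 22 members (IDs I-1 … III-C4): the two deceased
grandparents (no plasma phenotype), five of their children with five
married-in spouses, and ten grandchildren. Labels follow the family
classification — high: Lp(a) > 150 nmol/L; normal: ≤ 90 nmol/L. The fixed
template transmission reproduces the published segregation pattern: the
21-KIV allele enters through founder I-1; every high-labelled member
carries it except the spouse II-C1 (his own 15-KIV/20-KIV combination, the
20-KIV allele tagged by rs10455872) and his daughter III-C3 (who inherited
the 15-KIV allele). The grandchildren counts are stylized (ten rather than
the full sibships of the source family); the headline structure — 22
members, 17 related, 5 spouses, six high-Lp(a) members with premature CAD —
is preserved.

Gene dropping is Mendelian without recombination: each transmitted
haplotype *is* one founder haplotype, so a member's genome per chromosome
is a pair of founder-haplotype labels; chromosomes assort independently.
`gene_drop` draws each inherited haplotype uniformly from the parent's
pair; `template_gene_drop` applies the fixed pattern. Mendelian consistency
(every child allele identical to a parental allele) is asserted in tests on
every simulated drop.

## Phenotype model

Allele expression follows a monotone size curve
`E(k) = e0 · exp(−λ(k − k0))` nmol/L with defaults e0 = 160, k0 = 15,
λ = 0.12 — only the inverse size–concentration relation is established, so
a parametric monotone form was chosen for testability. An allele's
contribution is `E(k) · ε + Σ effects(SNPs) · 2.4`, floored at 0, where ε
is log-normal with unit mean (σ = 0.25; Lp(a) is right-skewed) and per-SNP
effects are in mg/dL: rs186696265 +47.6 and rs140570886 +23.8 (joint-model
estimates, appropriate because the three SNPs co-occur on one haplotype),
rs3798220 +43 (no published per-SNP estimate; the low end of the quoted
range for these variants), 4925G>A −5 (expression-damping), rs10455872 0
(its effect on the spouse allele is deliberately left configurable, not
asserted). The mg/dL → nmol/L factor 2.4 is a field convention and is
exposed as a parameter everywhere it is used. Total Lp(a) is the sum over
the two alleles. With these defaults, noise off, 21-KIV carriers lie near
350–400 nmol/L, II-C1 at ≈ 250, III-C3 at ≈ 195, and non-carriers below
90 — thresholding at 150 nmol/L reproduces the carrier partition plus the
two spouse-allele cases exactly.

The dominant-isoform fraction is the shorter expressed allele's share of
total Lp(a); when the shorter allele carries an enhancer SNP it is drawn
from a truncated normal (mean 0.86, sd 0.14 on [0.5, 1]), reflecting the
observed predominance of the short isoform in carriers. oxPL/Lp(a) is
normal with mean 7.45 (sd 1.65) in non-carriers and 7.45 + 1.32 = 8.77
(sd 0.68) in rs3798220 carriers. LDL-C is N(3.0, 0.75²) mmol/L,
independent of Lp(a) — by design the family's raw LDL-C does not separate
the phenotype groups; only the Lp(a)-corrected value trends lower.

CAD status uses a liability threshold: liability = polygenic component
(standardized) + β · standardized Lp(a) + residual N(0, 0.5²), affected
above the threshold that gives 5% baseline prevalence at β = 0. Default
β = 1 per standardized Lp(a) unit (population mean 35, sd 45 nmol/L) makes the
family's extreme Lp(a) the dominant liability term.

## Genotyping panel, weight files, reference cohort

The emitted panel holds 117 biallelic sites: the five named LPA variants at
(approximate GRCh37) positions inside the ablation interval
chr6:159,991,850–161,753,083; 12 "tag" sites carried on the 21-KIV
haplotype (standing in for the LD between the causal haplotype and the
genome-wide-significant region); 32 filler sites; 28 exome background sites
placed inside, within 50 bp of, and beyond 50 bp of annotated exons (three
with a designed low-coverage sample); and 40 CAD background sites on other
chromosomes. The 48-row Lp(a) weight file (three rare SNPs at their nmol/L
effects, rs10455872, the tags, small-weight fillers) and the 56-row CAD
weight file are generated with a fixed internal panel seed, so they behave
as fixed inputs across simulation seeds. The reference cohort draws
genotypes per site as Binomial(2, p) — Hardy–Weinberg equilibrium —
independently across sites and individuals; a calibrated chi-square
goodness-of-fit check (common frequencies, n = 4000, so expected counts
support the asymptotic level) verifies it.

The planted causal site for the segregation scan is the exonic rs3798220
(the other two co-segregating rare SNPs are intronic/upstream, hence
removed by the proximity filter). After background genotypes are drawn, any
other exon-proximal site that would segregate perfectly in the 13-member
exome subset has the unaffected spouse founder haplotype II-A1.0 set to
carrier — a Mendelian-consistent correction that guarantees the planted
site is the unique survivor under default filters.

## Scoring, percentiles, segregation, models — numerical choices

* Weight rows match genotypes by (chromosome, position) with allele-set
  verification (variant IDs drift between builds); chromosome labels are
  compared after stripping `chr`. No strand flipping: mismatches are
  surfaced (skip or strict policy), never silently resolved.
* Intervals are 1-based and inclusive of both endpoints, matching printed
  locus coordinates; BED converts at the read boundary. A weight row on an
  interval endpoint is excluded.
* Missing genotypes default to "skip" (the row contributes nothing and is
  counted); the "impute" policy substitutes 2 × the effect-allele frequency
  estimated from the cohort's non-missing calls.
* Percentiles use the mid-rank convention, which is exact under the ties
  that integer dosages produce; flags are strict (> 95th, > 97.5th
  empirical percentiles). Paired full/ablated reports always recompute the
  reference under the same exclusion.
* The depth filter is variant-level: every analyzed sample must reach the
  threshold (default 4×), because the segregation verdict needs confident
  calls in each informative individual. The homozygous-carrier tolerance is
  counted among affected samples only. Missing genotypes fail the
  affected-carrier requirement and never count as phenocopies.
* The inverse-normal transform uses Blom offsets, Φ⁻¹((r − 3/8)/(n + ¼)),
  with mid-ranks for ties. Variance-explained models are ordinary least
  squares (no kinship adjustment — deliberately mirroring the family-study
  practice of fitting plain regressions despite relatedness; a mixed model
  would be the statistically stricter choice). Welch's t uses Satterthwaite
  df clamped at ≥ 1 for degenerate zero-variance groups. Isoform size
  enters models as the KIV count of the shorter expressed allele; 4925G>A
  as a carrier indicator.
* LDL-C correction: corrected = LDL-C − 0.30 × (Lp(a)/2.4) × 0.02586
  mmol/L, floored at 0; both the cholesterol fraction and the mass
  conversion are parameters because the exact published formula is not
  fully specified.

## What the generator does and does not emulate

It reproduces the study's *structure*: Mendelian segregation of a
multi-SNP high-expressing haplotype, isoform-size-dependent expression,
phenotype thresholds, a 13-exome dominant-model scan with a single causal
site, and a CAD score whose family elevation flows through the *LPA*
interval. It does not emulate real LD structure (tags are perfectly linked
to the haplotype; fillers are independent), sequencing error, imputation
uncertainty, ascertainment beyond the fixed template, allelic
heterogeneity, or recombination within chromosomes. Passing tests
therefore demonstrate correctness of the pipeline's logic under its stated
model, not calibration against real cohort data — the published
variance-explained figures, survivor counts and real-family percentile
placements require subject-level genotypes that are not publicly deposited.

## Problem sizes used in tests and the acceptance script

Transmission statistics use 10,000 gene drops; additivity 100 random
panels; oracle checks enumerate all 4⁵ genotype configurations for 3
affected + 2 unaffected samples; percentile self-uniformity a 5,000-member
reference; Hardy–Weinberg calibration 200 cohorts of 4,000; the
variance-explained recovery 500 replicates at n = 17 (the family's
informative sample size), where the median recovered R² sits ≈ 2 points
above the 58.1% calibration — the expected small-n inflation of OLS R²,
with wide dispersion quantified by the replicates; the ablation flag-flip
rate 200 seeds with a 250-member reference. These sizes are the package's
own choice of a demonstration scale; all generators accept larger values.
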
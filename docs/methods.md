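# Methods

## The compatibility model

Each subject carries an unphased genotype — an unordered pair of
two-field HLA alleles per classical locus (A, B, C, DPB1, DQA1, DQB1,
DRB1) and an unordered pair of bases per mHag tag SNP. For a
mother–child duo at one locus, the maternally transmitted allele is
any child allele found in the mother's pair; matching consumes
multiplicity, so a homozygous mother m/m can transmit only m, which
prevents spurious Mendelian errors in m/m × m/p duos. The remaining
child allele is the paternal candidate and the mother's remaining
allele is the noninherited maternal allele (NIMA). Outcomes:

* **resolved** — exactly one paternal candidate;
* **ambiguous** — both child alleles lie in the mother's set and the
  candidates differ; every candidate is then a maternal allele;
* **Mendelian error** — no child allele matches the mother; the duo
  carries no valid transmission information;
* **missing** — either genotype is untyped.

A child is *histocompatible from the mother's perspective* iff every
paternal candidate is indistinguishable from one of the mother's
alleles. Under ambiguity all candidates are maternal by construction,
so the rule collapses to: both child alleles are members of the
mother's allele set. The test suite proves this equivalence against a
brute-force enumeration of all phase assignments on alphabets of up to
six alleles.

Per-mother exposure at a locus is "any histocompatible child". For
case mothers only children born before diagnosis are eligible; all
children of control mothers are eligible (the diagnosis-date flag has
no meaning for them). Children with missing or Mendelian-inconsistent
verdicts are excluded from the any-compatible OR but tallied; we treat
a Mendelian-error verdict like a missing one on the grounds that an
inconsistent duo identifies no paternal allele. The exposure is
missing only when no eligible child has a usable verdict. HLA analyses
use a complete-case sample: mothers with a non-missing exposure at all
seven loci.

## SSM scoring

The sequence similarity matching score of two aligned allele protein
sequences is

    SSM(a, b) = Σ_{p : a[p] ≠ b[p]}  w(locus, p) · d(a[p], b[p])

with a symmetric, zero-diagonal, non-negative amino-acid dissimilarity
`d` and non-negative position weights `w` (default 1). Both are fully
configurable; the packaged default `d` is derived from BLOSUM62 as the
substitution-kernel distance `d(a,b) = s(a,a) + s(b,b) − 2·s(a,b)`,
which is zero iff the residues are identical. Sequences must be
pre-aligned to equal length; no internal alignment is attempted.

A mother–child pair scores the NIMA against the paternal allele.
Genotype-identical pairs score exactly 0. When the transmission
assignment is not unique the score-minimizing assignment is used — a
deterministic tie-break that biases toward similarity and agrees with
the zero rule on identical genotypes. Per-mother locus scores are the
mean over eligible children with available pair scores.

Quartile cutpoints are the empirical 25/50/75th percentiles of the
control mothers' mean scores (linear-interpolation definition, fixed
for reproducibility). Assignment intervals are left-closed and
right-open with the last interval closed; quartile 1 holds the
smallest scores (most histocompatible), quartile 4 the largest. Fewer
than four distinct control scores is an error directing the analyst to
manual bins rather than silently producing degenerate quartiles.

## mHag layer

The six shipped definitions pair each mHag tag SNP with its HLA
restriction allele: SLC19A1/rs1051266/DRB1\*15:01,
LB-WNK1/rs12828016/A\*02:01, HA-3/rs2061821/A\*01:01,
ZAPHIR/rs2074071/B\*07:02, HEATR1/rs2275687/B\*08:01,
C19orf48/rs3745526/A\*02:01. Analyses are restricted to mothers
carrying at least one copy of the restriction allele (carriage-based,
not dosage-based); carriage is missing, and the mother excluded, when
her restriction-locus genotype is untyped. SNP compatibility uses the
same mother-perspective rule on a two-letter alphabet, so a
SNP-heterozygous mother is compatible with every Mendelian child. The
combined HLA+mHag exposure is a per-child conjunction — the same child
must be compatible at both the restriction locus and the SNP — OR'd
across children; a mother with one HLA-compatible child and a
different mHag-compatible child is not combined-compatible. A child
incompatible on either side is a known non-contributor even when the
other verdict is missing.

## Association layer

Adjusted ORs come from maximum-likelihood logistic regression of
case status on the binary exposure plus the number of live births
entered as a continuous linear term; 95% CIs are Wald intervals on the
log-odds scale. Complete or quasi-separation (non-convergence, or a
Wald SE above 50 on the log scale) returns a flagged, non-estimable
result rather than a spurious OR. Crude ORs use the cross-product with
Woolf log-method CIs; a zero cell leaves the OR undefined and flagged
— no continuity correction is applied. Fisher's exact p values follow
the minimum-likelihood two-sided convention (sum of all
fixed-margin tables no more probable than the observed one, with the
conventional 1 + 1e-7 tie tolerance); the test suite checks them
against an exact integer-arithmetic enumeration on every table with
total ≤ 60. Bonferroni correction multiplies p by the number of loci
tested (seven by default), capped at 1. The SSM trend test enters the
quartile as a single ordinal numeric term (1–4) — a convention; the
Wald p is invariant to affine recoding. Missingness comparisons use
Pearson's chi-square without continuity correction, warning when an
expected cell falls below 1.

## Synthetic cohorts

The generator defines the study conditions under which the pipeline is
validated:

* **Allele frequencies.** Mothers are drawn under Hardy–Weinberg
  equilibrium from per-locus frequency vectors; the defaults
  approximate European two-field HLA frequencies (14–22 alleles per
  class I locus, 9–19 per class II) and common-variant frequencies for
  the six tag SNPs. Children receive one maternal allele uniformly at
  random and one paternal allele from the population.
* **Parity.** Live births per mother follow a zero-truncated Poisson
  with mean parameter 2.0, echoing the roughly two births per mother
  in the emulated study populations; the number of genotyped children
  is capped at 3 per family to keep cohorts desk-scale.
* **Disease.** Case status is Bernoulli with logit equal to a baseline
  of −1.6 (≈22% case mothers at two live births, matching the
  case–control composition of the emulated samples) plus 0.15 per
  live birth plus a configurable log-OR per true any-compatible
  exposure at designated loci (default: none, the null model).
* **Missingness.** Applied last, missing-completely-at-random within
  disease group with per-locus (optionally group-specific) rates, so
  the generative truth is recorded before degradation.

The truth object (per-mother exposures, per-child paternal alleles,
disease probabilities) is emitted for recovery tests only; the
pipeline never reads it. With missingness 0 the classifier reproduces
the truth exposures exactly (pipeline-closure test).

What the generator does **not** emulate: linkage disequilibrium
between loci and between tag SNPs and HLA haplotypes, population
stratification, imputation error, genotyping batch effects, assortative
mating, and any dependence of fertility on genotype or latent disease.
Passing recovery tests therefore demonstrates the pipeline's
correctness under its own assumptions, not robustness to those
real-data complications.

## Problem sizes and numerical choices

The recovery study runs 200 cohorts of 1000 mothers at DPB1 (the
best-balanced locus, ~45% exposure prevalence) with a true adjusted
exposure OR of 1.8; the mean recovered OR lands within a few percent
of the target (finite-sample MLE and Jensen bias are visible at ~220
cases per cohort and vanish by n = 4000), and Wald coverage sits at
its nominal 95% within Monte-Carlo error. Null calibration uses 300
cohorts of 600 mothers for the locus test and the quartile trend test.
Exhaustive oracle checks cover all mother/child genotype combinations
on six-allele alphabets and all 2×2 tables with total ≤ 60.

Ties and degenerate inputs: half-called genotypes are collapsed to
missing; duplicate two-field FASTA records keep the first occurrence
with a warning; allele names above two-field resolution are truncated,
not rejected; the canonical missing token is `NA` (empty accepted on
input). Report files are written with fixed float formatting so
regeneration from identical inputs is byte-identical.

## Known limitations

* The SSM dissimilarity and functional-position weights of the original
  HistoCheck tool are proprietary; the scorer reproduces the score's
  *structure* and ships a documented generic default, so absolute score
  values are not comparable to HistoCheck output, though orderings
  under any fixed resource set are internally consistent.
* Published adjusted ORs cannot be recomputed from printed contingency
  tables without individual-level covariate data; the statistical layer
  is instead validated by simulation (parameter recovery, coverage,
  type-I error) and by the crude statistics the printed tables do
  determine.
* The logistic layer offers Wald inference only; profile-likelihood or
  Firth corrections would be natural extensions for sparse tables.
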
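# histocompat

Mother–child histocompatibility analysis for autoimmune-disease
epidemiology.

During pregnancy, fetal cells enter the maternal circulation and can
persist for decades (fetal microchimerism). If a child's paternally
inherited HLA allele is indistinguishable from one of the mother's own
alleles, those fetal cells look "self" to the maternal immune system —
a graft-like relationship hypothesized to influence the mother's risk
of rheumatoid arthritis (RA) and systemic lupus erythematosus (SLE).
`histocompat` implements the full analysis pipeline for testing that
hypothesis in case–control cohorts of mothers and their children:

* **Paternal-allele inference from unphased duos.** At each classical
  HLA locus (A, B, C, DPB1, DQA1, DQB1, DRB1) the maternally
  transmitted allele is resolved by multiset matching against the
  mother's genotype; the child is *histocompatible from the mother's
  perspective* iff the paternal allele lies in the mother's allele set
  (equivalently, iff both child alleles do). Per mother, exposure is
  "any histocompatible child", counting only children born before
  diagnosis for case mothers.
* **Sequence similarity matching (SSM) scores.** For non-identical
  pairs the disparity between the noninherited maternal allele *m* and
  the paternal allele *p* is scored positionally over aligned protein
  sequences, `SSM(m,p) = Σ_{m[i]≠p[i]} w_i · d(m[i], p[i])`, with a
  configurable amino-acid dissimilarity `d` and position weights `w`;
  genotype-identical pairs score 0. Per-mother locus means are binned
  into quartiles of the control distribution (quartile 1 = most
  similar).
* **HLA-restricted minor histocompatibility antigens (mHags).** Six
  mHags (SLC19A1, LB-WNK1, HA-3, ZAPHIR, HEATR1, C19orf48) are
  classified from their tag SNPs with the same mother-perspective
  rule, restricted to mothers carrying the presenting HLA allele
  (e.g. B\*07:02 for ZAPHIR), plus a per-child combined
  HLA-and-mHag exposure.
* **Association layer.** Logistic regression ORs adjusted for number
  of live births with 95% Wald CIs, crude ORs (Woolf CIs), two-sided
  Fisher's exact tests, Bonferroni correction over the seven loci,
  ordinal trend tests over SSM quartiles, and case–control
  missingness chi-squares.
* **Synthetic cohorts.** A generator draws mothers under
  Hardy–Weinberg equilibrium, transmits alleles Mendelianly, ties
  child counts to a live-birth distribution, assigns disease by a
  logistic model on true exposures, and emits the generative truth for
  recovery tests.

## Worked example

```python
import math
from histocompat import SimulationConfig, simulate_cohort, MotherChildModel

cfg = SimulationConfig(n_mothers=400, exposure_log_or={"B": math.log(1.8)}, seed=11)
cohort, truth = simulate_cohort(cfg)
results = MotherChildModel(cohort).fit()
print(results.hla[["disease", "locus", "case_any", "control_any",
                   "adj_or", "ci_low", "ci_high", "p_bonferroni"]]
      .head(3).to_string(index=False))
```

```
disease locus  case_any  control_any   adj_or   ci_low  ci_high  p_bonferroni
     RA     A        51          112 1.091124 0.693618 1.716435      1.000000
     RA     B        44           62 2.075951 1.292983 3.333046      0.017483
     RA     C        32           79 0.872730 0.527473 1.443973      1.000000
```

The cohort was simulated with a true exposure odds ratio of 1.8 at
HLA-B and no effect elsewhere: the fitted model recovers an elevated,
Bonferroni-significant OR at B (2.1 here; with n = 400 mothers the
estimate is noisy but the CI excludes 1) and near-null ORs at the
other loci. `results.summary()` prints all tables — HLA
associations, SSM quartiles (when scoring resources are supplied),
mHag and combined Fisher tables, and missingness — and
`results.save("report/")` writes them as TSVs plus a JSON summary.

The same pipeline is scriptable from the shell:

```bash
histocompat simulate --seed 7 --out cohort.tsv
histocompat classify --cohort cohort.tsv --out calls.tsv
histocompat associate --cohort cohort.tsv --out report/
histocompat fixtures --verify
```

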
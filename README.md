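# somaticlens

Somatic mutation analysis for targeted cancer-sequencing cohorts — with
or without matched normals.

Many translational cohorts (archival series, consecutive surgical
series) have tumor DNA but no matched blood, so germline variants cannot
be subtracted directly. `somaticlens` implements a high-fidelity
**tumor-only somatic filtering protocol** and the downstream cohort
analyses that depend on it, for panel or exome variant-call tables:

1. **Matched-pair filtering** — SNVs retained when on the capture
   target, inside exons or canonical splice sites, variant depth ≥ 5,
   normal depth ≥ 10, and absent from the matched normal; microindels
   pass a seven-rule filter (no simple repeat; depth ≥ 5 with both
   strands; normal depth ≥ 10; ≥ 5% of reads; window base quality ≥ 25;
   per-read mismatches ≤ 4; mismatched-base fraction ≤ 0.2).
2. **Two-step tumor-only filtering** — (i) exclude variants present in
   germline databases (dbSNP-like, population, panel-of-normals), but
   *rescue* variants catalogued as somatic cancer mutations (COSMIC);
   (ii) exclude variants with allele fraction VAF > 0.41. The rationale:
   in an impure tumor a het somatic mutation has expected VAF
   `p·m / (p·C + 2(1−p)) < 0.5`, while germline hets sit at ~0.5 and
   homozygotes at ~1. The package also reproduces the protocol's known
   failure mode (a COSMIC-listed germline variant below the cutoff is
   incorrectly retained) and scores it as a false positive.
3. **Validation** — confusion matrix and PPV/NPV/sensitivity/specificity
   of tumor-only calls against matched-normal (or simulated) truth, plus
   a VAF-threshold operating-characteristic sweep.
4. **Landscape** — samples × genes co-mutation matrix, per-gene
   frequencies, functional-class breakdown, pyrimidine-strand
   substitution spectrum with CpG split of C>T, cohort-vs-cohort
   chi-square comparison with Benjamini-Hochberg correction.
5. **Gene sets** — pathway alteration calls, exact hypergeometric
   enrichment over a gene universe, and a permutation test for mutual
   exclusivity that preserves per-gene alteration frequencies.
6. **Survival** — Kaplan-Meier curves, log-rank tests, univariate
   screening at P ≤ 0.2, multivariate Cox proportional hazards (Efron
   ties, Wald 95% CIs) stratified by pathway-mutation status.
7. **Synthetic cohorts** — a generator producing discovery-style
   (matched) and prevalence-style (tumor-only) cohorts with known
   somatic/germline truth, purity- and copy-number-driven VAFs, binomial
   read sampling, database membership, and exponential survival times
   whose hazard depends on pathway status — so every stage runs and is
   testable with no external data.

## Worked example

```python
from somaticlens.simulate import SimConfig, simulate_cohort
from somaticlens.filtering import run_tumor_only, evaluate_against_truth

truth = simulate_cohort(SimConfig(n_samples=18, seed=1))
decided = run_tumor_only(truth.variants)
m = evaluate_against_truth(decided["passed"].tolist(),
                           decided["truth_label"].tolist())
print(f"PPV={m.ppv:.3f} NPV={m.npv:.3f} "
      f"sens={m.sensitivity:.3f} spec={m.specificity:.3f}  n={m.n}")
```

prints

```
PPV=0.989 NPV=0.920 sens=0.787 spec=0.996  n=3882
```

meaning: on an 18-sample simulated cohort (default conditions: mean 61
somatic variants/sample, purity 0.5–0.8, 98% germline database
completeness), 98.9% of variants the tumor-only protocol retains are
truly somatic, it recovers 79% of somatic variants (losses are mostly
high-VAF somatic calls in copy-gained or high-purity samples), and it
excludes 99.6% of germline variants.

The same pipeline is available from the shell:

```bash
somaticlens simulate --seed 5 --out sim/
somaticlens filter-tumor-only --variants sim/variants.tsv --out decisions.tsv
somaticlens validate --decisions decisions.tsv --truth sim/variants.tsv --out metrics.json
somaticlens survive --clinical sim/survival.tsv --variants passing.tsv \
    --geneset notch.tsv --endpoint dfs --out surv.json
```

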
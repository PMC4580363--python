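# Methods

## Problem setting

Targeted deep sequencing of tumor cohorts yields per-sample variant
call tables mixing true somatic mutations with germline variants. With
a matched normal, germline calls are subtracted directly; without one,
somatic status must be inferred from population databases and allele
fractions. This package implements both routes and everything a
cohort-level mutation study builds on top of them: the co-mutation
matrix, per-gene frequencies, substitution spectra, pathway alteration
and exclusivity statistics, and survival stratification.

## Filtering model

**Matched-pair SNVs** are retained when they lie on the capture target
inside exons or canonical splice sites (the two intronic bases flanking
each exon), have variant depth ≥ 5 and matched-normal depth ≥ 10, and
show zero variant reads in the normal. **Microindels** additionally
must (1) avoid simple repeats, (2) carry ≥ 5 supporting reads with at
least one on each strand, (3) have normal depth ≥ 10, (4) occupy ≥ 5%
of reads, (5) show mean base quality ≥ 25 inside the indel ± 5 bases,
(6) mean per-read mismatches ≤ 4 and (7) mean mismatched-base fraction
≤ 0.2. Failures enumerate *every* violated rule (machine-readable
reason codes), and missing indel quality evidence fails closed under a
distinct code. The matched microindel path also applies normal
subtraction (any variant read in the normal fails the call): the seven
retention rules are read-quality filters, while subtraction is what
makes the design "matched"; leaving germline indels through would be
inconsistent with the SNV path.

**Tumor-only classification** is two steps, applied after the same
target/region/depth gate. Step 1 excludes variants present in any
germline allowlist — dbSNP-like, population (1000-Genomes-like, EVS-
like) and a panel of normals — unless the variant is catalogued in a
COSMIC-like somatic database ("rescue"): germline databases contain
recurrent oncogenic somatic mutations, and dropping them would
decimate, e.g., TP53 drivers. An ExAC-like allowlist is supported but
off by default for the same reason (it removes a large share of true
TP53 alterations). Step 2 excludes variants with VAF strictly above
0.41. Rationale: with purity `p`, local tumor copy number `C` and `m`
mutant copies, the expected fraction is `p·m/(p·C + 2(1−p))` for
somatic variants — usually well below 0.5 — while germline hets sit at
≈ 0.5 (exactly 0.5 when the tumor is diploid at the locus, independent
of purity) and homozygotes near 1. The VAF step is unconditional: it
also removes COSMIC-rescued variants, and a config switch can exempt
indels (the default applies it to both SNVs and indels). Raw
`variant_depth/total_depth` is used with no purity correction —
thresholding the observed read proportion is the protocol.

Two error modes are inherent and deliberately surfaced rather than
patched: a COSMIC-listed germline variant below the cutoff is retained
(a false positive), and a somatic mutation pushed above 0.41 by copy
gain or high purity is discarded (a false negative). Validation against
matched-pair (or simulated) truth reports TP/FP/TN/FN and
PPV/NPV/sensitivity/specificity, with rates whose denominator is zero
reported as absent, not zero.

## Landscape statistics

The co-mutation matrix flags a sample × gene cell when the sample
carries ≥ 1 passing nonsynonymous variant in the gene (multiplicity is
kept in a parallel count matrix); synonymous calls are excluded.
Frequencies are denominated on the full roster, including unaltered
samples, and a variant naming a sample outside the roster is an error
so denominators cannot drift silently. Functional-class percentages are
against the total nonsynonymous count. The substitution spectrum
collapses purine-reference SNVs onto the pyrimidine strand by reverse
complement (an involution: already-pyrimidine classes are unchanged)
and splits C>T by CpG context (collapsed context 5'-xCG). Cohort
comparisons use per-gene 2×2 Pearson chi-square without continuity
correction by default (Yates available by switch — it changes
borderline p-values) followed by Benjamini-Hochberg step-up across
exactly the supplied gene family; results with any expected cell < 1
are flagged but still reported.

## Gene sets and exclusivity

A sample is pathway-altered when any set gene is altered in the matrix;
set genes missing from the matrix contribute nothing and are reported.
Enrichment uses the exact upper-tail hypergeometric probability of the
observed overlap between the set and the cohort's mutated genes over a
stated universe (default: the capture panel). Mutual exclusivity — a
visual claim in most cohort studies — is made checkable here: the
statistic is the number of samples with ≥ 2 altered set genes, and the
null permutes each gene's sample labels independently, preserving
per-gene alteration frequencies exactly; p is the fraction of null
draws with co-occurrence ≤ observed. An exhaustive enumeration mode
(all joint column permutations) exists for tiny instances and anchors
the Monte Carlo test in the suite.

## Survival

Kaplan-Meier product-limit estimation, k-group log-rank tests,
univariate screening that keeps covariates with log-rank P ≤ 0.2
(boundary inclusive; continuous covariates must be dichotomized
explicitly — no cutpoint is guessed), and multivariate Cox proportional
hazards with Efron tie handling and Wald 95% CIs, all via lifelines.
Degenerate fits — zero events, constant covariates, monotone likelihood
from complete separation — raise instead of returning silent estimates.

## Synthetic cohort generator

The generator works at the variant-call level (no reads/FASTQ/BAM) and
emulates a targeted-panel study design. Defaults are the conditions the
package is calibrated to: 60 samples; somatic count per sample
Poisson(61); germline count Poisson(150) (a plausible panel-restricted
germline load on a 465-gene panel); purity uniform on (0.5, 0.8)
(cohorts of this type confirm > 50% tumor content but rarely report
per-sample purity — a documented assumption, not a measured truth);
tumor depth negative binomial with mean 136 and dispersion 8 (capture
depth is overdispersed relative to Poisson), normal depth mean 93;
local copy number in {1,2,3,4} with probabilities {0.10, 0.70, 0.15,
0.05}; germline het:hom 2:1; database completeness 0.98; 10% of somatic
variants COSMIC-listed and 1% of germline variants COSMIC-listed (the
rescue-rule failure mode must be representable); substitution classes
elevated for C>T, particularly at CpG (deamination-style spectrum),
with half of the calls emitted on the purine strand to exercise
collapsing; ~9% of somatic calls are indels with plausible quality
metrics. Variant placement is weighted by coding length over the gene
universe (uniform per base — the neutral choice). Survival times are
exponential with baseline hazard 0.012/month, multiplied by 3.3 for
samples carrying ≥ 1 nonsynonymous somatic variant in the designated
pathway (Notch by default), with ~30% independent uniform censoring;
proportional hazards holds by construction, so Cox recovery is
well-posed. All randomness flows from one `numpy` Generator seeded by
`SimConfig.seed`; identical configs produce byte-identical output
files.

What the generator does *not* emulate: shared germline variants across
samples (each draw is independent), sequence-context-realistic
signatures beyond the class distribution, segment-level copy-number
structure (copy state is drawn per variant), sample swaps or
contamination, and caller-specific artifacts. Tests passing on
simulated cohorts therefore demonstrate the pipeline's internal
correctness and its behavior under the stated generative assumptions,
not performance on any real cohort.

## Numerical and design choices

- Variant keys are normalized by right-trimming the shared allele
  suffix then left-trimming the prefix (position advancing), leaving at
  least one base — so equivalent indel spellings match across dialects
  without a reference genome.
- Tumor-only step order is gate → database → VAF, with reasons
  accumulating across steps; a VAF of exactly 0.41 is retained (strict
  inequality).
- Exact-tie boundary semantics throughout: depth ≥ 5/≥ 10, quality
  ≥ 25, mismatches ≤ 4/≤ 0.2, screening P ≤ 0.2 are all inclusive.
- The oracle-equivalence check (tumor-only = matched calls under
  complete databases, diploid copy state, purity ≤ 0.8) simulates at
  depth 2000: the binomial SD of observed VAF at 0.35 is ≈ 0.011, so
  sampling noise cannot push an expected-somatic call over the 0.41
  boundary and the equality is deterministic rather than
  seed-dependent.
- The VAF-convergence property is checked at depth 10⁴ as mean
  |observed − expected| ≤ 0.01 with a 99th-percentile guard at 0.02
  (per-variant binomial SD at that depth is ≈ 0.005, so a per-variant
  bound of 0.01 would sit at 2 SD).
- Hazard-ratio recovery uses a survival-focused configuration (500
  samples, 3 somatic variants each, a small panel with ~40% of variant
  mass on the hazard pathway) so both strata stay populated and 100
  replicate fits run in seconds; coverage of the planted HR 3.3 by the
  Wald 95% CI is required in ≥ 90/100 replicates.
- The synthetic prevalence table in `somaticlens.examples` is a
  code-generated stand-in reproducing published cohort-level marginal
  counts only (per-gene altered-sample counts; 19/60 mutually exclusive
  Notch-pathway samples; 25/60 chromatin-remodeling samples);
  sample-gene assignments and coordinates are arbitrary. It exists so
  matrix/pathway machinery has a worked example with known expected
  output.

## Known limitations

- No transcript-level consequence annotation: `functional_class` is an
  input, produced upstream by an external annotator.
- No liftover, no BAM-level evidence gathering (strand counts and
  quality metrics are inputs), no copy-number segmentation, and no
  significance-of-mutated-genes testing.
- The tumor-only protocol's accuracy depends on how well the panel of
  normals matches the cohort's population; the simulator models this
  only through the scalar `db_completeness`.
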
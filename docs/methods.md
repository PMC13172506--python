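# Methods

## The pooled trio design

Conventional trio-WES sequences three exomes per family. The pooled design
sequences the proband individually and combines parental DNA into two pools
(all mothers in one, all fathers in the other, `n` parents each). The pools
are used for exactly one inference per proband variant — presence or
absence of the allele — so all individual-level genotype information about
the parents is deliberately given up. What survives is precisely what trio
analysis needs: de novo status, parental origin of inherited variants, and
in-trans phasing of candidate compound heterozygotes.

Three closed-form quantities govern the design (`pool_design`):

| quantity | formula | default | meaning |
|---|---|---|---|
| required pool depth | `n × 2 × r` | `r = 20` reads/allele | mean depth so each of the `2n` allele copies keeps `r` supporting reads |
| expected allelic balance | `1 / (2n)` | — | expected VAF of a heterozygous singleton carrier |
| per-trio cost reduction | `1 − (1 + 2m/n) / 3` | `m = 1.28` | pooled trio (1 proband exome + per-trio share of two pools) vs 3 exomes |

The cost model amortises each pool over the `n` trios it serves and treats
the pooled run as costing `m` standard-exome units (the elevated depth
makes a pool ~28% dearer than one exome at default settings). With `n = 8`
the reduction is exactly 56%. Depth is reported as an exact integer target;
rounding for lane planning is the caller's concern. The reduction is
bounded by 2/3 for any `m ≥ 1` because the proband exome is never pooled.

## Presence and inheritance (`classify`)

Proband calls first pass a QC gate: VAF ≥ 0.3 and DP ≥ 20, both inclusive.
Pool presence is VAF ≥ 1%, inclusive. The threshold sits well below the
singleton expectation (5% at `n = 10`, 6.25% at `n = 8`) and above the
read-error floor; it is the operating point at which pooled designs have
been validated, and its known failure mode — a true carrier
under-represented in the pool drifting below 1% and being miscalled
de novo — is reproduced, deliberately, by the classifier (a 1-in-180-reads
observation is *absent* by this rule).

The decision table over (maternal, paternal) presence is: absent/absent →
de novo; present in exactly one pool → that parent; present/present →
biparental. Three safeguards:

* a pool with zero usable depth at the site returns *insufficient*, never
  absent, and any decision needing that pool becomes *undetermined* — a
  variant is never de novo by lack of data;
* on chrX with a male proband and a hemizygous call, only the maternal
  pool is informative; the paternal observation is recorded but unused.
  This sex-aware rule is this package's design choice (the general
  decision table does not address it); chrX het calls in females (and, for
  pseudoautosomal robustness, in males, flagged) use the autosomal table;
  unknown sex on chrX is undetermined with an explanatory flag;
* chrY and mitochondrial contigs pass through undetermined.

When a raw pileup recount table is supplied, it is preferred over
caller-emitted pool VCF evidence: callers tuned for germline or somatic
calling can drop low-fraction carrier alleles entirely, while the decisive
quantity here is the raw alt read fraction at the site.

Compound-heterozygote phasing emits all maternal×paternal pairs within a
gene as in-trans; pairs containing a biparental member ("carrier in both
pools") or an undetermined member are reported unphaseable with the reason;
same-parent pairs are in-cis and omitted.

## SNV prioritization (`prioritize`)

Frequency gate, keyed on the gene's mode of inheritance: dominant and
X-linked context keeps gnomAD allele count < 5 (strict); recessive context
keeps allele frequency < 0.1%. ClinVar overrides take absolute precedence:
benign/likely-benign always drops, pathogenic/likely-pathogenic always
keeps. Genes of unknown MOI use the stricter dominant rule. Missing gnomAD
entries count as absent.

In-silico evidence per consequence class: missense uses CADD > 20,
REVEL > 0.5, AlphaMissense > 0.6, SIFT < 0.01; loss-of-function calls carry
their own evidence and need no predictors; synonymous/splice-region calls
use SpliceAI ≥ 0.6. The SpliceAI bound is inclusive (a variant at exactly
0.6 is the kind of call this workflow reports); the missense bounds are
strict. The boolean connective over the missense predictors is genuinely
underdetermined in practice, so it is configurable: `majority` of the
*available* predictors (default; missing scores leave the denominator),
`all_of`, or `any_of`. A missense call with no predictor at all is not
prioritized and is flagged `no_evidence` rather than passed vacuously.

Reporting criteria, evaluated in order with first match winning (one call
per variant; a hemizygous de novo in a known X-linked gene therefore
reports under the de novo criterion):

1. de novo variants in known AD/XL panel genes (`denovo_AD_XL`), or in
   candidate genes with Domino ≥ 0.6 (`denovo_candidate_dominant`);
2. hemizygous variants in XL genes (`hemizygous_XL`), regardless of Domino;
3. homozygous or in-trans compound-heterozygous variants in known AR panel
   genes (`biallelic_AR`) or candidate genes with Domino < 0.6
   (`biallelic_candidate_recessive`). Genes with no Domino score and
   unknown MOI fall to this branch for biallelic variants only, flagged
   `no_moi_evidence`, so a missing score cannot silently hide a biallelic
   candidate.

Candidate-gene evidence is summarised as flags with no composite cutoff:
Domino ≥ 0.6, pLI > 0.9, pNull < 0.1, LOEUF < 0.6, missense Z > 3.09,
gnomAD absent-or-singleton. The flag count ranks candidates; it never
gates them.

## CNV cascade (`cnv`)

Applied to solo-exome CNV calls only — pooling averages coverage across
individuals, so depth-based CNV detection in pools is not attempted. Rules
in order: panel-gene overlap; within-run recurrence (distinct individuals
with a same-type call at ≥ 50% reciprocal overlap; recurrent calls are
batch artifacts); single-caller calls dropped; the LOEUF rule; dosage
scores (deletions kept only when the haploinsufficiency percentile is
< 40, duplications when triplosensitivity < 40); full containment within a
same-type benign population event. Multi-gene calls aggregate gene scores
by minimum — the most dosage-sensitive overlapped gene governs, the
clinically conservative choice. Missing scores skip their rule rather than
drop the call. Each dropped call carries its first failing rule; because
every rule is a pure predicate of the call, the retained set is invariant
under rule reordering.

The LOEUF rule ships in three modes because its source formulation
("exclude LOEUF < 0.6, indicative of low functional impact") inverts
standard LOEUF semantics, under which *low* LOEUF marks a constrained,
high-impact gene. `literal` (default) implements that text verbatim and
the CLI prints a warning when it is active; `semantic` instead drops calls
whose overlapped genes are all unconstrained (min LOEUF ≥ 0.6); `off`
disables the rule.

Retained calls rank by caller support, then coding impact, then phenotype
relevance, with the smaller span first as a deterministic tie-break (stable
sort).

## Validation statistics (`stats`)

* **Sensitivity** `100 × TP/(TP+FN)`, two decimals, half-up rounding so
  recomputed percentages match printed ones digit for digit.
* **Detection breakdown** partitions pool VAFs into contiguous half-open
  bins `[1%, 1]`, `[0.55%, 1%)`, `(0, 0.55%)` and an exact-zero bin. The
  descriptive bands reported for such experiments have gaps; contiguous
  bins keep the partition total while reproducing the same counts on the
  same data. The top bin is "detected" at the presence threshold.
* **Allelic balance**: Wilcoxon signed-rank of observed singleton VAFs
  against `1/(2n)`. Zero differences are dropped; differences are rounded
  to 12 decimals before ranking so binary floating-point noise cannot break
  exact ties or sample symmetry; the exact null is used for ≤ 25 untied
  nonzero differences, otherwise the normal approximation with continuity
  correction. An all-zero difference vector returns p = 1 with a
  degenerate flag.
* **Yields**: per-phase percentages with phase-appropriate denominators
  (solo: all patients; trio: trio entrants) plus overall rows against all
  patients; every percentage is recomputed from raw counts.

## Simulator (`simulate`)

What it emulates: per-site pool depth Poisson around the design target
(switchable off for exact tests); a carrier of `k` alleles among `2n`
produces alt reads Binomial(depth, p) with
`p = Σ w_i d_i/2 · (1−e) + (1−Σ w_i d_i/2) · e`, where `d_i` are per-sample
allele doses, `e` the symmetric per-read error (default 0.001), and `w_i`
per-sample pool weights — equal when `overdispersion = 0`, otherwise a
symmetric Dirichlet draw with concentration `1/overdispersion`, the
simplest model of unequal pipetting; probands at ~100× with binomial
allele sampling. Scenario defaults make de novo events the largest class
(40%), with uniparental, biparental, compound-het, hemizygous-maternal and
homozygous classes filling the remainder, reflecting the mutational
spectrum of severe sporadic neurodevelopmental phenotypes. Pool sizes of
8–10 at depth `2n×20` are the validated operating range; cohort defaults
use 8, the best cost/quality balance, while validation-style runs use 10.

What it does not emulate: mapping artifacts, strand or context-specific
error, indel realignment effects, batch effects between capture kits, and
clustering of dropout within specific individuals beyond what the
overdispersion knob induces. Passing recovery tests therefore demonstrates
correctness of the decision logic under the stated read model, not
end-to-end accuracy on real sequencing.

All randomness flows from one `numpy.random.default_rng(seed)`; outputs are
byte-reproducible per platform. Annotation draws in `simulate_cohort` are
scenario-consistent (so planted variants are recoverable end to end), while
`simulate_annotated_variants` deliberately samples broadly — including
threshold-adjacent scores and missing fields — to stress every branch of
the cascade against independent oracles.

## Workflow routing (`workflow`)

Solo phase: QC- and frequency-passing variants; a ClinVar P/LP hit in a
panel gene diagnoses the patient and stops the workflow. Otherwise the
patient proceeds to the trio phase when pool data exist; patients without
parental samples are flagged `no_parental_samples` and remain unsolved.
The `max_unresolved_vus` knob (default 0) optionally routes patients with
few enough solo candidates to single-variant segregation instead of the
trio phase — the quantification of "few enough" is a site policy, not a
property of the method, hence a config value. Trio phase: inheritance is
attached from the pools, the full cascade runs, and the outcome is
`diagnosed_known_gene` if any known-tier call exists, else
`candidate_gene` if any call exists, else `unsolved`.

## Problem sizes and numerical choices

Simulation-based tests use 150–300 variants per replicate over 20–25 seeds
and cohorts up to 200 trios — large enough that the ≥ 99% recovery bounds
bind at the design depth, small enough to keep the suite fast. Percentages
round half-up at two decimals. Breakdown bin edges must be strictly
decreasing (overlap is rejected). Counts tables require a unique
(chrom, pos, ref, alt) key and reject negative or inconsistent counts with
the offending row number. Multi-allelic VCF records are decomposed to
biallelic calls and left-normalized against their own alleles (suffix then
prefix trimming; no reference genome needed). CLI outputs are written via a
`.partial` temp file and renamed on completion.

## Known limitations

* Parental mosaicism and carrier identity within a pool are undetectable by
  construction; a biparental presence call cannot distinguish both parents
  carrying from one parent plus an unrelated pool member (rare variants
  make the latter unlikely, not impossible).
* The 1% presence rule has a documented false-negative mode for
  under-represented carriers; the classifier reproduces it rather than
  papering over it.
* CNV inheritance cannot be assessed from pools; the CNV module filters
  solo calls only.
* Specificity of pooled detection is not estimated: false positives would
  be sequencing artifacts equally likely in individual WES, or carriers
  genuinely present in another pooled individual, which rare-variant
  assumptions make negligible.
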
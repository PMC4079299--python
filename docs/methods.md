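# Methods

## Problem setting

Short single-end sequencing tags (default 36 nt) from brain-style bulk
transcriptomes are classified to their source and, within the human
endogenous retrovirus (HERV) fraction, to one family and one proviral
region (*env*, *gag-pol*, LTR).  Because HERV families descend from
common ancestors and share LTR sequence, some tags are genuinely
unassignable to a single family; the pipeline's central design commitment
is that such tags are detected and quarantined rather than distributed.

## Tag classification

**Alignment model.**  Tags are scored by Hamming distance (substitutions
only, no gaps) against both the reference and its reverse complement, with
a mismatch cap (default 2).  Candidate placements come from exact seed
lookup: the tag is cut into `max(max_mismatches + 1, ceil(L / seed_length))`
disjoint chunks and the index-k prefix (k = 12) of each chunk is looked up
in a per-class k-mer index.  By pigeonhole, any placement within the
mismatch cap leaves at least one chunk mismatch-free, so the candidate set
is complete and the output equals an exhaustive all-position scan — this
equivalence is asserted against an independently implemented brute-force
scanner in the tests.  Chunks must be at least k long; for tags too short
to support `max_mismatches + 1` chunks of k nt the aligner refuses rather
than silently losing sensitivity.

**Triage hierarchy.**  Tiers are tried in the fixed order rRNA → host
transcriptome → nuclear genome → mtDNA → microbial → HERV; the first tier
with ≥ 1 hit decides the category, so a tag matching both rRNA and HERV is
rRNA by construction.  The nuclear tier captures
"nuclear-genome-but-not-transcriptome" tags as its own category.  Tags
hitting nothing are UNASSIGNED.

**Ambiguity rule.**  Within the HERV tier, with d_f the best distance per
family, the tag is assigned to argmin d_f only when unique and the
runner-up satisfies d₂ ≥ d₁ + margin (default 1: any tie is ambiguous —
the strictest operationalization of "unambiguous assignment").
HERV_AMBIGUOUS tags never enter family counts.  The region label is the
annotation containing the midpoint of the aligned interval, so a
boundary-straddling tag is counted exactly once, deterministically, and
the outcome does not depend on scan order.

## Quantification

Family frequency = 100 · count_f / Σ counts over unambiguously assigned
HERV tags (a flag includes ambiguous tags as their own category in the
denominator instead).  Region rate = tag count / total annotated nt of
that label summed over the family's references; frequencies rescale rates
to 100% within the family, so a short, densely covered LTR correctly
outranks a long *gag-pol* with equal raw counts.  Per-region (rather than
per-reference) lengths are used as the normalizer.  Group summaries are
medians.

**Mann-Whitney.**  For groups of at most 8 values each, the two-sided
p-value is computed by full enumeration of all C(n1+n2, n1) group
assignments, counting arrangements whose U is at least as far from
n₁n₂/2 as observed; ties are handled through midranks.  This convention
gives p = 2/20 = 0.1 for {1,2,3} vs {4,5,6} and p = 1 for identical
groups, and is validated against an independent pure-Python enumeration
and (on tie-free data) scipy's exact method.  Above the cutoff the
tie-corrected normal approximation with continuity correction is used.
Under the null the enumerated p-values are superuniform
(P(p ≤ α) ≤ α), which the tests verify empirically.

## Host-gene association screen

Pipeline: global normalization → detection filter → correlation screen →
(clinical mode) fold-change filter → overrepresentation test.

* **Global normalization** rescales each sample's column so all totals
  equal the mean of the original totals.  Using the mean (not a fixed
  constant) preserves overall scale and makes the operation idempotent.
* **Detection**: max count across samples ≥ 2 by default; a strict
  per-sample mode requires the threshold in every sample.
* **Correlation**: Pearson r of each gene against the per-sample HERV-K
  *env* abundance vector; the screen is on r² ≥ 0.5, so both induced and
  suppressed genes pass.  Zero-variance genes are flagged undefined and
  fail.
* **Fold change** is read symmetrically as |mean(case)/mean(control) − 1|
  ≥ 0.3, so 1.3× up and 0.7× down both pass; a zero control mean with
  positive case mean is infinite and passes.  ("0.3 fold change" admits
  several readings; the symmetric ratio-deviation one covers both induced
  and suppressed genes and is switchable.)
* **Enrichment** is a hypergeometric upper tail P[X ≥ k] per term over a
  user-supplied gene → term table, BH-adjusted across terms.  Running
  GO-style or pathway-style analyses is purely a choice of table.  The
  implementation is cross-checked against one-sided Fisher exact tests on
  the equivalent 2×2 tables.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated:

* **Tags**: fixed length 36 nt, single-end, i.i.d. substitution errors at
  rate 0.01, uniform start and strand.  No indels (the classifier scores
  Hamming distance and substitutions dominated short-tag platforms), no
  quality modeling, no paired ends, no PCR duplicates.
* **Class mixture** (defaults): rRNA 32.8%, host transcriptome 12.3%,
  nuclear-only 17.0%, mtDNA 8.0%, microbial 0.1%, HERV 15.0%, junk 14.8%.
  The rRNA/transcriptome/mtDNA/microbial proportions follow the observed
  triage of a brain transcriptome; part of the nuclear-only and unmapped
  mass is reallocated to HERV because at desk scale (10⁴–10⁵ tags/sample,
  not 10⁶–10⁷) a realistic sub-percent HERV fraction would leave family-
  and region-level statistics unestimable.  JUNK (i.i.d. random sequence)
  provides the true-negative unmapped class.
* **HERV families**: 6 families derived from one random ancestor by
  i.i.d. substitution at divergence 0.10, each 3 kb with LTR 500 /
  gag-pol 2000 / env 500 nt (1:4:1, so equal coverage gives distinct
  per-nt rates).  Family mixture defaults to a healthy-brain-style profile
  (H 57%, K 31%, minor W/R/E/FRD).  A 60-nt LTR motif is copied verbatim
  into every family at the same offset: tags drawn wholly inside it are
  exactly equidistant from all families and must be caught by the
  ambiguity rule — the planted hard case.
* **Cohort**: 4 HIV+ and 4 HIV− samples.  Per-sample env abundance is
  uniform around group means 3.0 (HIV+) and 0.5 (HIV−) with half-width
  0.3; the ~6-fold contrast makes the planted effect strong — module-gene
  expected r² ≈ 0.85 given the count noise below, the regime in which the
  r² ≥ 0.5 screen should operate near-perfectly.  A 20-gene module (of
  200) has negative-binomial counts with mean μ_g·(1 + effect·(env/ē − 1))
  (effect 1 ⇒ proportional to env; effect 0 ⇒ null), dispersion 0.1
  (Var = μ + 0.1μ²; dispersion 0 degenerates to rounded means for exact
  tests), baseline μ_g log-normal around 50.  One planted term covers the
  module plus 5 decoy genes, next to 50 random 15-gene decoy terms.  The
  per-sample FASTQ's HERV-K weight is tilted proportionally to env
  abundance, so the classifier-measured env signal tracks the generative
  one (observed Pearson r ≈ 0.99).
* **Determinism**: every stage draws from its own seed-derived stream
  (`SeedSequence([seed, stage, sample])`), so outputs are byte-identical
  across runs and — importantly — tag sequences can never replay the
  stream that generated the references (identical streams would plant
  spurious exact matches).

What passing tests on this generator do **not** show about real data:
real HERV loci are not a star phylogeny at uniform divergence; real reads
have indels, quality gradients and coverage biases; real env abundance is
not the sole driver of any host module; and real annotation terms overlap
heavily.  The generator's role is to make each algorithmic guarantee
falsifiable, not to imitate a particular biological dataset.

## Numerical and statistical choices

* Alignment ties are broken by (mismatches, ref_id, position, strand) for
  determinism; assignment tables are invariant to input record order up to
  row permutation.
* The error model interacts with the mismatch cap: a mapped tag with more
  than `max_mismatches` errors (P = 5.6·10⁻³ at 36 nt, rate 0.01) is
  unmappable by design and lands in UNASSIGNED.  Calibration checks of
  the class triage therefore centre their binomial bands on the adjusted
  expectations p·(1−ℓ) (mapped) and p_junk + ℓ·(1−p_junk) (unmapped),
  ℓ = P[Binom(36, 0.01) > 2], rather than on the raw mixture.
* Family frequencies are computed over unambiguous tags; because the
  motif sits at the same offset in every family, motif-tag exclusion is
  proportional across families and does not bias the recovered mixture.
* Zero-total samples make global normalization undefined and are rejected
  by name; zero HERV tags make family frequencies undefined and are
  rejected per sample.
* BH q-values are monotone in p-rank; q may be below p's naive bound only
  through the step-up minimum, never above 1.

## Problem sizes

Validation runs use 5 samples × 50,000 tags for mixture recovery, 30,000
tags for region uniformity, 50,000 for triage calibration, 500 tags for
brute-force aligner equivalence, and 40 null cohort replicates for FDR
calibration; the bundled demo uses 8 samples × 8,000 tags.  These sizes
put every recovery band well inside its sampling noise while keeping a
full validation run in the low minutes on one core.

## Known limitations

Single-end only; no gapped alignment (a single indel shifts the frame and
the tag is lost at the mismatch cap); family-level, not locus-level,
assignment; no GO DAG propagation or term-overlap handling in enrichment;
the fold-change and detection-filter readings are conventions (both have
strict-mode switches); the exact Mann-Whitney enumerates only up to 8 per
group (C(16,8) = 12,870 arrangements) before switching to the
approximation.
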
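# retroscope

Quantifying human endogenous retrovirus (HERV) expression from short
sequencing tags, and screening host genes whose expression tracks HERV-K
*env* abundance.

HERVs are retroviral sequences fixed in the human genome (~8% of it);
families such as HERV-K, -H, -W, -R, -E and -FRD are groups of related
proviral loci whose transcripts show up in bulk RNA sequencing as short
tags.  Profiling them is awkward because family members are highly similar
and their LTRs recur across families, so a read can be genuinely
unassignable to a single family.  `retroscope` implements a complete,
testable pipeline for this problem:

1. **Hierarchical tag triage.**  Each tag is aligned (exact-seed
   seed-and-extend, Hamming scoring, both strands) against labeled
   reference tiers in a fixed priority order — rRNA → host transcriptome →
   nuclear genome → mtDNA → microbial → HERV — and the first tier with a
   hit decides its class.
2. **Unambiguous family assignment.**  Within the HERV tier a tag is
   assigned to family *f* only if *f*'s best Hamming distance d₁ beats
   every other family's best d₂ by a margin, d₂ ≥ d₁ + m (default m = 1,
   so any tie ⇒ ambiguous).  Ambiguous tags are counted separately and
   never contribute to a family.
3. **Abundance quantification.**  Family tag frequency = a family's
   percent share of unambiguously assigned HERV tags.  Region frequency
   for *env* / *gag-pol* / LTR is length-normalized: count/Σ(annotated nt),
   rescaled to 100% within the family.  Group contrasts use the two-sided
   Mann-Whitney U test, exact by full enumeration for small groups.
4. **Host-gene association screen.**  Gene counts are globally normalized
   (all sample totals rescaled to their mean), filtered for detection
   (≥ 2 tags), correlated with per-sample HERV-K *env* abundance
   (screen on Pearson r² ≥ 0.5, both signs pass), optionally filtered on
   fold change |case/control − 1| ≥ 0.3, and the selected set is tested
   for term overrepresentation with a hypergeometric upper-tail test,
   p = P[X ≥ k], X ~ Hypergeom(N, K, n), under Benjamini–Hochberg control.

A bundled synthetic-data generator produces reference sets, tag FASTQs and
two-group cohorts with full ground truth (including a shared LTR motif
planted verbatim across families — tags from it are provably ambiguous),
so every stage is verifiable without any external download.

## Worked example

The numbered scripts under `analysis/` run the two study designs on
synthetic data (from the repository root):

```sh
python analysis/01_simulate.py     # cohort: reference, FASTQs, counts, truth
python analysis/02_classify.py     # tag triage per sample
python analysis/03_quantify.py     # family/region frequencies, group contrast
python analysis/04_associate.py    # host-gene screen + term enrichment
```

`03_quantify.py` prints, for the default seed:

```
median family frequencies (% of HERV tags):
  HERV-H      56.80
  HERV-K      30.89
  ...
group contrast (exact Mann-Whitney, two-sided):
  HERV-K     median HIV+  53.10  HIV-   8.65  p=0.0286
```

i.e. HERV-H dominates the overall profile with HERV-K second (the planted
healthy-brain-style mixture is recovered), and the HIV+ group's elevated
HERV-K share is detected at the smallest p the exact test can produce for
4 vs 4 samples.  `04_associate.py` then reports:

```
36/200 genes pass the screen (detection, r2 >= 0.5, |FC| >= 0.3)
planted-module sensitivity 1.00; background pass rate 0.089
top enriched term: TERM_PLANTED (k=21/25, q=1.86e-13)
```

showing the screen recovers the planted env-tracking gene module and
ranks its annotation term first.

The same pipeline is available as a CLI
(`retroscope simulate|classify|quantify|associate|demo`);
`retroscope demo --seed 0 --out demo/` runs everything end to end and
writes a truth-recovery report.

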
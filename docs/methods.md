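# Methods

## The validation design being modeled

A custom capture/amplicon panel (TS) is qualified against whole-exome
sequencing (WES) by running both assays on the same patients and comparing
them *inside the panel's target space*: coding exons of the panel genes with
25 bp of flank on each side, plus selected UTR/promoter regions. All
coordinates are BED-style 0-based half-open internally; conversion to VCF
1-based coordinates happens only in file readers and in target-membership
queries. Book-ended intervals merge, so the total target length always equals
the size of the flanked base-set union — this identity is what makes per-base
coverage fractions well defined.

## Coverage statistics

Per-sample mean depth is the sum of depths over all target bases divided by
the target length; bases missing from a depth track count as zero. The
"% of targets at 10x" statistic counts bases with depth **≥ 10**: the assay's
calling cutoff of 10x is read as "10x is acceptable", and the same boundary
convention is used for the variant depth filter so the two stages cannot
disagree about a 10x base.

Per-gene depth pools all samples of a platform: sum of depths over the gene's
target bases across samples ÷ (gene target length × n samples). The
low-coverage-exon statistic uses the (flanked exon, sample) pair as its unit
and reports the fraction of units with mean depth < 10, pooled over samples.

Platform comparisons use the paired Wilcoxon signed-rank test (two-sided).
Zero differences are dropped before ranking (the classical convention, rather
than Pratt's). For n ≤ 25 retained pairs the exact null distribution of the
positive-rank sum is computed by a tie-aware dynamic program over all 2^n
sign assignments (midranks are doubled to keep integer support), and the
two-sided p-value is 2·min(P(W ≤ w), P(W ≥ w)) capped at 1; above n = 25 a
normal approximation with continuity correction and tie-corrected variance is
used. The exact branch is cross-checked in the tests against brute-force
enumeration and against `scipy.stats.wilcoxon(method="exact")`, which is
deliberately *not* used as the implementation so the two routes stay
independent. The 2×2 exon comparison uses Pearson's chi-squared without
Yates correction (1 df), delegated to scipy.

## Variant normalization and matching

Variants are matched across platforms purely by the normalized key
(chrom, pos, ref, alt); rsIDs are metadata only. Multi-allelic records are
split before normalization. Left-normalization trims shared trailing bases
(extending left through the reference whenever an allele would empty), then
shared leading bases, yielding the unique left-most minimal representation;
SNVs are fixed points. An indel's target membership is judged by its
anchor (left-most) base after normalization — a single unambiguous rule.

Filters are order-independent set filters and commute: depth ≥ 10 (both
platforms), alt-read fraction ≥ 0.20 (exome pipeline only, where the
calling pipeline discards sub-20% calls), target restriction, and the
platform pipeline filter flag (e.g. VQSR tranche pass). Records failing the
pipeline flag are excluded from the comparison universe but are retained for
discrepancy-reason assignment.

## HFI triage

The cascade is ordered A (ClinVar P/LP) → B (MAF < 0.005) → C
(0.005 ≤ MAF ≤ 0.05 and CADD > 20); the first matching criterion wins and
the consequence gate (exonic non-synonymous / UTR / splice-site) is applied
first. Three conventions are forced by the validation cohort's own
classifications rather than left open:

- Benign/Likely-benign ClinVar labels do **not** veto criteria B/C ("VUS" is
  read operationally as "not ClinVar P/LP") — the cohort counts a Benign
  variant with CADD 29.7 and MAF 0.03 as high-impact via C;
- absent population frequency counts as MAF 0 (rare via B);
- boundaries: B is strict (< 0.005), C is the closed interval
  [0.005, 0.05], CADD strictly > 20.

All three thresholds are configurable (`maf_rare`, `maf_max`, `cadd_min`).
UTR/splice variants face the same B/C thresholds as exonic ones.

## Truth model and metrics

Variants called by both platforms are accepted as true without orthogonal
testing — the design Sanger-sequences only platform-unique calls. Unique
calls are true if confirmed, false if not confirmed, and "untested" (excluded
from metrics, with a warning) if unlabeled. Detection rate and specificity
follow the definitions in the README; both are computed over the HFI subset
by default (`metrics_over_all_variants` switches to the full universe).
Percentages are rounded half-up: one decimal for metrics, integers for
set-decomposition summaries. The comparison universe is deduplicated at the
key level across samples; a key counts as shared if both platforms ever call
it (in the simulator every variant lives in exactly one sample, so per-sample
and key-level readings coincide).

## Discrepancy reasons

For each platform-unique variant a fixed cascade assigns one reason:
(1) the non-calling platform's depth at the locus, in the sample(s) where the
variant was called, is below `reason_depth_threshold` (missing track = 0) →
insufficient coverage; (2) the non-calling platform emitted a record that
failed its pipeline filter → pipeline filter fail; (3) the variant is an
unconfirmed false positive with GC ≥ `gc_misalign` (default 70%) in a
±50 bp window, or a repeat flag → misalignment false positive; else
(4) unexplained. `reason_depth_threshold` defaults to the 10x calling cutoff,
but published discrepancy tables label 14–15x loci "insufficiently covered",
i.e. their operational bar sits above the calling cutoff; setting the
threshold to 20 reproduces such labels. The package does not guess a single
"right" value — it exposes the knob and defaults to the stated cutoff.
The GC threshold of 70% is the smallest rule consistent with the cohort's
two misalignment false positives (73.5% and 75% GC).

## Synthetic studies

The generator's defaults are the study conditions: 19 samples; per-sample
platform mean depths lognormal with mean/sd 300/190 (TS) and 102/7 (WES);
per-base depth negative-binomial around the sample mean (size 8 for the
noisier amplicon assay, 30 for capture); dropout exons — whole flanked exons
forced below 10x — chosen once per platform (capture/amplicon dropout is a
design property shared by samples) covering 3% (TS) and 13% (WES) of target
bases, preferentially in GC-rich-flagged exons for WES, which lands the
%≥10x statistics at ≈97 and ≈87. Because dropout bases average ≈4.5x, the
non-dropout base mean is inflated by rate·4.5/(1−rate) so the realized track
mean matches the configured platform mean.

The planted HFI decomposition defaults to the cohort's realized one
(89 shared true, 4 TS-only true, 3 WES-only true, 2 TS false positives,
0 WES false positives) plus a non-HFI background of 199/60/17
shared/TS-only/WES-only common synonymous variants, reproducing the
374-variant universe. Platform-unique true variants are hidden from the other
platform by the intended mechanism — depth forced below 10x at the locus, or
(for half the TS-only variants by default) an emitted WES record with a
failing filter flag — and false positives receive misalignment-compatible
annotations (GC ≥ 70 or repeat flag) and "not confirmed" labels; every other
unique variant is labeled confirmed. Annotation values are drawn from
criterion-conditional ranges (e.g. criterion C: MAF uniform on
[0.005, 0.045], CADD uniform on (20, 40]) so every verdict is decidable by
construction. A single `numpy.random.Generator`, seeded once, drives every
stage; identical config + seed gives byte-identical outputs.

What the simulation does *not* emulate: read-level errors, alignment,
genotypes/zygosity, linkage between variants, real GC landscapes, or
annotation noise. Passing the planted-recovery tests therefore demonstrates
that the *analysis* pipeline is exact and internally consistent, not that
the upstream callers would behave as modeled on real reads. The raw cohort
counts (374/288/66/20), the per-gene depth p = 3.7e-15 and the exon-fraction
p = 2.1e-06 depend on the deposited reads and are emulation targets only.

## Problem sizes and numerical choices

Tests run the default 82-gene scenario (~150k target bases × 38 tracks) in a
few seconds; the randomized recovery suite uses 3–8-gene panels with 2–4
samples per config, which is ample to exercise every code path while keeping
the suite fast. Depth tracks are stored as per-chromosome sorted
position/depth arrays with binary-search lookup; absent positions read as
depth 0 everywhere. Rounding for reports uses decimal half-up (not banker's)
to match conventional printed tables.

## Known limitations

- The real 82-gene region list is not bundled; panels are user-supplied, with
  a six-gene toy panel (one per disease category) and the simulator standing
  in. Bundled cohort reference data cover the printed summary tables only.
- Zygosity and genotype concordance are out of scope (the validation design
  compares site/allele detection only).
- VCF ingestion expects site-level INFO annotations (key map configurable);
  FORMAT/sample-level depth is not consulted.
- Whether the cohort's per-gene signed-rank test paired per-gene pooled means
  (as implemented) or per-gene-per-sample values is not determinable from the
  printed material; the pooled reading is documented and used throughout.
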
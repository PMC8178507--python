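# Methods

`piratrue` implements a contamination-aware detection cascade for small RNAs
annotated in piRNA databases, followed by the association analyses such a
study runs downstream: differential expression across clinicopathological
groups and quartile-stratified survival. Because real cohort sequencing data
of this kind are typically not shareable, the package ships a synthetic-data
generator with machine-readable truth, and every claim the test suite makes
is a claim about planted truth recovery or about agreement with an
independent oracle.

## The detection cascade

**Placement.** Database entries (~20–32 nt, RNA alphabet, U→T normalized on
ingest) are anchored to the genome by exact-match substring search on both
strands. Entries with zero hits or more than `max_hits` (default 10) genomic
hits are dropped and reported; for retained entries exactly one location is
kept. Exact matching replaces heuristic local alignment deliberately: at
mature small-RNA length it is the stricter and fully deterministic choice,
and it makes the brute-force scan an exact oracle. When an entry hits several
locations, the retained one is the first under (chromosome lexicographic,
start ascending, `+` before `-`); this tie-break is a declared convention —
nothing in the data prefers one location — chosen so that reruns and
reimplementations agree. Overlapping occurrences each count as a hit.

**Blacklist filtering.** The blacklist is the strand-agnostic merged union of
the entire mitochondrial contig, all annotated sncRNA / tRNA / miRNA
primary-transcript intervals, and repeats strictly longer than 24 bp (a 24-bp
repeat stays out; a 25-bp one goes in). An alignment is removed iff it
overlaps the blacklist by at least one base, the most conservative reading of
"remove alignments to"; strandedness of the original filtering is unknown, so
strand-agnostic is the documented contract. Reads surviving this step cannot
be trivial fragments of the annotated ncRNA universe.

**Counting.** Only primary alignments with MAPQ ≥ 1 are counted. A read is
assigned to an entry when their overlap reaches
`max(min_overlap_nt, ceil(frac_overlap · read_length))` reference bases
(defaults 15 nt and 0.80). `ceil` implements "at least 80%" as a lower bound;
the computation rounds the product to 9 decimals first so that binary float
artifacts (0.80 · 20 = 16.000000000000004) cannot shift the threshold. A read
qualifying for several entries is counted once, to the largest overlap, ties
broken by (chromosome, start, accession). Overlap is measured on aligned
reference bases; the denominator is the full read length. Counting is
strand-agnostic by default, matching common counting-tool defaults.

**Presence tiers.** An entry is *present* with ≥ `min_reads` (2) counted
reads in ≥ `min_samples` (10) samples; otherwise *secondary* with ≥ 1 read in
≥ 25 samples; otherwise *absent*.

**Stack and sequence evidence.** Visual genome-browser inspection of read
stacks is formalized as two scores: *uniformity* (fraction of reads whose 5′
end lies within ± 2 nt of the modal 5′ position) and *containment* (mean
fraction of read bases inside the entry interval). Default nomination
thresholds are uniformity ≥ 0.5 and containment ≥ 0.8; these
operationalize a criterion that was inherently visual, are configurable, and
carry no claim of equivalence to any particular human judgement. The 5′
nucleotide is reported in RNA alphabet (primary piRNAs prefer 5′ U), and full
reverse-complement matches of each entry against a target set are found by
exact scan.

## Differential expression

Size factors are median-of-ratios (reference: per-entry geometric mean over
samples, computed on entries positive in every sample), rescaled to geometric
mean 1; normalized values are `log2(count / factor + 1)`. This is a simple
monotone stand-in for a variance-stabilizing transform: the only property the
downstream quartile assignment uses is the per-sample ordering, which any
strictly increasing transform preserves. It is *not* numerically comparable
to VST output.

Per entry, a negative-binomial log-linear model is fitted with offset
`log(size factor)` and terms intercept + group (+ one categorical adjustment
covariate when requested), using IRLS at a fixed dispersion. Dispersion is
method-of-moments, pooled over design cells with weights (n−1) and floored at
1e−8 — deliberately simple and per-entry, without empirical-Bayes sharing
across entries; with ≥ ~20 samples per group this is adequately calibrated
(the acceptance suite checks type-I error at n = 50/50). The Wald statistic
is log2FC / SE against a standard normal; BH controls FDR over the entries
actually tested (all-zero entries are excluded from the family; in pipeline
runs the family is the presence-filtered set). Fold-change shrinkage is a
normal-prior posterior mean, `lfc · τ² / (τ² + se²)`, with τ estimated as the
SD of raw log2FCs when not supplied: same qualitative contract as heavier
shrinkage estimators (noisy, low-information entries shrink most; shrinkage
never flips sign or increases magnitude), not the same numbers.

The ΔΔCq check converts qPCR Cq triplicate means into relative expression
`2^(−ΔΔCq)` against a control assay and a reference sample, and reports the
Pearson correlation between log2 relative expression and the entry's
normalized sequencing values over shared samples (≥ 3 required).

## Survival analysis

Endpoints from diagnosis: RFS (recurrence; otherwise censored at the earliest
of death, last follow-up, global censor date), BCSS (death from the disease;
other-cause deaths censored at death), OS (any death). Clinical tables may
carry a per-subject `last_followup_date`; when present it bounds censoring,
which is how individually censored cohorts are represented. Eligibility is
invasive, local disease (no in-situ, no metastasis at diagnosis). Treatment
subsets (RT-treated, tamoxifen-treated, RT-only, adjuvant-CT-treated,
surgery-only) come with covariate plans: base clinical covariates (grade,
histology, size, ER, PR, HER2, age), ER dropped under an ER restriction, RT
added for the tamoxifen and CT subsets, CT and ET added for the RT subset.

For a given RNA, samples are split into expression quartiles by rank (Q1
lowest; sizes ⌈n/4⌉ first, so n = 10 gives 3/3/2/2; value ties broken by
sample id for determinism; ≥ 8 samples required). Cox proportional-hazards
models compare Q2/Q3/Q4 against Q1 with Breslow tie handling (the lifelines
default and the default of the common R fitter family). The overall p-value
is the likelihood-ratio test of the whole quartile block. The multivariate
procedure forces the quartile block into the model — published quartile HRs
appear in every final model, implying the RNA term was never dropped — and
adds covariates forward-greedily by AIC (= −2·log partial likelihood + 2k),
stopping when no addition lowers AIC; forward-only, no backward steps.
Missing covariates are handled by complete-case analysis within each model
family. Non-convergence or separation yields a flagged fit (`converged =
False`, |coef| > 10 heuristic), never a crash. BH adjusts overall p-values
within each (endpoint × subset) family. Kaplan–Meier curves are exported as
step functions with overall and pairwise-vs-Q1 log-rank p-values; plot
rendering is out of scope.

## The synthetic-data generator

`SimConfig` defaults define the study conditions: 3 × 60 kb chromosomes plus
a 3 kb mitochondrial contig; 12 genuine loci (unique 26–30 nt sequences
planted into the genome, 5′ U with probability 0.9, a quarter on the minus
strand), of which 3 are simulated at mean 0.15 counts/sample to sit clearly
below the presence criterion; 18 fragment decoys registered as database
entries but actually substrings of tRNA/snoRNA/miRNA/long-repeat annotations,
plus 2 mitochondrial decoys; one 12-copy entry exercising the placement cap
and one entry absent from the genome; 60 samples; read lengths uniform
20–32 nt; 5′-start jitter SD 1 nt; NB dispersion 0.3 with genuine mean 30 and
decoy mean 15; grade probabilities (0.25, 0.40, 0.35) and P(ER+) = 0.7;
planted log2 fold-changes 1.3 (grade III, 3 loci) and 1.0 (ER−, 2 loci),
matching the effect scale such studies report; quartile log-hazards
(0, 0.3, 0.2, ln 5) on the target entry — a Q4-vs-Q1 hazard ratio of 5, the
magnitude the survival analysis is meant to detect; exponential baseline
(rate 1/2500 per day), independent other-cause mortality, ~30% independent
uniform censoring (the censor-time upper bound is calibrated by root-finding
against the drawn survival times), 15-year follow-up. Repeat annotations
straddle the 24-bp bound (20, 24, 25, 30, 80, 200 bp) so the boundary is
exercised end to end.

This scale keeps a full pipeline run under ~5 s while leaving wide margins:
a mean-30 locus meets "2 reads in 10 samples" in essentially every sample,
a mean-0.15 locus in essentially none, so the truth-vs-pipeline comparison
is not fragile to the handful of long reads that miss the 80% overlap bound
at a short locus. A cohort-scale configuration (hundreds of samples, tens of
thousands of entries) is a config choice, not a default.

What the generator does **not** emulate: sequencing errors and quality
scores, paired-end structure, multi-mapping ambiguity beyond planted
multicopy sequences, GC/length biases, library-size variation (all samples
are drawn at the same depth scale, so size factors hover near 1), RNA
integrity effects, correlated censoring, or time-varying hazards. Passing
tests therefore demonstrate correctness of the cascade's logic and the
statistical calibration of its estimators under the stated model — not
robustness to every artifact of real small RNA-seq.

All randomness flows from the mandatory seed through named `numpy`
Generator streams; identical configs give byte-identical FASTA/GFF3/SAM/TSV
outputs and run reports.

## Numerical and design notes

- Reverse-complement-palindromic sequences count once per genomic window
  (forward), not twice; irrelevant for random sequences, documented for
  determinism.
- Placement report statuses: `placed`, `no_hit`, `too_many_hits`, plus
  `invalid_alphabet` for per-entry alphabet rejections.
- The null partial log-likelihood used in likelihood-ratio tests is computed
  directly (each event contributes −log of its risk-set size under Breslow
  ties) rather than by fitting an empty model.
- BH is implemented directly (step-up with monotonicity enforcement, missing
  values propagated and excluded from the family) and is cross-checked
  against `statsmodels` in the test suite.
- Degenerate inputs error early and by name: empty genome, all-zero sample,
  presence thresholds exceeding the sample count, censoring fraction 1.0,
  quartiles on < 8 samples, confounded adjustment covariates.

## Problem sizes used by the test and acceptance suites

Oracle-equivalence checks run on ≥ 20 random fixtures of up to a few
thousand reads and ≤ 50 entries against quadratic/exhaustive references;
placement oracles on ~100 kb genomes. Statistical calibration uses 500
entries at n = 50 vs 50 (differential expression) and 200 replicates at
n = 400 subjects (Cox hazard-ratio recovery and CI coverage), sizes at which
the binomial/KS acceptance bands quoted in the tests are meaningful.
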
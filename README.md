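# piratrue

Contamination-aware detection of small RNAs annotated in piRNA databases
from bulk small RNA-seq, with the downstream association analyses such
studies run: differential expression across clinicopathological groups and
quartile-stratified survival.

## The problem

piRNA databases are contaminated: many entries are fragments of other
non-coding RNAs (tRNAs, snoRNAs, miRNA precursors, repeats). Reads that
support such entries come from the host ncRNA, not from an independent
piRNA, so naive counting against a piRNA annotation wildly overstates piRNA
prevalence in somatic tissue. `piratrue` implements the defensive cascade:

1. **Placement** — anchor each database sequence to one genomic location by
   exact two-strand search, discarding entries with more than 10 genomic
   hits.
2. **Blacklist filtering** — remove every alignment touching the
   mitochondrial contig, annotated sncRNAs/tRNAs/miRNA primary transcripts,
   or repeats longer than 24 bp.
3. **Counting** — count primary alignments (MAPQ ≥ 1) whose overlap with an
   entry reaches max(15 nt, 80% of the read length); one count per read, to
   the largest overlap.
4. **Presence tiers** — *present*: ≥ 2 counted reads in ≥ 10 samples;
   *secondary*: ≥ 1 read in ≥ 25 samples.
5. **Evidence** — read-stack uniformity and containment at the locus, 5′
   uridine, and full reverse-complement matches.
6. **Associations** — per-entry negative-binomial Wald tests
   (log2 fold-change, BH FDR, normal-prior shrinkage) for group contrasts,
   and Cox proportional-hazards models comparing expression quartiles
   Q2/Q3/Q4 against Q1 (hazard ratios with 95% CIs, forward-stepwise AIC
   covariate selection, treatment-defined patient subsets, Kaplan–Meier
   export) for RFS/BCSS/OS endpoints.

Cohort data of this kind are typically not public, so the package includes a
seeded synthetic-data generator (`piratrue.simulate`) that plants genuine
loci, fragment decoys, grade/ER-linked fold changes and quartile-dependent
hazards with known truth; the analysis scripts and the test suite run the
whole cascade against that truth. See `docs/methods.md` for the model
details and assumptions.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic dataset (seed 1), writing tables under `results/analysis/`:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_build_transcriptome.py
python analysis/03_filter_count_presence.py
python analysis/04_stack_and_sequence_evidence.py
python analysis/05_differential_expression.py
python analysis/06_survival_analysis.py
```

Step 3 prints the detection funnel and the truth comparison:

```
read funnel: 38,881 aligned -> 20,973 after blacklist -> 20,195 counted
tier
absent     23
present     9
present == expected genuine loci: True
fragment decoys called present: 0
```

Of 34 database entries, 32 place uniquely (one exceeds the 10-hit cap, one
has no genomic hit). All 20 placed fragment decoys lose every read to the
blacklist and end *absent*; the 9 genuine loci simulated above the abundance
criterion are exactly the *present* set. Step 5 recovers the planted
fold-changes, e.g. for the grade III vs grade I contrast:

```
gradeIII_vs_gradeI (n=23 vs 14): 2 / 9 entries at padj < 0.05
  DB0002: log2FC +1.22 (shrunk +0.91, planted +1.30), padj 3.87e-03
  DB0003: log2FC +1.11 (shrunk +0.93, planted +1.30), padj 6.34e-04
```

and step 6 fits the quartile Cox models (planted Q4-vs-Q1 hazard ratio 5 on
the target entry); in the all-invasive-local subset (n = 49, 34 events) the
multivariate model estimates

```
Q4 HR (CI 95%) = 4.86 (1.57-15.00), p = 0.0060, p_overall = 0.044
```

Small treatment subsets behave as small subsets do: wide intervals, and a
flagged (`unstable`) fit where the partial likelihood separates.

The same cascade is scriptable over files via the CLI
(`piratrue simulate | build-transcriptome | filter | quantify | presence |
de | survival | run`), e.g.

```sh
piratrue run --seed 1 --out-dir results/run
```

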
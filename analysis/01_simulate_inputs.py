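#!/usr/bin/env python
"""Step 1 — generate the synthetic study inputs.

Writes a toy multi-contig genome with planted small-RNA loci, ncRNA/repeat
annotation layers, a deliberately contaminated database FASTA (genuine loci +
ncRNA-fragment decoys + placement-cap exercisers), per-sample single-end SAM
alignments, per-sample conditions (grade, ER status), and the truth file.
"""

from pathlib import Path

from piratrue import simulate as sim

SEED = 1
OUT = Path("results/analysis/sim")


def main() -> None:
    cfg = sim.SimConfig(seed=SEED)
    ref = sim.simulate_reference(cfg, OUT)
    per_sample, conditions, truth = sim.simulate_alignments(cfg, ref, OUT)
    conditions.to_csv(OUT / "sample_metadata.tsv", sep="\t")

    n_reads = sum(len(r) for r in per_sample.values())
    classes = {}
    for info in truth["entries"].values():
        classes[info["class"]] = classes.get(info["class"], 0) + 1
    print(f"genome: {len(ref.genome)} contigs, "
          f"{sum(len(s) for s in ref.genome.values()):,} bp")
    print(f"database: {len(ref.db)} entries by class {classes}")
    print(f"alignments: {n_reads:,} records across {cfg.n_samples} samples -> {OUT}")
    print(f"expected present (>=2 reads in >=10 samples): "
          f"{sum(truth['expected_present'].values())} genuine loci")


if __name__ == "__main__":
    main()
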
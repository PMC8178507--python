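import numpy as np
import pytest

from piratrue import simulate as sim
from piratrue.pipeline import RunConfig, run_pipeline
from piratrue.types import AlignmentRecord, GenomicInterval

SEED = 7


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale synthetic reference + alignments with truth."""
    cfg = sim.SimConfig(seed=SEED)
    ref = sim.simulate_reference(cfg)
    per_sample, conditions, truth = sim.simulate_alignments(cfg, ref)
    return cfg, ref, per_sample, conditions, truth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic dataset."""
    out = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(RunConfig(seed=SEED), out)
    return out, report


def random_alignments(rng, n, chroms, samples, max_pos=1000, len_range=(15, 40)):
    """Random alignment records for oracle comparisons."""
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        L = int(rng.integers(*len_range))
        start = int(rng.integers(0, max_pos - L))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(
            AlignmentRecord(
                read_id=f"r{i}",
                sample_id=samples[rng.integers(len(samples))],
                interval=GenomicInterval(chrom, start, start + L, strand),
                is_primary=bool(rng.random() < 0.9),
                mapq=int(rng.integers(0, 40)),
                read_length=L,
            )
        )
    return out
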
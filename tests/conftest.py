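import numpy as np
import pytest

from bisdrip.io import ReadRecord
from bisdrip.simulate import SimConfig, simulate_dataset


def make_read(
    read_id="r1",
    chrom="chr1",
    start=100,
    end=200,
    strand="+",
    converted=(),
    unconverted=(),
    sample_id="S1",
    condition="control",
):
    return ReadRecord(
        read_id=read_id,
        chrom=chrom,
        start=start,
        end=end,
        conversion_strand=strand,
        converted_positions=tuple(converted),
        unconverted_positions=tuple(unconverted),
        sample_id=sample_id,
        condition=condition,
    )


def random_reads(rng, n_reads, n_cytosines=10, p=0.01, chrom="chr1",
                 read_length=100, genome_length=100_000, sample_id="S1"):
    """Background-only reads with a fixed per-read cytosine count."""
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, genome_length - read_length))
        strand = "+" if rng.random() < 0.5 else "-"
        positions = np.sort(
            rng.choice(np.arange(start, start + read_length), size=n_cytosines,
                       replace=False)
        )
        converted_mask = rng.random(n_cytosines) < p
        reads.append(
            make_read(
                read_id=f"r{i}", chrom=chrom, start=start,
                end=start + read_length, strand=strand,
                converted=[int(x) for x in positions[converted_mask]],
                unconverted=[int(x) for x in positions[~converted_mask]],
                sample_id=sample_id,
            )
        )
    return reads


@pytest.fixture(scope="session")
def toy_dataset():
    """The default synthetic experiment, shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A faster, smaller synthetic experiment."""
    return simulate_dataset(
        SimConfig(seed=7, n_genes=6, n_rloop_genes=2, reads_per_promoter=200,
                  chrom_length=400_000, gene_spacing=30_000)
    )
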
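"""Closed-loop synthetic datasets with known R-loop ground truth.

The generator emits everything the pipeline consumes — per-read conversion
tables per sample and condition, a GTF of gene models, a candidate TSS BED,
nascent-transcription (GRO-seq-style) reads, and a truth table — from a toy
genome whose R-loop content is chosen up front.

The data model mirrors the assay's physics at the statistical level: every
cytosine on a read's assessed strand converts independently at a low
background rate (DNA breathing), except that in the control condition
cytosines lying on the displaced strand of an implanted R-loop convert at a
high rate.  A sense-strand R-loop occupies the TSS-to-first-junction interval
and displaces the coding strand; an antisense-strand R-loop sits upstream of
the TSS and displaces the template strand.  Transcription-inhibited
(triptolide-analog) samples convert at background everywhere, and a
nuclease-treated (RNase-H-analog) condition is statistically identical to it.
Promoter activity scales the number of nascent-transcription reads per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import TSSRecord
from .io import (
    ReadRecord,
    TranscriptModel,
    write_bed,
    write_conversion_table,
    write_gtf,
)

#: genomic offset of minus-strand cytosines relative to plus-strand ones
MINUS_STRAND_PHASE = 2


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic experiment.

    Defaults model a modest but clearly powered desk-scale experiment: a 1 Mb
    single-chromosome genome, 20 genes, a 1% stochastic background conversion
    rate against an 80% in-loop rate, 100 nt reads at 100 reads per promoter
    window and sample, cytosines every 5 bp per strand, and two replicates
    per condition.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 1_000_000
    n_genes: int = 20
    gene_spacing: int = 40_000
    first_exon_length_range: tuple[int, int] = (150, 400)
    gene_length: int = 5_000
    fraction_intronless: float = 0.2
    n_rloop_genes: int = 4
    antisense_rloop_genes: int = 0
    intronless_rloop_length: int = 500
    antisense_rloop_length: int = 500
    p_bg: float = 0.01
    p_loop: float = 0.8
    read_length: int = 100
    reads_per_promoter: int = 100
    cytosine_spacing: int = 5
    # replicate structure of the emulated study: 13 control samples and 2
    # transcription-inhibited samples; condition-level values are
    # across-sample means
    n_control: int = 13
    n_triptolide: int = 2
    groseq_read_length: int = 50
    activity_scale: float = 50.0
    rloop_activity_boost: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bg < self.p_loop <= 1.0:
            raise ValueError("need 0 <= p_bg < p_loop <= 1")
        if self.n_rloop_genes + self.antisense_rloop_genes > self.n_genes:
            raise ValueError("more implanted genes than genes")
        if self.n_genes * self.gene_spacing > self.chrom_length * self.n_chromosomes:
            raise ValueError("genome too small for the requested gene count")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one implanted R-loop."""

    gene_id: str
    chrom: str
    gene_strand: str
    displaced_strand: str
    start: int  # genomic, 0-based half-open
    end: int
    offset_start: int  # gene-oriented offsets relative to the TSS
    offset_end: int
    kind: str = "sense"  # sense | antisense
    present_in: tuple[str, ...] = ("control",)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    first_exon_length: int | None  # None for intronless genes
    length: int
    activity: float

    @property
    def intronless(self) -> bool:
        return self.first_exon_length is None

    def junction(self) -> int | None:
        """Genomic coordinate of the first exon-intron boundary."""
        if self.first_exon_length is None:
            return None
        if self.strand == "+":
            return self.tss + self.first_exon_length
        return self.tss - self.first_exon_length

    def transcript(self) -> TranscriptModel:
        if self.strand == "+":
            start, end = self.tss, self.tss + self.length
            if self.intronless:
                exons = [(start, end)]
            else:
                intron_end = min(start + self.first_exon_length + 1500, end - 200)
                exons = [(start, start + self.first_exon_length), (intron_end, end)]
        else:
            start, end = self.tss - self.length + 1, self.tss + 1
            if self.intronless:
                exons = [(start, end)]
            else:
                intron_start = max(end - self.first_exon_length - 1500, start + 200)
                exons = [(start, intron_start), (end - self.first_exon_length, end)]
        return TranscriptModel(
            transcript_id=f"{self.gene_id}.t1", gene_id=self.gene_id,
            chrom=self.chrom, strand=self.strand, exons=exons,
        )


@dataclass
class SimulatedDataset:
    config: SimConfig
    genes: list[GeneModel]
    truth: list[TruthRecord]
    samples: dict[str, tuple[str, list[ReadRecord]]]  # sample_id -> (condition, reads)
    groseq: pd.DataFrame
    tss_candidates: list[TSSRecord] = field(default_factory=list)

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [g.transcript() for g in self.genes]

    def reads_by_condition(self, condition: str) -> list[list[ReadRecord]]:
        return [reads for _, (cond, reads) in sorted(self.samples.items())
                if cond == condition]

    def truth_genes(self, kind: str = "sense") -> set[str]:
        return {t.gene_id for t in self.truth if t.kind == kind}

    def write(self, outdir: str | Path) -> None:
        """Emit the dataset in the formats the pipeline consumes, plus truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.transcripts, outdir / "genes.gtf")
        tss_bed = pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "start": [g.tss for g in self.genes],
                "end": [g.tss + 1 for g in self.genes],
                "name": [g.gene_id for g in self.genes],
                "score": [g.activity for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )
        write_bed(tss_bed, outdir / "tss_candidates.bed")
        write_bed(self.groseq, outdir / "groseq_reads.bed")
        for sample_id, (_cond, reads) in sorted(self.samples.items()):
            write_conversion_table(reads, outdir / f"{sample_id}.conversions.tsv")
        pd.DataFrame(
            [
                {
                    "gene_id": t.gene_id, "chrom": t.chrom,
                    "gene_strand": t.gene_strand,
                    "displaced_strand": t.displaced_strand,
                    "start": t.start, "end": t.end,
                    "offset_start": t.offset_start, "offset_end": t.offset_end,
                    "kind": t.kind, "present_in": ",".join(t.present_in),
                }
                for t in self.truth
            ]
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def cytosine_positions(start: int, end: int, strand: str, spacing: int
                       ) -> np.ndarray:
    """Deterministic cytosine lattice on one strand over [start, end)."""
    phase = 0 if strand == "+" else MINUS_STRAND_PHASE
    first = start + (-(start - phase)) % spacing
    return np.arange(first, end, spacing)


def _build_genes(config: SimConfig, rng: np.random.Generator
                 ) -> tuple[list[GeneModel], list[int]]:
    genes = []
    lo, hi = config.first_exon_length_range
    n_intronless = int(round(config.fraction_intronless * config.n_genes))
    intronless_ids = set(
        rng.choice(config.n_genes, size=n_intronless, replace=False).tolist()
    )
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    activities = np.sort(
        rng.lognormal(mean=np.log(config.activity_scale), sigma=0.5,
                      size=config.n_genes)
    )[::-1]
    for i in range(config.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        anchor = 10_000 + slot * config.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        tss = anchor if strand == "+" else anchor + config.gene_length
        first_exon = (
            None if i in intronless_ids else int(rng.integers(lo, hi + 1))
        )
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:03d}", chrom=chrom, strand=strand, tss=tss,
                first_exon_length=first_exon, length=config.gene_length,
                activity=float("nan"),
            )
        )
    # Transcription-dependent R-loops require transcription, so implants go
    # to the most active promoters: hand the largest activities to the
    # implanted genes (with a boost that keeps them clearly above the
    # activity-percentile cutoff despite read-sampling noise), the rest at
    # random.
    implant_order = rng.permutation(config.n_genes)
    n_implant = config.n_rloop_genes + config.antisense_rloop_genes
    implanted = [int(i) for i in implant_order[:n_implant]]
    others = [int(i) for i in implant_order[n_implant:]]
    for rank, gi in enumerate(implanted + others):
        boost = config.rloop_activity_boost if rank < n_implant else 1.0
        genes[gi].activity = float(activities[rank]) * boost
    return genes, implanted


def _implant_truth(config: SimConfig, genes: list[GeneModel],
                   implanted: list[int]) -> list[TruthRecord]:
    truth = []
    for j, gi in enumerate(implanted):
        gene = genes[gi]
        antisense = j >= config.n_rloop_genes
        if antisense:
            a, b = -config.antisense_rloop_length, 0
            displaced = "-" if gene.strand == "+" else "+"
        else:
            a = 0
            b = (gene.first_exon_length if gene.first_exon_length is not None
                 else config.intronless_rloop_length)
            displaced = gene.strand
        if gene.strand == "+":
            start, end = gene.tss + a, gene.tss + b + 1
        else:
            start, end = gene.tss - b, gene.tss - a + 1
        truth.append(
            TruthRecord(
                gene_id=gene.gene_id, chrom=gene.chrom, gene_strand=gene.strand,
                displaced_strand=displaced, start=start, end=end,
                offset_start=a, offset_end=b,
                kind="antisense" if antisense else "sense",
            )
        )
    return truth


def _sample_reads(
    config: SimConfig,
    genes: list[GeneModel],
    truth: list[TruthRecord],
    sample_id: str,
    condition: str,
    rng: np.random.Generator,
) -> list[ReadRecord]:
    hot: dict[tuple[str, str], list[tuple[int, int]]] = {}
    if condition == "control":
        for t in truth:
            hot.setdefault((t.chrom, t.displaced_strand), []).append((t.start, t.end))
    reads = []
    counter = 0
    for gene in genes:
        window_start = max(0, gene.tss - 1000)
        window_end = gene.tss + 1000 + 1
        max_start = window_end - config.read_length
        starts = rng.integers(window_start, max_start + 1,
                              size=config.reads_per_promoter)
        strands = np.where(rng.random(config.reads_per_promoter) < 0.5, "+", "-")
        for start, strand in zip(starts, strands):
            start = int(start)
            end = start + config.read_length
            cyt = cytosine_positions(start, end, strand, config.cytosine_spacing)
            rate = np.full(len(cyt), config.p_bg)
            for lo, hi_ in hot.get((gene.chrom, strand), []):
                rate[(cyt >= lo) & (cyt < hi_)] = config.p_loop
            converted_mask = rng.random(len(cyt)) < rate
            counter += 1
            reads.append(
                ReadRecord(
                    read_id=f"{sample_id}:{gene.gene_id}:{counter}",
                    chrom=gene.chrom, start=start, end=end,
                    conversion_strand=str(strand),
                    converted_positions=tuple(int(p) for p in cyt[converted_mask]),
                    unconverted_positions=tuple(int(p) for p in cyt[~converted_mask]),
                    sample_id=sample_id, condition=condition,
                )
            )
    return reads


def _groseq_reads(config: SimConfig, genes: list[GeneModel],
                  rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for gene in genes:
        n_reads = max(1, int(rng.poisson(gene.activity)))
        if gene.strand == "+":
            lo, hi = gene.tss, gene.tss + 1000 - config.groseq_read_length + 1
        else:
            lo, hi = gene.tss - 1000, gene.tss - config.groseq_read_length + 1
        starts = rng.integers(lo, hi + 1, size=n_reads)
        for i, start in enumerate(starts):
            rows.append(
                (gene.chrom, int(start), int(start) + config.groseq_read_length,
                 f"{gene.gene_id}.gro{i}", 0, gene.strand)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a complete synthetic experiment, reproducible from the seed."""
    root = np.random.SeedSequence(config.seed)
    ss_genes, ss_gro, ss_samples = root.spawn(3)
    genes, implanted = _build_genes(config, np.random.default_rng(ss_genes))
    truth = _implant_truth(config, genes, implanted)
    groseq = _groseq_reads(config, genes, np.random.default_rng(ss_gro))

    plan = [("control", config.n_control), ("triptolide", config.n_triptolide)]
    sample_ids = [
        (f"{cond[:4]}_{i + 1}", cond)
        for cond, n in plan for i in range(n)
    ]
    streams = ss_samples.spawn(len(sample_ids))
    samples = {}
    for (sample_id, cond), stream in zip(sample_ids, streams):
        reads = _sample_reads(config, genes, truth, sample_id, cond,
                              np.random.default_rng(stream))
        samples[sample_id] = (cond, reads)

    tss_candidates = [
        TSSRecord(gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, tss=g.tss,
                  annotation_confidence=1)
        for g in genes
    ]
    return SimulatedDataset(
        config=config, genes=genes, truth=truth, samples=samples,
        groseq=groseq, tss_candidates=tss_candidates,
    )
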
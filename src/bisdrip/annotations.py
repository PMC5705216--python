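"""Reference annotations: TSS list, promoter regions, junctions, activity.

Transcription start sites are deduplicated by priority — CAGE-supported sites
first (stronger CAGE signal wins), then annotation confidence, then a seeded
random tiebreak — removing any candidate within 1000 bp of a kept site.
Promoter windows are gene-oriented and inclusive of both endpoints, so a
±1000 bp promoter spans 2001 nucleotide positions.  Promoter activity is a
fractional-overlap count of stranded nascent-transcription reads.  The
first exon-intron junction set is deduplicated, restricted to active
promoters (top 20th percentile of activity), and carries gene-oriented
first-exon lengths.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import GenomicRegion, TranscriptModel, ValidationError

CAGE_MATCH_DISTANCE = 25
TSS_EXCLUSION_RADIUS = 1000
PROMOTER_HALF_WIDTH = 1000
ACTIVE_PERCENTILE = 80.0  # promoters at/above this activity percentile are active


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    annotation_confidence: int = 0  # smaller = higher confidence
    cage_distance: int | None = None
    cage_signal: float | None = None
    tiebreak: float = 0.0


@dataclass(frozen=True)
class JunctionRecord:
    gene_id: str
    chrom: str
    strand: str
    junction: int
    tss: int
    first_exon_length: int
    junction_class: str = "first_exon_intron"

    def __post_init__(self) -> None:
        if self.junction_class == "first_exon_intron" and self.first_exon_length <= 0:
            raise ValidationError(
                f"{self.gene_id}: junction at {self.junction} is not downstream "
                f"of its TSS at {self.tss}"
            )


@dataclass(frozen=True)
class PromoterRecord:
    tss_record: TSSRecord
    activity_1000: float = 0.0
    activity_250: float = 0.0
    antisense_activity: float = 0.0
    active: bool = False

    @property
    def gene_id(self) -> str:
        return self.tss_record.gene_id

    @property
    def region(self) -> GenomicRegion:
        """±1000 bp promoter window (2001 positions, both endpoints included)."""
        t = self.tss_record
        return GenomicRegion(
            chrom=t.chrom,
            start=max(0, t.tss - PROMOTER_HALF_WIDTH),
            end=t.tss + PROMOTER_HALF_WIDTH + 1,
            strand=t.strand,
            name=t.gene_id,
        )


def gene_window(tss: TSSRecord, from_offset: int, to_offset: int) -> GenomicRegion:
    """Gene-oriented window [from_offset, to_offset] around a TSS, inclusive.

    Offsets are measured in the direction of transcription; for a minus-strand
    gene "+N bp" lies at decreasing genomic coordinate.
    """
    if tss.strand == "+":
        start, end = tss.tss + from_offset, tss.tss + to_offset + 1
    else:
        start, end = tss.tss - to_offset, tss.tss - from_offset + 1
    return GenomicRegion(chrom=tss.chrom, start=max(0, start), end=end,
                         strand=tss.strand, name=tss.gene_id)


def build_tss_reference(
    candidates: list[TSSRecord],
    cage_sites: pd.DataFrame | None = None,
    seed: int = 0,
) -> list[TSSRecord]:
    """Deduplicate candidate TSS by priority within a 1000 bp radius.

    Priority: (1) CAGE-matched within 25 bp, ranked by descending signal of
    the strongest matching site; (2) annotation confidence; (3) a seeded
    random tiebreak.  A greedy sweep keeps the highest-priority candidate and
    drops every candidate within 1000 bp (inclusive) of a kept one on the
    same chromosome.
    """
    rng = random.Random(seed)
    annotated: list[TSSRecord] = []
    for cand in sorted(candidates, key=lambda t: (t.chrom, t.tss, t.gene_id)):
        cage_dist: int | None = None
        cage_sig: float | None = None
        if cage_sites is not None and len(cage_sites):
            near = cage_sites[
                (cage_sites["chrom"] == cand.chrom)
                & ((cage_sites["start"] - cand.tss).abs() <= CAGE_MATCH_DISTANCE)
            ]
            if len(near):
                # strongest site within range, not the nearest
                best = near.loc[near["score"].idxmax()]
                cage_dist = int(abs(int(best["start"]) - cand.tss))
                cage_sig = float(best["score"])
        annotated.append(
            replace(cand, cage_distance=cage_dist, cage_signal=cage_sig,
                    tiebreak=rng.random())
        )

    def priority(t: TSSRecord):
        cage_rank = 0 if t.cage_signal is not None else 1
        return (cage_rank, -(t.cage_signal or 0.0), t.annotation_confidence,
                t.tiebreak)

    kept: list[TSSRecord] = []
    for cand in sorted(annotated, key=priority):
        if any(
            k.chrom == cand.chrom and abs(k.tss - cand.tss) <= TSS_EXCLUSION_RADIUS
            for k in kept
        ):
            continue
        kept.append(cand)
    kept.sort(key=lambda t: (t.chrom, t.tss))
    return kept


def fractional_read_count(reads: pd.DataFrame, region: GenomicRegion,
                          strand: str | None = None) -> float:
    """Fractional-overlap read count of a region from a BED6 frame.

    Each read overlapping the region adds overlap_length / read_length; reads
    fully inside add 1.  ``strand`` restricts to reads on that strand.
    """
    df = reads[reads["chrom"] == region.chrom]
    if strand is not None:
        df = df[df["strand"] == strand]
    if not len(df):
        return 0.0
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    overlap = np.minimum(end, region.end) - np.maximum(start, region.start)
    overlap = np.clip(overlap, 0, None).astype(float)
    return float((overlap / (end - start)).sum())


def promoter_activity(reads: pd.DataFrame, tss: TSSRecord,
                      window: str = "sense_1000") -> float:
    """Promoter activity in a gene-oriented window.

    ``sense_1000``: sense-strand reads, TSS..+1000; ``sense_250``:
    sense-strand reads, TSS..+250; ``antisense``: antisense-strand reads,
    TSS..+1000 upstream-oriented (i.e. -1000..TSS on the sense axis).
    """
    anti = "-" if tss.strand == "+" else "+"
    if window == "sense_1000":
        return fractional_read_count(reads, gene_window(tss, 0, 1000), tss.strand)
    if window == "sense_250":
        return fractional_read_count(reads, gene_window(tss, 0, 250), tss.strand)
    if window == "antisense":
        return fractional_read_count(reads, gene_window(tss, -1000, 0), anti)
    raise ValueError(f"unknown activity window {window!r}")


def classify_promoters(
    tss_list: list[TSSRecord],
    groseq_reads: pd.DataFrame,
    active_percentile: float = ACTIVE_PERCENTILE,
    activity_window: str = "sense_1000",
) -> list[PromoterRecord]:
    """Attach activity measurements and the active/inactive class.

    Promoters in the bottom ``active_percentile`` of the chosen activity
    measure are inactive; ties at the cutoff are counted as active.
    """
    records = [
        PromoterRecord(
            tss_record=t,
            activity_1000=promoter_activity(groseq_reads, t, "sense_1000"),
            activity_250=promoter_activity(groseq_reads, t, "sense_250"),
            antisense_activity=promoter_activity(groseq_reads, t, "antisense"),
        )
        for t in tss_list
    ]
    key = {"sense_1000": "activity_1000", "sense_250": "activity_250"}[activity_window]
    values = np.array([getattr(r, key) for r in records])
    if not len(values):
        return []
    cutoff = np.percentile(values, active_percentile)
    return [
        replace(r, active=bool(getattr(r, key) >= cutoff)) for r in records
    ]


def junction_reference(
    transcripts: list[TranscriptModel],
    promoters: list[PromoterRecord],
    exclude_genes: tuple[str, ...] = (),
) -> list[JunctionRecord]:
    """First exon-intron junction set for active promoters.

    One junction per transcript's first exon boundary; junctions shared by
    two promoter regions are kept once; junctions of inactive promoters and
    of explicitly excluded genes are dropped.  First-exon length is the
    gene-oriented TSS -> junction distance.
    """
    by_gene = {p.gene_id: p for p in promoters}
    seen: set[tuple[str, str, int]] = set()
    out: list[JunctionRecord] = []
    for t in transcripts:
        if t.gene_id in exclude_genes:
            continue
        promoter = by_gene.get(t.gene_id)
        if promoter is None or not promoter.active:
            continue
        junction = t.first_junction()
        if junction is None:
            continue
        key = (t.chrom, t.strand, junction)
        if key in seen:
            continue
        seen.add(key)
        tss = promoter.tss_record.tss
        length = (junction - tss) if t.strand == "+" else (tss - junction)
        out.append(
            JunctionRecord(
                gene_id=t.gene_id, chrom=t.chrom, strand=t.strand,
                junction=junction, tss=tss, first_exon_length=int(length),
            )
        )
    return out


def bin_by_first_exon_length(
    junctions: list[JunctionRecord], k: int = 5
) -> list[list[JunctionRecord]]:
    """Split junctions into k near-equal-count bins of increasing exon length."""
    if len(junctions) < k:
        raise ValueError(f"need at least {k} junctions, got {len(junctions)}")
    ordered = sorted(junctions, key=lambda j: (j.first_exon_length, j.gene_id))
    return [list(chunk) for chunk in np.array_split(np.array(ordered, dtype=object), k)]
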
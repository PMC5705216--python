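"""Readers and writers for the on-disk formats the pipeline consumes and emits.

The canonical per-read input is a tab-separated conversion table: one row per
aligned read, carrying the read's interval, the genomic strand its assessed
cytosines lie on, and the coordinates of its converted and unconverted
cytosines.  Gene models arrive as GTF, CAGE sites and nascent-transcription
(GRO-seq-style) reads as BED6, and per-nucleotide score tracks leave as
bedGraph.

All internal coordinates are 0-based half-open.  GTF (1-based inclusive) is
converted on read; BED and bedGraph are already 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

CONDITIONS = ("control", "triptolide", "rnaseh", "delayed")

#: Required columns of the conversion TSV, in canonical order.
CONVERSION_COLUMNS = (
    "read_id",
    "sample_id",
    "condition",
    "chrom",
    "start",
    "end",
    "conversion_strand",
    "converted_positions",
    "unconverted_positions",
)


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read with its cytosine-conversion calls.

    ``conversion_strand`` is the genomic strand carrying the read's assessed
    cytosines (the strand the bisulfite reaction could act on in this
    alignment).  ``n_cytosines`` is the original number of cytosines:
    converted plus unconverted.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    conversion_strand: str
    converted_positions: tuple[int, ...]
    unconverted_positions: tuple[int, ...]
    sample_id: str = "S1"
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"read {self.read_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.conversion_strand not in ("+", "-"):
            raise ValidationError(
                f"read {self.read_id}: conversion_strand must be '+' or '-', "
                f"got {self.conversion_strand!r}"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"read {self.read_id}: unknown condition {self.condition!r}"
            )
        for pos in self.converted_positions + self.unconverted_positions:
            if not (self.start <= pos < self.end):
                raise ValidationError(
                    f"read {self.read_id}: cytosine position {pos} outside "
                    f"[{self.start}, {self.end})"
                )
        object.__setattr__(
            self, "converted_positions", tuple(sorted(self.converted_positions))
        )
        object.__setattr__(
            self, "unconverted_positions", tuple(sorted(self.unconverted_positions))
        )

    @property
    def n_converted(self) -> int:
        return len(self.converted_positions)

    @property
    def n_cytosines(self) -> int:
        """Original number of cytosines: converted + unconverted."""
        return len(self.converted_positions) + len(self.unconverted_positions)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def conversion_fraction(self) -> float:
        n = self.n_cytosines
        return self.n_converted / n if n else 0.0


@dataclass(frozen=True)
class GenomicRegion:
    """A named, optionally stranded genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"region {self.name or '?'}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _join_positions(positions: Sequence[int]) -> str:
    return ",".join(str(p) for p in positions)


def _split_positions(cell: object) -> tuple[int, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(int(tok) for tok in text.split(","))


def read_conversion_table(path: str | os.PathLike) -> list[ReadRecord]:
    """Parse a conversion TSV into validated :class:`ReadRecord` objects.

    Raises :class:`FormatError` when required columns are missing and
    :class:`ValidationError` (naming the read and line) when a row violates a
    record invariant.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"read_id": str, "sample_id": str, "condition": str, "chrom": str,
               "converted_positions": str, "unconverted_positions": str},
        keep_default_na=False,
    )
    missing = [c for c in CONVERSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: conversion table missing required columns: {', '.join(missing)}"
        )
    records: list[ReadRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header
        try:
            records.append(
                ReadRecord(
                    read_id=row.read_id,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    conversion_strand=row.conversion_strand,
                    converted_positions=_split_positions(row.converted_positions),
                    unconverted_positions=_split_positions(row.unconverted_positions),
                    sample_id=row.sample_id,
                    condition=row.condition,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}:{line_no}: {exc}") from exc
    return records


def write_conversion_table(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    """Serialize reads to the canonical conversion TSV."""
    rows = [
        {
            "read_id": r.read_id,
            "sample_id": r.sample_id,
            "condition": r.condition,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "conversion_strand": r.conversion_strand,
            "converted_positions": _join_positions(r.converted_positions),
            "unconverted_positions": _join_positions(r.unconverted_positions),
        }
        for r in reads
    ]
    pd.DataFrame(rows, columns=list(CONVERSION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def summarize_bismark_calls(
    calls: pd.DataFrame,
    sample_id: str = "S1",
    condition: str = "control",
) -> list[ReadRecord]:
    """Best-effort adapter from methylation-extractor-style per-cytosine output.

    Expects one row per assessed cytosine with columns ``read_id``, ``chrom``,
    ``position`` (0-based), ``strand`` and ``converted`` (boolean-ish);
    optional ``read_start``/``read_end`` override the inferred interval.  A
    read's interval defaults to the span of its assessed cytosines plus one.
    """
    required = {"read_id", "chrom", "position", "strand", "converted"}
    missing = required - set(calls.columns)
    if missing:
        raise FormatError(
            f"bismark-style call table missing columns: {', '.join(sorted(missing))}"
        )
    records = []
    for read_id, grp in calls.groupby("read_id", sort=False):
        strands = grp["strand"].unique()
        if len(strands) != 1:
            raise ValidationError(
                f"read {read_id}: cytosine calls on multiple strands {list(strands)}"
            )
        pos = grp["position"].astype(int)
        conv = grp["converted"].astype(bool)
        start = int(grp["read_start"].iloc[0]) if "read_start" in grp else int(pos.min())
        end = int(grp["read_end"].iloc[0]) if "read_end" in grp else int(pos.max()) + 1
        records.append(
            ReadRecord(
                read_id=str(read_id),
                chrom=str(grp["chrom"].iloc[0]),
                start=start,
                end=end,
                conversion_strand=str(strands[0]),
                converted_positions=tuple(pos[conv]),
                unconverted_positions=tuple(pos[~conv]),
                sample_id=sample_id,
                condition=condition,
            )
        )
    return records


# ---------------------------------------------------------------------------
# BED6

BED6_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 file (0-based half-open) into a DataFrame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=list(BED6_COLUMNS), dtype={0: str, 3: str, 5: str},
    )
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValidationError(f"{path}: BED interval with end <= start at row {bad}")
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, list(BED6_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


def bed_to_regions(df: pd.DataFrame) -> list[GenomicRegion]:
    return [
        GenomicRegion(chrom=c, start=int(s), end=int(e), strand=st, name=str(n))
        for c, s, e, n, st in zip(
            df["chrom"], df["start"], df["end"], df["name"], df["strand"]
        )
    ]


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track, strand: str, path: str | os.PathLike,
                   track_name: str | None = None) -> None:
    """Write one strand of a score track as a sorted, run-length-merged bedGraph.

    Intervals are 0-based half-open, non-overlapping, sorted by chromosome then
    start; adjacent positions with equal value are merged into one line.
    """
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, start, end, value in track.nonzero_intervals(strand):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    """Read a bedGraph data section into a DataFrame (track lines skipped)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# GTF

@dataclass
class TranscriptModel:
    """Exon structure of one annotated transcript, 0-based half-open exons."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Transcription start site (first transcribed base, 0-based)."""
        if self.strand == "+":
            return min(e[0] for e in self.exons)
        return max(e[1] for e in self.exons) - 1

    def first_junction(self) -> int | None:
        """Gene-oriented first exon-intron boundary, or None if intronless.

        Returned as the 0-based coordinate of the first intronic base (for a
        minus-strand gene, the base just 5' of the first exon's genomic start).
        """
        if len(self.exons) < 2:
            return None
        exons = sorted(self.exons)
        if self.strand == "+":
            return exons[0][1]
        return exons[-1][0] - 1


def read_gtf_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Load transcript models from a GTF file via gffutils.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    models = []
    for t in db.features_of_type("transcript"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(t, featuretype="exon")
        ]
        if not exons:
            continue
        models.append(
            TranscriptModel(
                transcript_id=t.attributes.get("transcript_id", [t.id])[0],
                gene_id=t.attributes.get("gene_id", ["?"])[0],
                chrom=t.seqid,
                strand=t.strand,
                exons=sorted(exons),
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | os.PathLike,
              source: str = "bisdrip") -> None:
    """Write transcript models as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            g_start = min(e[0] for e in m.exons) + 1
            g_end = max(e[1] for e in m.exons)
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write(f"{m.chrom}\t{source}\tgene\t{g_start}\t{g_end}\t.\t{m.strand}\t.\t"
                     f'gene_id "{m.gene_id}";\n')
            fh.write(f"{m.chrom}\t{source}\ttranscript\t{g_start}\t{g_end}\t.\t"
                     f"{m.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(sorted(m.exons), start=1):
                fh.write(f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                         f'{attrs} exon_number "{i}";\n')
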
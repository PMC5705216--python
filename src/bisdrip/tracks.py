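"""Strand-specific per-nucleotide score tracks and region scores.

A read's normalized score is attributed to every nucleotide it covers, on the
strand its converted cytosines lie on; the per-nucleotide track value is the
sum over covering reads.  Region scores add each overlapping read's score
weighted by the fraction of the read's length inside the region, which makes
region scores exactly additive over a partition of the genome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .io import GenomicRegion, ReadRecord


def read_effective_strand(read: ReadRecord) -> str:
    """Strand a read's score counts toward.

    The strand of the read's converted cytosines; a conversion-free read
    falls back to its aligner-assigned conversion strand (its score is 0 in a
    background-dominated sample, so the fallback has no numeric effect).
    """
    return read.conversion_strand


@dataclass
class ScoreTrack:
    """Sparse strand-specific per-nucleotide score accumulator.

    Stored as per-(chrom, strand) boundary deltas: adding ``v`` over
    ``[start, end)`` adds +v at ``start`` and -v at ``end``; per-base values
    are prefix sums of the sorted deltas.  Absent positions are 0.
    """

    label: str = ""
    _deltas: dict[tuple[str, str], dict[int, float]] = field(
        default_factory=lambda: defaultdict(lambda: defaultdict(float))
    )

    def add_interval(self, chrom: str, strand: str, start: int, end: int,
                     value: float) -> None:
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        d = self._deltas[(chrom, strand)]
        d[start] += value
        d[end] -= value

    def chroms(self, strand: str) -> list[str]:
        return sorted({c for c, s in self._deltas if s == strand})

    def nonzero_intervals(self, strand: str
                          ) -> Iterator[tuple[str, int, int, float]]:
        """Maximal runs of equal nonzero value, sorted by chrom then start."""
        for chrom in self.chroms(strand):
            d = self._deltas[(chrom, strand)]
            level = 0.0
            run_start: int | None = None
            for pos in sorted(d):
                new_level = level + d[pos]
                if abs(new_level - level) <= 1e-12:
                    continue  # net-zero boundary: keep the run unbroken
                if run_start is not None and abs(level) > 1e-12:
                    yield chrom, run_start, pos, level
                level = new_level
                run_start = pos

    def per_base(self, chrom: str, strand: str, start: int, end: int
                 ) -> np.ndarray:
        """Dense per-base values over [start, end)."""
        out = np.zeros(end - start)
        d = self._deltas.get((chrom, strand))
        if not d:
            return out
        for c, s, e, v in self.nonzero_intervals(strand):
            if c != chrom:
                continue
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out[lo - start: hi - start] += v
        return out

    def is_empty(self) -> bool:
        return not any(
            any(abs(v) > 0 for v in d.values()) for d in self._deltas.values()
        )

    def scale(self, factor: float) -> "ScoreTrack":
        out = ScoreTrack(label=self.label)
        for key, d in self._deltas.items():
            out._deltas[key] = defaultdict(float, {p: v * factor for p, v in d.items()})
        return out

    def __iadd__(self, other: "ScoreTrack") -> "ScoreTrack":
        for key, d in other._deltas.items():
            mine = self._deltas[key]
            for p, v in d.items():
                mine[p] += v
        return self


def build_track(reads: Sequence[ReadRecord], scores: np.ndarray,
                label: str = "") -> ScoreTrack:
    """Sum each read's score over its covered positions on its effective strand."""
    track = ScoreTrack(label=label)
    for read, score in zip(reads, scores):
        if score == 0:
            continue
        track.add_interval(read.chrom, read_effective_strand(read),
                           read.start, read.end, float(score))
    return track


def mean_track(tracks: Sequence[ScoreTrack], label: str = "") -> ScoreTrack:
    """Across-sample mean of per-sample tracks (condition-level track)."""
    if not tracks:
        raise ValueError("mean_track needs at least one track")
    out = ScoreTrack(label=label)
    for t in tracks:
        out += t.scale(1.0 / len(tracks))
    return out


def region_score(
    reads: Sequence[ReadRecord],
    scores: np.ndarray,
    region: GenomicRegion,
    strand_filter: str | None = None,
) -> float:
    """Fractional-overlap score of a region.

    Each overlapping read (passing the effective-strand filter, if given)
    contributes score x overlap_length / read_length; reads fully inside
    contribute their whole score.
    """
    total = 0.0
    for read, score in zip(reads, scores):
        if read.chrom != region.chrom:
            continue
        if strand_filter is not None and read_effective_strand(read) != strand_filter:
            continue
        overlap = min(read.end, region.end) - max(read.start, region.start)
        if overlap <= 0:
            continue
        total += float(score) * overlap / read.length
    return total


def windowed_base_composition(sequence: str, flank: int = 25) -> np.ndarray:
    """Mean A/C/G/T counts in a sliding window of width 2*flank+1.

    Returns an array of shape (len(sequence), 4) ordered A, C, G, T; windows
    are clipped at the sequence ends.
    """
    seq = sequence.upper()
    n = len(seq)
    out = np.zeros((n, 4))
    onehot = np.zeros((n, 4))
    for j, base in enumerate("ACGT"):
        onehot[:, j] = [1.0 if ch == base else 0.0 for ch in seq]
    cum = np.vstack([np.zeros(4), np.cumsum(onehot, axis=0)])
    for i in range(n):
        lo, hi = max(0, i - flank), min(n, i + flank + 1)
        out[i] = (cum[hi] - cum[lo]) / (hi - lo)
    return out
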
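"""Monte Carlo nulls for spatial clustering of read scores.

Two null models against a 1 kb tiling of the genome:

* random regions — each read is reassigned uniformly at random to a 1 kb
  region on its own chromosome that had at least one aligned read in the
  real data (read-free regions leave the assignment universe), carrying its
  score; this models a fully non-specific assay.
* shuffled scores — read positions stay fixed and the scores are permuted
  within each chromosome; this models stochastic per-read scoring.

Both conserve the total score per chromosome exactly, so only the spatial
arrangement of scores differs between real data and a null draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import GenomicRegion, ReadRecord

REGION_WIDTH = 1000


@dataclass
class RegionGrid:
    """Disjoint fixed-width tiling of each chromosome."""

    chrom_sizes: dict[str, int]
    width: int = REGION_WIDTH

    def regions(self) -> list[GenomicRegion]:
        out = []
        for chrom in sorted(self.chrom_sizes):
            size = self.chrom_sizes[chrom]
            for start in range(0, size, self.width):
                out.append(
                    GenomicRegion(chrom=chrom, start=start,
                                  end=min(start + self.width, size),
                                  name=f"{chrom}:{start}")
                )
        return out

    def region_index(self, read: ReadRecord) -> int:
        """Grid slot of a read's start position (local index in its chromosome)."""
        return read.start // self.width


def grid_scores(reads: list[ReadRecord], scores: np.ndarray,
                grid: RegionGrid) -> dict[str, float]:
    """Fractional-overlap score of every grid region, keyed by region name.

    Exploits the tiling: a read only touches the regions its interval spans,
    so each read is distributed over those slots in O(read length / width).
    """
    w = grid.width
    acc: dict[tuple[str, int], float] = {}
    for read, score in zip(reads, scores):
        if score == 0:
            continue
        first, last = read.start // w, (read.end - 1) // w
        for slot in range(first, last + 1):
            lo, hi = slot * w, (slot + 1) * w
            overlap = min(read.end, hi) - max(read.start, lo)
            key = (read.chrom, slot)
            acc[key] = acc.get(key, 0.0) + float(score) * overlap / read.length
    out = {}
    for region in grid.regions():
        out[region.name] = acc.get((region.chrom, region.start // w), 0.0)
    return out


def _per_chrom_rngs(chroms: list[str], seed: int) -> dict[str, np.random.Generator]:
    """Independent, deterministic per-chromosome streams from one seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(chroms))
    return {c: np.random.default_rng(s) for c, s in zip(sorted(chroms), children)}


def occupied_region_starts(reads: list[ReadRecord], grid: RegionGrid
                           ) -> dict[str, np.ndarray]:
    """Per chromosome, the start coordinates of grid regions holding >= 1 read."""
    occupied: dict[str, set[int]] = {}
    for read in reads:
        occupied.setdefault(read.chrom, set()).add(read.start // grid.width * grid.width)
    return {c: np.array(sorted(s)) for c, s in occupied.items()}


def simulate_random_regions(
    reads: list[ReadRecord], scores: np.ndarray, grid: RegionGrid, seed: int
) -> tuple[list[ReadRecord], np.ndarray]:
    """Reassign each read to a random occupied region on its chromosome.

    The read keeps its length and score and takes the region's start as its
    new start, clipped to the chromosome end.  Returns new reads with the
    original score array (scores travel with their reads).
    """
    eligible = occupied_region_starts(reads, grid)
    rngs = _per_chrom_rngs(sorted(grid.chrom_sizes), seed)
    out = []
    for read in reads:
        starts = eligible.get(read.chrom)
        if starts is None or not len(starts):
            out.append(read)
            continue
        rng = rngs[read.chrom]
        new_start = int(starts[rng.integers(len(starts))])
        chrom_size = grid.chrom_sizes.get(read.chrom)
        length = read.length
        if chrom_size is not None:
            new_start = min(new_start, max(0, chrom_size - length))
        shift = new_start - read.start
        out.append(
            replace(
                read,
                start=new_start,
                end=new_start + length,
                converted_positions=tuple(p + shift for p in read.converted_positions),
                unconverted_positions=tuple(
                    p + shift for p in read.unconverted_positions
                ),
            )
        )
    return out, np.asarray(scores, dtype=float).copy()


def simulate_shuffled_scores(
    reads: list[ReadRecord], scores: np.ndarray, seed: int
) -> np.ndarray:
    """Permute scores among the reads of each chromosome.

    The multiset of scores per chromosome — hence the per-chromosome total —
    is unchanged; only the score-to-position pairing is randomized.
    """
    scores = np.asarray(scores, dtype=float).copy()
    chroms = sorted({r.chrom for r in reads})
    rngs = _per_chrom_rngs(chroms, seed)
    chrom_arr = np.array([r.chrom for r in reads])
    for chrom in chroms:
        idx = np.flatnonzero(chrom_arr == chrom)
        scores[idx] = scores[idx][rngs[chrom].permutation(len(idx))]
    return scores


def null_region_maxima(
    reads: list[ReadRecord],
    scores: np.ndarray,
    grid: RegionGrid,
    n_draws: int,
    seed: int,
    mode: str = "shuffle",
) -> np.ndarray:
    """Maximum grid-region score of each of ``n_draws`` null datasets."""
    if mode not in ("shuffle", "regions"):
        raise ValueError(f"mode must be 'shuffle' or 'regions', got {mode!r}")
    maxima = np.empty(n_draws)
    seeds = np.random.SeedSequence(seed).generate_state(n_draws) % (2**31)
    for i in range(n_draws):
        if mode == "shuffle":
            null_scores = simulate_shuffled_scores(reads, scores, int(seeds[i]))
            vals = grid_scores(reads, null_scores, grid)
        else:
            null_reads, null_scores = simulate_random_regions(
                reads, scores, grid, int(seeds[i])
            )
            vals = grid_scores(null_reads, null_scores, grid)
        maxima[i] = max(vals.values()) if vals else 0.0
    return maxima
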
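"""Per-read single-strandedness scoring against a binomial background model.

Under non-denaturing bisulfite treatment only single-stranded DNA is
deaminated, so reads drawn from double-stranded regions accumulate cytosine
conversions at a low stochastic background rate while reads from the displaced
strand of an R-loop convert at a high rate.  Each read is scored by comparing,
within its sample, the observed number of reads sharing its (original
cytosine count n, converted count c) bin against the count expected if every
conversion were background: score = 1 - E/O when O > E, else 0.  The score is
the estimated fraction of the bin's reads whose conversions are not explained
by chance, and it is shared by every read in the bin.

Sparse tails are pooled: once a bin's expected count drops to the cutoff
(default 5), all higher conversion counts are scored from cumulative tail
sums, and tails whose expected mass is itself below the cutoff inherit the
previous conversion count's score.  Cytosine-count groups with too few reads
(default <= 1000) inherit scores from the next-smaller group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import ReadRecord


class ScoringError(ValueError):
    """Raised when a score model cannot be estimated or applied."""


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable constants of the scoring procedure.

    outlier_fold
        Reads whose own conversion fraction exceeds this multiple of the
        global per-cytosine conversion fraction are excluded from the
        background-rate estimate (one pass).
    min_group_reads
        A cytosine-count group must exceed this many reads to be scored from
        its own counts; smaller groups inherit from the next-smaller group.
    min_expected
        Expected-count cutoff below which bins are pooled into cumulative
        tails.
    normalization_total
        Post-normalization sum of read scores per sample.
    """

    outlier_fold: float = 2.5
    min_group_reads: int = 1000
    min_expected: float = 5.0
    normalization_total: float = 1_000_000.0

    def __post_init__(self) -> None:
        for name in ("outlier_fold", "min_group_reads", "min_expected",
                     "normalization_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScoringConfig.{name} must be strictly positive")


@dataclass
class ScoreBin:
    """Observed/expected read counts and score for one (n, c) bin."""

    n: int
    c: int
    O: float
    E: float
    score: float
    inherited_from: int | None = None  # donor group's n when inherited


@dataclass
class SampleScoreModel:
    """Background rate plus the (n, c) -> score lookup for one sample."""

    sample_id: str
    background_rate: float
    bins: dict[tuple[int, int], ScoreBin] = field(default_factory=dict)
    group_sizes: dict[int, int] = field(default_factory=dict)

    def score(self, n: int, c: int) -> float:
        if n == 0:
            return 0.0
        try:
            return self.bins[(n, c)].score
        except KeyError:
            raise ScoringError(
                f"sample {self.sample_id}: no score bin for n={n}, c={c}"
            ) from None

    def to_dict(self) -> dict:
        """JSON-serializable dump (background rate plus per-bin table)."""
        return {
            "sample_id": self.sample_id,
            "background_rate": self.background_rate,
            "group_sizes": {str(n): s for n, s in self.group_sizes.items()},
            "bins": [
                {"n": b.n, "c": b.c, "observed": b.O, "expected": b.E,
                 "score": b.score, "inherited_from": b.inherited_from}
                for b in self.bins.values()
            ],
        }


def estimate_background_rate(
    reads: list[ReadRecord], config: ScoringConfig = ScoringConfig()
) -> float:
    """Estimate the stochastic per-cytosine conversion probability.

    The global per-cytosine conversion fraction is computed over all reads
    with at least one cytosine; reads whose own conversion fraction exceeds
    ``outlier_fold`` times that estimate are removed and the fraction is
    recomputed once over the remainder.
    """
    n_cyt = np.array([r.n_cytosines for r in reads], dtype=float)
    n_conv = np.array([r.n_converted for r in reads], dtype=float)
    total = n_cyt.sum()
    if total == 0:
        raise ScoringError("cannot estimate background rate: no cytosines in any read")
    rough = n_conv.sum() / total
    with np.errstate(invalid="ignore"):
        per_read = np.where(n_cyt > 0, n_conv / np.maximum(n_cyt, 1), 0.0)
    keep = per_read <= config.outlier_fold * rough
    kept_cyt = n_cyt[keep].sum()
    if kept_cyt == 0:
        # Every read is an outlier relative to the rough estimate; fall back
        # to the rough estimate rather than dividing by zero.
        return float(rough)
    return float(n_conv[keep].sum() / kept_cyt)


def expected_reads(N: float, n: int, c: int, p: float) -> float:
    """Expected number of reads with c conversions among N reads of n cytosines.

    N times the Binomial(n, p) probability mass at c.
    """
    if not 0 <= c <= n:
        raise ValueError(f"need 0 <= c <= n, got c={c}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"need 0 <= p <= 1, got p={p}")
    if N < 0:
        raise ValueError(f"need N >= 0, got N={N}")
    return float(N) * float(sps.binom.pmf(c, n, p))


def _score_group(N: int, O: np.ndarray, E: np.ndarray, min_expected: float
                 ) -> np.ndarray:
    """Score all conversion counts 0..n of one cytosine-count group.

    Per-bin rule while E_c > min_expected (scanning c ascending); from the
    first c with E_c <= min_expected, cumulative-tail pooling; tails with
    expected mass <= min_expected inherit the previous count's score.
    """
    n = len(O) - 1
    scores = np.zeros(n + 1)
    tail_start = n + 1
    for c in range(n + 1):
        if E[c] <= min_expected:
            tail_start = c
            break
        scores[c] = max(0.0, 1.0 - E[c] / O[c]) if O[c] > E[c] else 0.0
    for x in range(tail_start, n + 1):
        tail_E = E[x:].sum()
        tail_O = O[x:].sum()
        if tail_E > min_expected:
            scores[x] = max(0.0, 1.0 - tail_E / tail_O) if tail_O > tail_E else 0.0
        else:
            scores[x] = scores[x - 1] if x > 0 else 0.0
    return scores


def build_score_model(
    reads: list[ReadRecord],
    config: ScoringConfig = ScoringConfig(),
    sample_id: str | None = None,
    background_rate: float | None = None,
) -> SampleScoreModel:
    """Build the (n, c) -> score lookup for one sample.

    Groups with more than ``min_group_reads`` reads are scored from their own
    observed/expected counts; smaller groups inherit, per conversion count,
    the score of the next-smaller scored group (recursing downward; score 0
    when no scored group exists below).  Reads with zero cytosines score 0.
    """
    if sample_id is None:
        sample_id = reads[0].sample_id if reads else "S1"
    if background_rate is None:
        background_rate = estimate_background_rate(reads, config)
        if background_rate == 0.0 and any(r.n_converted for r in reads):
            # The outlier pass excluded every converted read (possible when
            # reads carry few cytosines, so a single conversion already
            # exceeds the fold threshold).  A zero rate would degenerate the
            # binomial model, so fall back to the pre-exclusion estimate.
            total = sum(r.n_cytosines for r in reads)
            background_rate = sum(r.n_converted for r in reads) / total
    p = background_rate

    counts: dict[int, np.ndarray] = {}
    for r in reads:
        n = r.n_cytosines
        if n not in counts:
            counts[n] = np.zeros(n + 1)
        counts[n][r.n_converted] += 1

    model = SampleScoreModel(sample_id=sample_id, background_rate=p)
    group_scores: dict[int, np.ndarray] = {}
    scored_ns: list[int] = []

    for n in sorted(counts):
        O = counts[n]
        N = int(O.sum())
        model.group_sizes[n] = N
        if n == 0:
            model.bins[(0, 0)] = ScoreBin(0, 0, O[0], O[0], 0.0)
            continue
        E = N * sps.binom.pmf(np.arange(n + 1), n, p)
        if N > config.min_group_reads:
            scores = _score_group(N, O, E, config.min_expected)
            inherited: int | None = None
            scored_ns.append(n)
        else:
            donor = max((m for m in scored_ns if m < n), default=None)
            if donor is None:
                scores = np.zeros(n + 1)
                inherited = None
            else:
                donor_scores = group_scores[donor]
                # conversion counts beyond the donor's range take its tail score
                idx = np.minimum(np.arange(n + 1), donor)
                scores = donor_scores[idx]
                inherited = donor
        group_scores[n] = scores
        for c in range(n + 1):
            model.bins[(n, c)] = ScoreBin(
                n=n, c=c, O=float(O[c]), E=float(E[c]), score=float(scores[c]),
                inherited_from=inherited,
            )
    return model


def detects_enrichment(model: SampleScoreModel, min_conversions: int = 3) -> bool:
    """Whether a sample's score model registers any conversion enrichment.

    A sample whose every bin at ``min_conversions`` or more conversions
    scores zero carries no information about single-stranded structure: the
    observed counts at the anchor bins fell at or below expectation, so the
    cumulative-tail rule propagates zero through all highly converted reads.
    At realistic sequencing depth this does not occur; in a shallow sample it
    marks a failed measurement, and condition-level analyses should treat
    such a replicate as quality-failed rather than as evidence of absence.
    """
    return any(
        b.score > 0 for (n, c), b in model.bins.items() if c >= min_conversions
    )


def assign_read_scores(
    reads: list[ReadRecord], model: SampleScoreModel
) -> np.ndarray:
    """Raw score per read, aligned with the input order.

    Every read with the same (n, c) receives the same score; zero-cytosine
    reads score 0.
    """
    return np.array([model.score(r.n_cytosines, r.n_converted) for r in reads])


def normalize_scores(
    raw_scores: np.ndarray, config: ScoringConfig = ScoringConfig()
) -> np.ndarray:
    """Rescale raw scores so the per-sample total equals normalization_total."""
    total = float(np.sum(raw_scores))
    if total <= 0:
        raise ScoringError(
            "cannot normalize: sample has no reads with positive score"
        )
    return np.asarray(raw_scores, dtype=float) * (config.normalization_total / total)


def normalize_or_zero(
    raw_scores: np.ndarray, config: ScoringConfig = ScoringConfig()
) -> np.ndarray:
    """Like :func:`normalize_scores`, but an all-zero sample stays all-zero.

    A sample in which no read scores above background (e.g. a fully
    transcription-inhibited sample in a clean synthetic experiment) has no
    mass to renormalize; pipeline stages treat it as contributing zero
    everywhere rather than failing.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.sum() <= 0:
        return np.zeros_like(raw)
    return normalize_scores(raw, config)


def cytosine_normalize(
    reads: list[ReadRecord],
    raw_scores: np.ndarray,
    config: ScoringConfig = ScoringConfig(),
) -> tuple[np.ndarray, dict[int, float]]:
    """Equalize mean scores across cytosine-count groups, then normalize.

    Each group's scores are multiplied by a group constant chosen so all
    group means match the overall mean raw score; groups whose scores are all
    zero cannot be rescaled and are left at zero.  Returns the normalized
    scores and the per-group factors (0.0 marks an unscalable group).
    """
    raw = np.asarray(raw_scores, dtype=float)
    ns = np.array([r.n_cytosines for r in reads])
    target = raw.mean()
    adjusted = raw.copy()
    factors: dict[int, float] = {}
    for n in np.unique(ns):
        mask = ns == n
        mean = raw[mask].mean()
        if mean > 0:
            factor = target / mean
            adjusted[mask] = raw[mask] * factor
            factors[int(n)] = float(factor)
        else:
            factors[int(n)] = 0.0
    return normalize_scores(adjusted, config), factors
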
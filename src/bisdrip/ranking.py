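"""Ranking promoters by transcription-dependent sense-strand R-loop formation.

All region scores here are measured gene-orientedly between the TSS and
+250 bp.  Candidates must be active promoters (top 20th percentile of
nascent-transcription activity in that window) with a positive non-template
score in every control replicate.  Survivors are ranked by

    2 * (log2(s_NT_ctrl + 1) - log2(s_NT_tpl + 1)) - log2(s_T_ctrl + 1)

which rewards transcription-inhibitor-sensitive non-template signal and
penalizes template signal.  The derived "R-loop formation" measure is the sum
of the strand asymmetry and the inhibitor sensitivity of the non-template
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import PromoterRecord, gene_window
from .io import GenomicRegion, ReadRecord
from .metaplots import strand_asymmetry
from .stats import TestResult, rank_test
from .tracks import region_score

RANKING_WINDOW = 250  # gene-oriented TSS..+250 bp


def triptolide_sensitivity(s_nt_ctrl: float, s_nt_tpl: float) -> float:
    """Drop in non-template score under transcription inhibition."""
    return s_nt_ctrl - s_nt_tpl


def rank_score(s_nt_ctrl: float, s_nt_tpl: float, s_t_ctrl: float) -> float:
    """2 x the inhibitor-sensitive log2 non-template signal, minus the log2
    template signal (all +1 pseudocounts)."""
    return float(
        2.0 * (np.log2(s_nt_ctrl + 1.0) - np.log2(s_nt_tpl + 1.0))
        - np.log2(s_t_ctrl + 1.0)
    )


@dataclass
class PromoterSummary:
    promoter: PromoterRecord
    s_nt_ctrl: float = 0.0
    s_t_ctrl: float = 0.0
    s_nt_tpl: float = 0.0
    replicate_s_nt: list[float] = field(default_factory=list)
    passed_filters: bool = False
    rank_value: float = float("nan")

    @property
    def gene_id(self) -> str:
        return self.promoter.gene_id

    @property
    def sensitivity(self) -> float:
        return triptolide_sensitivity(self.s_nt_ctrl, self.s_nt_tpl)

    @property
    def asymmetry(self) -> float:
        return strand_asymmetry(self.s_nt_ctrl, self.s_t_ctrl)

    @property
    def rloop_formation(self) -> float:
        """Sum of strand asymmetry and inhibitor sensitivity."""
        return self.asymmetry + self.sensitivity


def summarize_promoters(
    promoters: list[PromoterRecord],
    control_replicates: list[tuple[list[ReadRecord], np.ndarray]],
    triptolide_replicates: list[tuple[list[ReadRecord], np.ndarray]],
    window: int = RANKING_WINDOW,
) -> list[PromoterSummary]:
    """Measure per-promoter strand-specific region scores, TSS..+window.

    Replicates are (reads, normalized scores) pairs; condition-level scores
    are across-replicate means.
    """
    out = []
    for prom in promoters:
        tss = prom.tss_record
        region = gene_window(tss, 0, window)
        sense, anti = tss.strand, ("-" if tss.strand == "+" else "+")
        rep_nt = [region_score(reads, scores, region, sense)
                  for reads, scores in control_replicates]
        rep_t = [region_score(reads, scores, region, anti)
                 for reads, scores in control_replicates]
        tpl_nt = [region_score(reads, scores, region, sense)
                  for reads, scores in triptolide_replicates]
        out.append(
            PromoterSummary(
                promoter=prom,
                s_nt_ctrl=float(np.mean(rep_nt)) if rep_nt else 0.0,
                s_t_ctrl=float(np.mean(rep_t)) if rep_t else 0.0,
                s_nt_tpl=float(np.mean(tpl_nt)) if tpl_nt else 0.0,
                replicate_s_nt=rep_nt,
            )
        )
    return out


def apply_filters(summaries: list[PromoterSummary]) -> list[PromoterSummary]:
    """Keep active promoters with positive s_NT in every control replicate."""
    kept = []
    for s in summaries:
        ok = s.promoter.active and all(v > 0 for v in s.replicate_s_nt) \
            and len(s.replicate_s_nt) > 0
        s.passed_filters = ok
        if ok:
            kept.append(s)
    return kept


def rank_promoters(summaries: list[PromoterSummary]) -> list[PromoterSummary]:
    """Filter, score and sort promoters, best candidates first."""
    kept = apply_filters(summaries)
    for s in kept:
        s.rank_value = rank_score(s.s_nt_ctrl, s.s_nt_tpl, s.s_t_ctrl)
    kept.sort(key=lambda s: (-s.rank_value, s.gene_id))
    return kept


def precision_at_k(ranked: list[PromoterSummary], truth_genes: set[str],
                   k: int | None = None) -> float:
    """Fraction of the top k ranked promoters that are true R-loop genes."""
    if k is None:
        k = len(truth_genes)
    if k == 0:
        return float("nan")
    top = ranked[:k]
    return sum(1 for s in top if s.gene_id in truth_genes) / k


def promoter_enrichment_test(
    promoters: list[PromoterRecord],
    matched_regions: dict[str, GenomicRegion],
    reads: list[ReadRecord],
    scores: np.ndarray,
) -> TestResult:
    """Compare promoter-region scores against matched within-gene regions.

    Matched regions are exon-centered windows >= 2 kb downstream of the TSS
    in the same gene (supplied by the caller; genes shorter than 2 kb are
    expected to be absent from the mapping).  The comparison is the unpaired
    two-sample rank test.
    """
    prom_scores, matched_scores = [], []
    for prom in promoters:
        match = matched_regions.get(prom.gene_id)
        if match is None:
            continue
        prom_scores.append(region_score(reads, scores, prom.region))
        matched_scores.append(region_score(reads, scores, match))
    if not prom_scores:
        raise ValueError("no promoters with matched regions")
    return rank_test(prom_scores, matched_scores, paired=False)
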
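"""Offset-indexed aggregation of read scores and conversions around
reference points, R-loop signal, and boundary detection.

For every read nucleotide within W of the read's proximal reference point
(a TSS or first exon-intron junction), the read's score is added to the
gene-oriented offset of that nucleotide, split into non-template (read
effective strand equals the gene's coding strand) and template series.
The R-loop signal at an offset is the transcription-inhibitor-corrected
non-template score minus the corrected template score:

    signal = (ctrl_NT - tpl_NT) - (ctrl_T - tpl_T)

so it is positive where transcription-dependent single-strandedness sits on
the coding strand — the signature of a sense-strand R-loop — and negative
for the antisense-strand counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ReadRecord
from .tracks import read_effective_strand

DEFAULT_WINDOW = 1000

SERIES_KEYS = ("ctrl_NT", "ctrl_T", "tpl_NT", "tpl_T")


@dataclass(frozen=True)
class RefPoint:
    """A gene-oriented reference position (TSS or junction)."""

    chrom: str
    position: int
    strand: str
    name: str = ""


@dataclass
class MetaplotProfile:
    """Per-offset summed (or averaged) scores, one series per strand class
    and condition; offsets run -W..+W in the direction of transcription."""

    window: int = DEFAULT_WINDOW
    series: dict[str, np.ndarray] = field(default_factory=dict)
    n_regions: int = 0

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def get(self, key: str) -> np.ndarray:
        if key not in self.series:
            raise KeyError(
                f"metaplot series {key!r} missing; have {sorted(self.series)}"
            )
        return self.series[key]


def assign_proximal_refpoints(
    reads: Sequence[ReadRecord], refpoints: Sequence[RefPoint]
) -> list[RefPoint | None]:
    """Nearest reference point per read, by read-midpoint distance.

    Ties go to the reference point with the smaller genomic coordinate;
    reads on chromosomes without reference points map to None.
    """
    by_chrom: dict[str, list[RefPoint]] = {}
    for rp in refpoints:
        by_chrom.setdefault(rp.chrom, []).append(rp)
    for lst in by_chrom.values():
        lst.sort(key=lambda rp: rp.position)
    positions = {c: np.array([rp.position for rp in lst])
                 for c, lst in by_chrom.items()}

    out: list[RefPoint | None] = []
    for read in reads:
        lst = by_chrom.get(read.chrom)
        if not lst:
            out.append(None)
            continue
        pos = positions[read.chrom]
        mid = (read.start + read.end - 1) / 2.0
        i = int(np.searchsorted(pos, mid))
        candidates = [j for j in (i - 1, i) if 0 <= j < len(lst)]
        # smaller coordinate wins ties: prefer the earlier candidate on equality
        best = min(candidates, key=lambda j: (abs(pos[j] - mid), pos[j]))
        out.append(lst[best])
    return out


def score_metaplot(
    reads: Sequence[ReadRecord],
    scores: np.ndarray,
    refpoints: Sequence[RefPoint],
    window: int = DEFAULT_WINDOW,
    series_key: str | None = None,
    reducer: str = "sum",
) -> MetaplotProfile:
    """Aggregate read scores by gene-oriented offset from proximal refpoints.

    Returns a profile with series ``NT`` (read effective strand = gene coding
    strand) and ``T`` (opposite), or ``<series_key>_NT`` / ``<series_key>_T``
    when a key (e.g. a condition label) is given.  ``reducer`` is ``sum``
    (default) or ``mean`` (divide by the number of reference points).
    """
    if reducer not in ("sum", "mean"):
        raise ValueError(f"reducer must be 'sum' or 'mean', got {reducer!r}")
    width = 2 * window + 1
    nt = np.zeros(width)
    t = np.zeros(width)
    assignments = assign_proximal_refpoints(reads, refpoints)
    for read, score, rp in zip(reads, scores, assignments):
        if rp is None or score == 0:
            continue
        positions = np.arange(read.start, read.end)
        offsets = positions - rp.position if rp.strand == "+" else rp.position - positions
        inside = offsets[np.abs(offsets) <= window] + window
        if not len(inside):
            continue
        target = nt if read_effective_strand(read) == rp.strand else t
        np.add.at(target, inside, float(score))
    if reducer == "mean" and refpoints:
        nt /= len(refpoints)
        t /= len(refpoints)
    prefix = f"{series_key}_" if series_key else ""
    return MetaplotProfile(
        window=window,
        series={f"{prefix}NT": nt, f"{prefix}T": t},
        n_regions=len(refpoints),
    )


def combine_profiles(profiles: Sequence[MetaplotProfile],
                     reducer: str = "mean") -> MetaplotProfile:
    """Merge per-sample profiles; shared series are averaged (or summed)."""
    if not profiles:
        raise ValueError("no profiles to combine")
    window = profiles[0].window
    if any(p.window != window for p in profiles):
        raise ValueError("profiles have differing windows")
    keys: dict[str, list[np.ndarray]] = {}
    for p in profiles:
        for k, v in p.series.items():
            keys.setdefault(k, []).append(v)
    series = {
        k: (np.mean(vs, axis=0) if reducer == "mean" else np.sum(vs, axis=0))
        for k, vs in keys.items()
    }
    return MetaplotProfile(window=window, series=series,
                           n_regions=profiles[0].n_regions)


def rloop_signal(profile: MetaplotProfile) -> np.ndarray:
    """(ctrl_NT - tpl_NT) - (ctrl_T - tpl_T), per offset."""
    ctrl_nt, ctrl_t = profile.get("ctrl_NT"), profile.get("ctrl_T")
    tpl_nt, tpl_t = profile.get("tpl_NT"), profile.get("tpl_T")
    return (ctrl_nt - tpl_nt) - (ctrl_t - tpl_t)


def conversion_metaplot(
    reads: Sequence[ReadRecord],
    refpoints: Sequence[RefPoint],
    window: int = DEFAULT_WINDOW,
) -> dict[str, np.ndarray]:
    """Summed converted-cytosine counts per offset, split NT/T."""
    width = 2 * window + 1
    out = {"NT": np.zeros(width), "T": np.zeros(width)}
    assignments = assign_proximal_refpoints(reads, refpoints)
    for read, rp in zip(reads, assignments):
        if rp is None or not read.converted_positions:
            continue
        positions = np.array(read.converted_positions)
        offsets = positions - rp.position if rp.strand == "+" else rp.position - positions
        inside = offsets[np.abs(offsets) <= window] + window
        if not len(inside):
            continue
        key = "NT" if read.conversion_strand == rp.strand else "T"
        np.add.at(out[key], inside, 1.0)
    return out


def conversion_asymmetry_metaplot(
    control_samples: Sequence[Sequence[ReadRecord]],
    triptolide_samples: Sequence[Sequence[ReadRecord]],
    refpoints: Sequence[RefPoint],
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """log2 ratio of inhibitor-corrected conversion counts, NT over T.

    Per offset: mean per-sample conversion counts per strand and condition;
    the triptolide-condition mean is subtracted from the control mean
    (negative corrected counts clamped to 0), and the profile is
    log2((NT_corr + 1) / (T_corr + 1)).
    """
    def condition_mean(samples):
        maps = [conversion_metaplot(s, refpoints, window) for s in samples]
        return {
            k: np.mean([m[k] for m in maps], axis=0) for k in ("NT", "T")
        }

    ctrl = condition_mean(control_samples)
    tpl = condition_mean(triptolide_samples)
    nt_corr = np.clip(ctrl["NT"] - tpl["NT"], 0.0, None)
    t_corr = np.clip(ctrl["T"] - tpl["T"], 0.0, None)
    return np.log2(nt_corr + 1.0) - np.log2(t_corr + 1.0)


def smooth_profile(values: np.ndarray, width: int) -> np.ndarray:
    """Moving average with edge-corrected denominators.

    Single-locus per-base profiles are shot-noise dominated (one read spans
    ~100 offsets, so a couple of high-scoring background reads can stack into
    a narrow spurious spike); averaging over a read-length-scale window
    before boundary detection suppresses such spikes while leaving the
    half-maximum crossing of a plateau centered on the plateau's true edge.
    """
    if width <= 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(width)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return num / den


def half_max_boundary(signal: np.ndarray, window: int,
                      side: str = "three_prime",
                      mode: str = "global") -> int | None:
    """Outermost offset where the R-loop signal reaches half its maximum.

    ``three_prime``: largest offset with signal >= max/2; ``five_prime``:
    smallest such offset.  None when the maximum is not positive.

    ``mode='global'`` scans the whole profile — the natural reading for
    aggregate metaplots, which decay monotonically away from their peak.
    ``mode='main_peak'`` restricts the search to the contiguous run of
    above-half-maximum offsets containing the global maximum; on single-locus
    profiles, where isolated shot-noise bumps elsewhere in the window can
    brush the half-maximum level, this returns the boundary of the peak
    itself.  The two modes agree whenever the above-half set is contiguous.
    """
    if side not in ("three_prime", "five_prime"):
        raise ValueError(f"side must be 'three_prime' or 'five_prime', got {side!r}")
    if mode not in ("global", "main_peak"):
        raise ValueError(f"mode must be 'global' or 'main_peak', got {mode!r}")
    peak = float(np.max(signal))
    if peak <= 0:
        return None
    above = signal >= peak / 2.0
    if mode == "main_peak":
        i = int(np.argmax(signal))
        lo = hi = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        while hi < len(signal) - 1 and above[hi + 1]:
            hi += 1
        idx = hi if side == "three_prime" else lo
        return int(idx - window)
    at_half = np.flatnonzero(above)
    idx = at_half[-1] if side == "three_prime" else at_half[0]
    return int(idx - window)


def strand_asymmetry(s_nt: float, s_t: float) -> float:
    """log2-fold non-template over template score, with +1 pseudocounts."""
    if s_nt < 0 or s_t < 0:
        raise ValueError("strand scores must be non-negative")
    return float(np.log2(s_nt + 1.0) - np.log2(s_t + 1.0))
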
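"""Nonparametric tests and the metaplot multiple-testing correction.

Comparisons between groups use the two-sided rank test: the unpaired
two-sample (rank-sum / Mann-Whitney) form by default, matching the stated
``paired = FALSE`` usage; the paired signed-rank form is also available.
Correlations use Spearman's rho with the asymptotic t approximation.
Metaplot p-values are Bonferroni-corrected by the number of offsets tested
(2001 for a ±1000 bp window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    corrected_p: float | None = None
    n_positions_tested: int | None = None

    def corrected(self, window: int) -> "TestResult":
        """Attach the metaplot Bonferroni correction for a ±window profile."""
        factor = 2 * window + 1
        return TestResult(
            statistic=self.statistic,
            p_value=self.p_value,
            method=self.method,
            corrected_p=metaplot_correction(self.p_value, window),
            n_positions_tested=factor,
        )


def rank_test(x, y, paired: bool = False) -> TestResult:
    """Two-sided rank test between two samples.

    Unpaired (default): two-sample rank-sum (Mann-Whitney U), exact null
    distribution for small tie-free samples, normal approximation otherwise.
    Paired: signed-rank test on the differences, requiring equal lengths.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_test requires nonempty samples")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired rank test requires equal-length samples")
        res = sps.wilcoxon(x, y, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue),
                          method="wilcoxon_signed_rank")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue),
                      method="wilcoxon_rank_sum")


def spearman_test(x, y) -> TestResult:
    """Spearman rank correlation with the asymptotic t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_test requires equal-length samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman correlation undefined for a constant vector")
    rho, _ = sps.spearmanr(x, y)
    n = len(x)
    # asymptotic t approximation: t = rho * sqrt((n-2) / (1-rho^2))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(float(rho), p, method="spearman_t_approx")


def metaplot_correction(p: float, window: int = 1000) -> float:
    """Bonferroni correction over the 2*window+1 offsets of a metaplot.

    min(1, p * (2W + 1)); the factor is 2001 at the default ±1000 bp window.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    return min(1.0, p * (2 * window + 1))
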
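import math

import numpy as np
import pytest

from bisdrip.scoring import (
    ScoringError,
    assign_read_scores,
    build_score_model,
    cytosine_normalize,
    estimate_background_rate,
    expected_reads,
    normalize_or_zero,
    normalize_scores,
)
from bisdrip.simulate import SimConfig, simulate_dataset

from conftest import make_read, random_reads


def reads_with_counts(pairs):
    """pairs: iterable of (n_cytosines, n_converted)."""
    out = []
    for i, (n, c) in enumerate(pairs):
        positions = list(range(100, 100 + n))
        out.append(
            make_read(read_id=f"r{i}", start=100, end=100 + max(n, 1),
                      converted=positions[:c], unconverted=positions[c:])
        )
    return out


# --------------------------------------------------------------------------
# Independent brute-force oracle: a literal transcription of the published
# per-bin / cumulative-tail / small-group-inheritance rules, written against
# plain dict/float arithmetic with no code shared with the implementation.


def oracle_scores(counts_by_n, p, min_group=1000, min_expected=5.0):
    """counts_by_n: {n: {c: observed}} -> {(n, c): score}."""

    def pmf(n, c):
        return math.comb(n, c) * p**c * (1 - p) ** (n - c)

    scores = {}
    scored_group_scores = {}
    for n in sorted(counts_by_n):
        if n == 0:
            scores[(0, 0)] = 0.0
            continue
        obs = counts_by_n[n]
        N = sum(obs.values())
        O = [obs.get(c, 0) for c in range(n + 1)]
        E = [N * pmf(n, c) for c in range(n + 1)]
        group = {}
        if N > min_group:
            mode = "per_bin"
            for c in range(n + 1):
                if mode == "per_bin" and E[c] <= min_expected:
                    mode = "tail"
                if mode == "per_bin":
                    group[c] = 1 - E[c] / O[c] if O[c] > E[c] else 0.0
                else:
                    tail_E = sum(E[c:])
                    tail_O = sum(O[c:])
                    if tail_E > min_expected:
                        group[c] = 1 - tail_E / tail_O if tail_O > tail_E else 0.0
                    else:
                        group[c] = group[c - 1] if c > 0 else 0.0
            scored_group_scores[n] = group
        else:
            donors = [m for m in scored_group_scores if m < n]
            if donors:
                donor = scored_group_scores[max(donors)]
                for c in range(n + 1):
                    group[c] = donor[min(c, max(donors))]
            else:
                group = {c: 0.0 for c in range(n + 1)}
        for c in range(n + 1):
            scores[(n, c)] = group[c]
    return scores


class TestBackgroundRate:
    def test_all_unconverted_reads_give_zero(self):
        reads = reads_with_counts([(10, 0)] * 10)
        assert estimate_background_rate(reads) == 0.0

    def test_single_fully_converted_outlier_is_excluded(self):
        # initial rate 10/100 = 0.1; the 10/10 read (fraction 1.0 > 0.25)
        # is dropped, leaving 0 conversions among 90 cytosines
        reads = reads_with_counts([(10, 10)] + [(10, 0)] * 9)
        assert estimate_background_rate(reads) == 0.0

    def test_homogeneous_sample_is_unchanged_by_exclusion(self):
        reads = reads_with_counts([(10, 1)] * 20)
        assert estimate_background_rate(reads) == pytest.approx(0.1)

    def test_no_cytosines_is_an_error(self):
        reads = [make_read()]
        with pytest.raises(ScoringError):
            estimate_background_rate(reads)


class TestExpectedReads:
    def test_degenerate_p_zero(self):
        assert expected_reads(500, 4, 0, 0.0) == 500
        assert expected_reads(500, 4, 2, 0.0) == 0

    def test_hand_expanded_pmf(self):
        # N * C(2,1) * p * (1-p) = 1000 * 2 * 0.1 * 0.9
        assert expected_reads(1000, 2, 1, 0.1) == pytest.approx(180.0)

    @pytest.mark.parametrize("N,n,p", [(1000, 5, 0.1), (37, 12, 0.7), (4, 1, 0.0)])
    def test_expectations_sum_to_N(self, N, n, p):
        total = sum(expected_reads(N, n, c, p) for c in range(n + 1))
        assert total == pytest.approx(N)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            expected_reads(10, 3, 4, 0.1)
        with pytest.raises(ValueError):
            expected_reads(10, 3, 1, 1.5)
        with pytest.raises(ValueError):
            expected_reads(-1, 3, 1, 0.5)


class TestScoreModel:
    def test_enriched_bin_score_is_one_minus_E_over_O(self):
        # n=2, p=0.1, N=2000: E = [1620, 360, 20], all above the cutoff, so
        # every bin uses the per-bin formula; the enriched c=2 bin with
        # O=100 against E=20 scores 1 - 20/100 = 0.8
        pairs = [(2, 0)] * 1700 + [(2, 1)] * 200 + [(2, 2)] * 100
        reads = reads_with_counts(pairs)
        model = build_score_model(reads, background_rate=0.1)
        assert model.score(2, 2) == pytest.approx(0.8)
        assert model.score(2, 0) == pytest.approx(1 - 1620 / 1700)

    def test_sparse_tail_inherits_score_from_last_pooled_bin(self):
        # deep tail bins whose cumulative expectation is below the cutoff
        # take the previous conversion count's score, even when heavily
        # enriched -- the published pooling rule, confirmed by the oracle
        counts = {10: {0: 1000, 9: 100, 10: 1}}
        expected = oracle_scores(counts, 0.01)
        assert expected[(10, 9)] == expected[(10, 2)]
        pairs = [(10, 0)] * 1000 + [(10, 9)] * 100 + [(10, 10)]
        model = build_score_model(reads_with_counts(pairs), background_rate=0.01)
        assert model.score(10, 9) == pytest.approx(expected[(10, 9)], abs=1e-12)

    def test_bin_with_O_at_most_E_scores_zero(self):
        reads = reads_with_counts([(5, 0)] * 1500)
        model = build_score_model(reads, background_rate=0.0)
        assert model.score(5, 0) == 0.0

    def test_small_group_inherits_from_next_smaller_scored_group(self):
        pairs = [(10, 0)] * 1200 + [(10, 2)] * 30 + [(11, 2)] * 5
        reads = reads_with_counts(pairs)
        model = build_score_model(reads, background_rate=0.005)
        assert model.score(11, 2) == model.score(10, 2)
        assert model.bins[(11, 2)].inherited_from == 10

    def test_inheritance_with_no_scored_donor_scores_zero(self):
        reads = reads_with_counts([(4, 2)] * 50)  # group far below 1000 reads
        model = build_score_model(reads, background_rate=0.01)
        assert model.score(4, 2) == 0.0

    def test_observed_counts_partition_group_sizes(self):
        rng = np.random.default_rng(0)
        reads = random_reads(rng, 1500, n_cytosines=6, p=0.05)
        model = build_score_model(reads)
        for n, size in model.group_sizes.items():
            total_O = sum(b.O for (bn, _), b in model.bins.items() if bn == n)
            assert total_O == size
            total_E = sum(b.E for (bn, _), b in model.bins.items() if bn == n)
            assert total_E == pytest.approx(size, rel=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_model_matches_brute_force_oracle_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(50, 5000))
        n_max = int(rng.integers(2, 20))
        p_true = float(rng.uniform(0.001, 0.05))
        ns = rng.integers(1, n_max + 1, size=N)
        cs = rng.binomial(ns, p_true)
        # sprinkle a high-conversion subpopulation to exercise the tails
        hot = rng.random(N) < 0.05
        cs[hot] = np.minimum(ns[hot], rng.integers(1, n_max + 1, size=N)[hot])
        reads = reads_with_counts(list(zip(ns.tolist(), cs.tolist())))
        model = build_score_model(reads)
        counts = {}
        for n, c in zip(ns.tolist(), cs.tolist()):
            counts.setdefault(n, {}).setdefault(c, 0)
            counts[n][c] += 1
        expected = oracle_scores(counts, model.background_rate)
        for (n, c), score in expected.items():
            assert model.score(n, c) == pytest.approx(score, abs=1e-12), (n, c)

    def test_scores_lie_in_unit_interval(self):
        rng = np.random.default_rng(5)
        reads = random_reads(rng, 3000, n_cytosines=12, p=0.02)
        model = build_score_model(reads)
        raw = assign_read_scores(reads, model)
        assert np.all(raw >= 0) and np.all(raw < 1)

    def test_identical_bins_get_identical_scores(self):
        reads = reads_with_counts([(8, 3), (8, 3)] + [(8, 0)] * 1100)
        model = build_score_model(reads, background_rate=0.01)
        raw = assign_read_scores(reads, model)
        assert raw[0] == raw[1]

    def test_missing_bin_is_a_consistency_error(self):
        reads = reads_with_counts([(5, 0)] * 1100)
        model = build_score_model(reads, background_rate=0.01)
        foreign = reads_with_counts([(9, 4)])
        with pytest.raises(ScoringError, match="n=9"):
            assign_read_scores(foreign, model)


class TestEnrichmentQC:
    def test_sample_with_positive_high_conversion_bins_passes(self):
        pairs = [(10, 0)] * 1500 + [(10, 2)] * 30 + [(10, 8)] * 60
        model = build_score_model(reads_with_counts(pairs),
                                  background_rate=0.01)
        from bisdrip.scoring import detects_enrichment
        assert model.score(10, 8) > 0
        assert detects_enrichment(model)

    def test_sample_with_all_zero_tail_is_flagged(self):
        # O at c=2 sits below E, so the tail inherits zero everywhere:
        # the sample registers no enrichment at any conversion count >= 3
        from bisdrip.scoring import detects_enrichment
        pairs = [(10, 0)] * 1800 + [(10, 1)] * 150 + [(10, 2)] * 5 \
            + [(10, 8)] * 45
        model = build_score_model(reads_with_counts(pairs),
                                  background_rate=0.013)
        assert model.score(10, 8) == 0.0
        assert not detects_enrichment(model)


class TestNormalization:
    def test_single_positive_read_takes_the_whole_total(self):
        out = normalize_scores(np.array([0.4]))
        assert out[0] == pytest.approx(1_000_000.0)

    def test_proportional_split(self):
        out = normalize_scores(np.array([1.0, 3.0]))
        np.testing.assert_allclose(out, [250_000.0, 750_000.0])

    def test_sum_is_the_normalization_total_for_arbitrary_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            raw = rng.uniform(0, 1, size=rng.integers(2, 400))
            assert normalize_scores(raw).sum() == pytest.approx(1e6, rel=1e-9)

    def test_all_zero_sample_is_an_error_but_zero_helper_passes(self):
        with pytest.raises(ScoringError):
            normalize_scores(np.zeros(5))
        assert normalize_or_zero(np.zeros(5)).sum() == 0.0


class TestCytosineNormalization:
    def _reads_with_group_scores(self):
        reads = reads_with_counts([(4, 0)] * 3 + [(8, 0)] * 3)
        raw = np.array([2.0, 2.0, 2.0, 4.0, 4.0, 4.0])
        return reads, raw

    def test_group_means_equalized(self):
        reads, raw = self._reads_with_group_scores()
        out, factors = cytosine_normalize(reads, raw)
        ns = np.array([r.n_cytosines for r in reads])
        means = [out[ns == n].mean() for n in (4, 8)]
        assert means[0] == pytest.approx(means[1])
        assert factors[4] == pytest.approx(1.5)
        assert factors[8] == pytest.approx(0.75)

    def test_total_is_one_million(self):
        reads, raw = self._reads_with_group_scores()
        out, _ = cytosine_normalize(reads, raw)
        assert out.sum() == pytest.approx(1e6, rel=1e-9)

    def test_equal_means_reduce_to_identity_reweighting(self):
        reads = reads_with_counts([(4, 0)] * 2 + [(8, 0)] * 2)
        raw = np.array([1.0, 3.0, 2.0, 2.0])
        out, factors = cytosine_normalize(reads, raw)
        np.testing.assert_allclose(out, normalize_scores(raw))
        assert factors == {4: 1.0, 8: 1.0}

    def test_all_zero_group_is_left_at_zero_and_reported(self):
        reads = reads_with_counts([(4, 0)] * 2 + [(8, 0)] * 2)
        raw = np.array([0.0, 0.0, 2.0, 6.0])
        out, factors = cytosine_normalize(reads, raw)
        ns = np.array([r.n_cytosines for r in reads])
        assert out[ns == 4].sum() == 0.0
        assert factors[4] == 0.0


class TestMonotonicity:
    def test_higher_inloop_rate_never_lowers_mean_rloop_read_score(self):
        """Stochastic monotonicity: stronger implanted conversion -> scores
        of in-loop reads do not decrease (fixed seeds)."""
        means = []
        for p_loop in (0.3, 0.5, 0.8):
            ds = simulate_dataset(
                SimConfig(seed=123, p_loop=p_loop, n_genes=8, n_rloop_genes=2,
                          chrom_length=500_000, gene_spacing=30_000)
            )
            _, reads = ds.samples["cont_1"]
            model = build_score_model(reads)
            raw = assign_read_scores(reads, model)
            hot = [
                i for i, r in enumerate(reads)
                if any(t.chrom == r.chrom and r.start < t.end and t.start < r.end
                       and r.conversion_strand == t.displaced_strand
                       for t in ds.truth)
            ]
            means.append(raw[hot].mean())
        assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9
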
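import numpy as np
import pytest
from scipy import stats

from cnvpop import (
    CnvConfigError,
    GeneSpan,
    SimConfig,
    deletion_carrier_count,
    gene_deletion_scores,
    normal_tail_pvalues,
    overlap_features,
    select_significant_genes,
    simulate_callset,
)
from cnvpop.core import MISSING
from cnvpop.genes import attach_pvalues, carrier_counts, rank_tail_pvalues

from conftest import brute_force_overlaps, build_callset, two_breed_samples


class TestCarrierCount:
    def test_counts_het_and_hom_carriers(self):
        assert deletion_carrier_count(np.array([0, 1, 2, 0])) == 2

    def test_all_reference_is_zero(self):
        assert deletion_carrier_count(np.zeros(5, dtype=int)) == 0

    def test_missing_raises(self):
        with pytest.raises(CnvConfigError, match="filter"):
            deletion_carrier_count(np.array([0, MISSING, 1]))

    def test_matches_elementwise_scan(self):
        rng = np.random.default_rng(17)
        row = rng.integers(0, 3, size=32)
        assert deletion_carrier_count(row) == sum(1 for g in row if g >= 1)

    def test_allele_mode_sums_dosage(self):
        cs = build_callset(
            [("c1", "chr1", 1, 10, [2, 1, 0])],
            two_breed_samples(2, 1),
        )
        assert carrier_counts(cs, "carrier").tolist() == [2]
        assert carrier_counts(cs, "allele").tolist() == [3]


class TestOverlap:
    def _cs(self, intervals):
        return build_callset(
            [
                (f"c{i}", chrom, s, e, [1, 1])
                for i, (chrom, s, e) in enumerate(intervals)
            ],
            two_breed_samples(1, 1),
        )

    def test_one_shared_base_overlaps(self):
        cs = self._cs([("chr1", 100, 200)])
        genes = [GeneSpan("g", "chr1", 200, 300)]
        assert overlap_features(cs, genes) == {"g": ["c0"]}

    def test_adjacent_disjoint(self):
        cs = self._cs([("chr1", 100, 200)])
        genes = [GeneSpan("g", "chr1", 201, 300)]
        assert overlap_features(cs, genes) == {}

    def test_chromosome_mismatch_disjoint(self):
        cs = self._cs([("chr1", 100, 200)])
        genes = [GeneSpan("g", "chr2", 100, 200)]
        assert overlap_features(cs, genes) == {}

    def test_random_intervals_match_brute_force(self):
        rng = np.random.default_rng(23)
        cs = self._cs(
            [
                (f"chr{rng.integers(1, 4)}", int(s), int(s + rng.integers(1, 500)))
                for s in rng.integers(1, 20_000, size=300)
            ]
        )
        genes = [
            GeneSpan(
                f"g{i}",
                f"chr{rng.integers(1, 4)}",
                int(s),
                int(s + rng.integers(1, 2_000)),
            )
            for i, s in enumerate(rng.integers(1, 20_000, size=80))
        ]
        assert overlap_features(cs, genes) == brute_force_overlaps(cs, genes)


class TestGeneScores:
    def test_sums_carrier_counts(self):
        cs = build_callset(
            [
                ("c1", "chr1", 100, 200, [2, 1, 1, 2, 1, 0, 0]),  # 5 carriers
                ("c2", "chr1", 150, 400, [1, 1, 1, 0, 0, 0, 0]),  # 3 carriers
            ],
            two_breed_samples(4, 3),
        )
        genes = [GeneSpan("g", "chr1", 120, 300)]
        (score,) = gene_deletion_scores(cs, genes)
        assert (score.score, score.l) == (8, 2)

    def test_minimum_score_single_carrier(self):
        cs = build_callset(
            [("c1", "chr1", 100, 200, [1, 0, 0])], two_breed_samples(2, 1)
        )
        (score,) = gene_deletion_scores(cs, [GeneSpan("g", "chr1", 50, 150)])
        assert score.score == 1 and score.l == 1

    def test_cnv_spanning_k_genes_counts_in_each(self):
        cs = build_callset(
            [("c1", "chr1", 100, 1000, [1, 1, 0])], two_breed_samples(2, 1)
        )
        genes = [GeneSpan("g1", "chr1", 50, 300), GeneSpan("g2", "chr1", 500, 800)]
        scores = gene_deletion_scores(cs, genes)
        assert [s.score for s in scores] == [2, 2]

    def test_additivity_of_cnv_removal(self):
        """Dropping one CNV lowers affected gene scores by its carrier count."""
        cs, _ = simulate_callset(SimConfig(n_cnvs=150, seed=31))
        from cnvpop import simulate_features

        rng = np.random.default_rng(5)
        picks = rng.choice(cs.n_cnvs, size=8, replace=False)
        plan = {f"g{k}": [cs.cnv_ids[i]] for k, i in enumerate(picks)}
        genes, _, _ = simulate_features(cs, n_genes=0, gene_plan=plan, seed=6)
        before = {s.gene_id: s.score for s in gene_deletion_scores(cs, genes)}
        drop = cs.cnv_ids[picks[0]]
        drop_count = int((cs.genotypes[picks[0]] >= 1).sum())
        smaller = cs.subset(np.array([c != drop for c in cs.cnv_ids]))
        after = {s.gene_id: s.score for s in gene_deletion_scores(smaller, genes)}
        assert before["g0"] - after.get("g0", 0) == drop_count
        for g in before:
            if g != "g0":
                assert after[g] == before[g]

    def test_score_bounds(self):
        cs, _ = simulate_callset(SimConfig(n_cnvs=300, seed=8))
        carriers = (cs.genotypes >= 1).sum(axis=1)
        cs = cs.subset(carriers > 0)
        from cnvpop import simulate_features

        rng = np.random.default_rng(9)
        picks = rng.choice(cs.n_cnvs, size=10, replace=False)
        plan = {f"g{k}": [cs.cnv_ids[i]] for k, i in enumerate(picks)}
        genes, _, _ = simulate_features(cs, gene_plan=plan, seed=10)
        for s in gene_deletion_scores(cs, genes):
            assert 1 <= s.score <= s.l * cs.n_samples


class TestTailPvalues:
    def test_mean_score_gets_half(self):
        scores = [1, 2, 3, 4, 5]
        ps = normal_tail_pvalues(scores)
        assert ps[2] == pytest.approx(0.5)

    def test_frozen_value_top_of_1_to_10(self):
        # z = (10 - 5.5) / 3.02765 = 1.48630, upper tail 0.068624
        ps = normal_tail_pvalues(list(range(1, 11)))
        z = (10 - 5.5) / np.std(range(1, 11), ddof=1)
        assert ps[-1] == pytest.approx(stats.norm.sf(z))
        assert ps[-1] == pytest.approx(0.0686, abs=2e-4)

    def test_symmetric_pair_sums_to_one(self):
        ps = normal_tail_pvalues([2, 4, 6, 8])
        assert ps[0] + ps[3] == pytest.approx(1.0)
        assert ps[1] + ps[2] == pytest.approx(1.0)

    def test_monotone_decreasing_in_score(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(1, 100, size=50)
        ps = normal_tail_pvalues(scores)
        order = np.argsort(scores)
        assert (np.diff(ps[order]) <= 0).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(CnvConfigError, match="variance"):
            normal_tail_pvalues([3, 3, 3, 3])

    def test_needs_three_scores(self):
        with pytest.raises(CnvConfigError, match=">= 3"):
            normal_tail_pvalues([1, 2])

    def test_rank_pvalues_count_ties(self):
        ps = rank_tail_pvalues([5, 1, 5, 3])
        assert ps.tolist() == [0.5, 1.0, 0.5, 0.75]


class TestSelectSignificant:
    def test_empty_when_nothing_extreme(self):
        cs = build_callset(
            [
                ("c1", "chr1", 100, 200, [1, 1, 0]),
                ("c2", "chr2", 100, 200, [1, 0, 0]),
                ("c3", "chr3", 100, 200, [1, 1, 1]),
            ],
            two_breed_samples(2, 1),
        )
        genes = [
            GeneSpan("g1", "chr1", 1, 500),
            GeneSpan("g2", "chr2", 1, 500),
            GeneSpan("g3", "chr3", 1, 500),
        ]
        scored = attach_pvalues(gene_deletion_scores(cs, genes))
        assert select_significant_genes(scored, alpha=0.01) == []

    def test_planted_extreme_gene_selected(self):
        """One gene overlapping ten full-carrier CNVs sits far in the tail."""
        rows = [(f"c{i}", "chr1", 10_000 * i, 10_000 * i + 100, [1, 0, 0])
                for i in range(30)]
        rows += [(f"x{i}", "chr2", 1_000 + 10 * i, 1_005 + 10 * i, [1, 1, 1])
                 for i in range(10)]
        cs = build_callset(rows, two_breed_samples(2, 1))
        genes = [GeneSpan(f"g{i}", "chr1", 10_000 * i, 10_000 * i + 100)
                 for i in range(30)]
        genes.append(GeneSpan("gBig", "chr2", 1, 2_000))
        scored = attach_pvalues(gene_deletion_scores(cs, genes))
        sig = select_significant_genes(scored, alpha=0.01)
        assert [s.gene_id for s in sig] == ["gBig"]
        z = (30 - np.mean([s.score for s in scored])) / np.std(
            [s.score for s in scored], ddof=1
        )
        assert stats.norm.sf(z) < 0.01  # confirmed against the fitted normal

    def test_sorted_by_score_then_id(self):
        from cnvpop.genes import GeneScore

        scores = [
            GeneScore("b", None, 1, 10, ("c",), p_value=0.001),
            GeneScore("a", None, 1, 10, ("c",), p_value=0.001),
            GeneScore("z", None, 1, 50, ("c",), p_value=0.0001),
        ]
        assert [s.gene_id for s in select_significant_genes(scores)] == ["z", "a", "b"]
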
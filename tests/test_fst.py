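import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvpop import (
    CnvConfigError,
    GeneSpan,
    SimConfig,
    benjamini_hochberg,
    breed_allele_frequencies,
    fst_scan,
    fst_significance,
    nei_fst,
    simulate_callset,
)
from cnvpop.fst import BreedFreq, annotate_selected, breed_weights

from conftest import brute_force_bh, build_callset, two_breed_samples


def _freqs(p1, p2, c1=22 / 32):
    return (
        BreedFreq("b1", 22, c1, p1),
        BreedFreq("b2", 10, 1 - c1, p2),
    )


class TestBreedFrequencies:
    def test_three_hets_of_ten(self):
        cs = build_callset(
            [("c", "chr1", 1, 10, [0] * 22 + [1, 1, 1] + [0] * 7)],
            two_breed_samples(22, 10),
        )
        (fr,) = breed_allele_frequencies(cs)
        assert fr[1].p == pytest.approx(3 / 20)

    def test_hanwoo_hom_and_het_counts(self):
        cs = build_callset(
            [("c", "chr1", 1, 10, [2] * 13 + [1] * 9 + [0] * 10)],
            two_breed_samples(22, 10),
        )
        (fr,) = breed_allele_frequencies(cs)
        assert fr[0].p == pytest.approx(35 / 44)

    def test_all_reference_zero(self):
        cs = build_callset(
            [("c", "chr1", 1, 10, [0] * 5)], two_breed_samples(3, 2)
        )
        (fr,) = breed_allele_frequencies(cs)
        assert fr[0].p == 0 and fr[1].p == 0

    def test_sample_weights_sum_to_one(self):
        assert breed_weights([22, 10]).tolist() == [22 / 32, 10 / 32]
        assert breed_weights([22, 10], "equal").tolist() == [0.5, 0.5]
        with pytest.raises(CnvConfigError):
            breed_weights([5, 0])


class TestNeiFst:
    def test_no_differentiation(self):
        _, _, f = nei_fst(_freqs(0.3, 0.3))
        assert f == pytest.approx(0.0, abs=1e-15)

    def test_fixed_difference(self):
        h_obs, h_exp, f = nei_fst(_freqs(1.0, 0.0))
        assert h_obs == 0
        assert f == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        h_obs, h_exp, f = nei_fst(_freqs(0.0, 0.0))
        assert h_exp == 0 and np.isnan(f)

    def test_weights_must_sum_to_one(self):
        bad = (BreedFreq("a", 5, 0.5, 0.2), BreedFreq("b", 5, 0.3, 0.4))
        with pytest.raises(CnvConfigError, match="sum"):
            nei_fst(bad)

    @settings(deadline=None, max_examples=200)
    @given(
        # exact fixation (0 and 1) is meaningful; frequencies closer to the
        # boundary than any 2n-allele grid allows (1/2n >= 1/64 here) only
        # probe float cancellation, not the algebra
        p1=st.one_of(st.sampled_from([0.0, 1.0]), st.floats(0.001, 0.999)),
        p2=st.one_of(st.sampled_from([0.0, 1.0]), st.floats(0.001, 0.999)),
        c1=st.floats(0.01, 0.99),
    )
    def test_matches_weighted_variance_form(self, p1, p2, c1):
        """F from heterozygosities equals Var_c(p) / (pbar * qbar)."""
        h_obs, h_exp, f = nei_fst(_freqs(p1, p2, c1))
        pbar = c1 * p1 + (1 - c1) * p2
        var_c = c1 * (p1 - pbar) ** 2 + (1 - c1) * (p2 - pbar) ** 2
        if h_exp == 0:
            assert np.isnan(f)
        else:
            assert f == pytest.approx(
                var_c / (pbar * (1 - pbar)), rel=1e-6, abs=1e-12
            )
            assert -1e-12 <= f <= 1 + 1e-12

    @settings(deadline=None, max_examples=200)
    @given(
        # keep 1 - p exactly representable so relabeling is lossless
        p1=st.floats(0.001, 0.999),
        p2=st.floats(0.001, 0.999),
        c1=st.floats(0.01, 0.99),
    )
    def test_allele_relabel_invariance(self, p1, p2, c1):
        _, _, f = nei_fst(_freqs(p1, p2, c1))
        _, _, g = nei_fst(_freqs(1 - p1, 1 - p2, c1))
        if np.isnan(f):
            assert np.isnan(g) or g == pytest.approx(f, nan_ok=True)
        else:
            assert g == pytest.approx(f, abs=1e-12, nan_ok=True)


class TestScan:
    def test_trivial_pair(self):
        cs = build_callset(
            [
                ("same", "chr1", 1, 10, [1] * 22 + [1] * 10),
                ("fixed", "chr1", 20, 30, [2] * 22 + [0] * 10),
            ],
            two_breed_samples(22, 10),
        )
        results = fst_scan(cs)
        assert results[0].fst == pytest.approx(0.0, abs=1e-15)
        assert results[1].fst == pytest.approx(1.0)

    def test_null_distribution_near_zero(self):
        """Equal breed frequencies: only sampling noise differentiates."""
        cfg = SimConfig(
            n_cnvs=1000,
            seed=55,
            frac_differentiated=0,
            frac_specific_b1=0,
            frac_specific_b2=0,
            frac_monomorphic=0,
        )
        cs, _ = simulate_callset(cfg)
        fvals = np.array([r.fst for r in fst_scan(cs) if r.defined])
        assert fvals.mean() < 0.05
        assert (fvals >= -1e-12).all() and (fvals <= 1 + 1e-12).all()

    def test_requires_two_breeds(self):
        cs = build_callset(
            [("c", "chr1", 1, 10, [1, 1])],
            [*two_breed_samples(2, 0)][:2],
        )
        with pytest.raises(CnvConfigError, match="2 breeds"):
            fst_scan(cs)


class TestSignificance:
    def test_bh_frozen_example(self):
        got = benjamini_hochberg([0.001, 0.008, 0.039, 0.041])
        assert got == pytest.approx([0.004, 0.016, 0.041, 0.041])

    def test_bh_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            assert benjamini_hochberg(p) == pytest.approx(brute_force_bh(p))

    def test_bh_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(100)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()

    def test_rank_method_identical_values_give_p_one(self):
        cs = build_callset(
            [
                (f"c{i}", "chr1", i * 100, i * 100 + 50, [2] * 11 + [0] * 11)
                for i in range(4)
            ],
            two_breed_samples(11, 11),
        )
        results = fst_significance(fst_scan(cs), method="rank")
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_rank_bh_is_identically_one(self):
        """Within-sample rank p-values are uniform ranks, so BH-adjusted
        values are exactly 1: the rank+BH route can never call anything."""
        cfg = SimConfig(n_cnvs=500, seed=2, frac_differentiated=0.04, delta=0.8)
        cs, _ = simulate_callset(cfg)
        results = fst_significance(fst_scan(cs), method="rank")
        qs = [r.q_value for r in results if r.defined]
        assert all(q == pytest.approx(1.0) for q in qs)

    def test_undefined_fst_excluded_from_pool(self):
        rows = [
            ("mono", "chr1", 1, 10, [0] * 8),
            ("a", "chr1", 20, 30, [2, 2, 0, 0, 1, 0, 1, 1]),
            ("b", "chr1", 40, 50, [1, 0, 1, 0, 2, 2, 0, 0]),
            ("c", "chr1", 60, 70, [2, 2, 2, 2, 0, 0, 0, 1]),
        ]
        cs = build_callset(rows, two_breed_samples(4, 4))
        results = fst_significance(fst_scan(cs))
        assert results[0].p_value is None and results[0].q_value is None
        assert not results[0].significant()
        assert all(r.p_value is not None for r in results[1:])

    def test_needs_three_defined(self):
        cs = build_callset(
            [("c", "chr1", 1, 10, [1, 0, 1, 0])], two_breed_samples(2, 2)
        )
        with pytest.raises(CnvConfigError, match=">= 3"):
            fst_significance(fst_scan(cs))


class TestAnnotateSelected:
    def _scanned(self):
        rows = [
            ("hot", "chr1", 100, 200, [2] * 22 + [0] * 10),
        ] + [
            (f"null{i}", "chr2", 1000 * i, 1000 * i + 100, [1] * 32)
            for i in range(20)
        ]
        cs = build_callset(rows, two_breed_samples(22, 10))
        return cs, fst_significance(fst_scan(cs))

    def test_gene_join_and_empty_field(self):
        cs, results = self._scanned()
        genes = [GeneSpan("gHot", "chr1", 150, 5_000)]
        table = annotate_selected(results, cs, genes)
        assert table["cnv_id"].tolist() == ["hot"]
        assert table["genes"].iloc[0] == "gHot"
        table2 = annotate_selected(results, cs, [])
        assert table2["genes"].iloc[0] == ""

    def test_per_breed_tallies_match_direct_count(self):
        cs, results = self._scanned()
        table = annotate_selected(results, cs, None)
        row = table.iloc[0]
        geno = cs.genotypes[0]
        assert row["Hanwoo_hom_del"] == sum(1 for g in geno[:22] if g == 2)
        assert row["Hanwoo_het"] == sum(1 for g in geno[:22] if g == 1)
        assert row["Holstein_carriers"] == sum(1 for g in geno[22:] if g >= 1)
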
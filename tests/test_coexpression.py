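import numpy as np
import pytest
from scipy import stats

from lncforge.coexpression import (
    ConstantVectorError,
    CorrelationResult,
    best_hit_per_query,
    coexpress,
    cp_from_r,
    dual_sign_patterns,
    expressed_in_all_groups,
    expressed_in_at_least,
    filter_homology_hits,
    pearson_with_p,
    species_comparison,
)
from lncforge.io_formats import HitRecord
from lncforge.synthetic_data import SimulationConfig, simulate_expression

from conftest import make_expr


def _hit(q="q", t="t", qcov=80.0, tcov=80.0, evalue=1e-20, bitscore=100.0):
    return HitRecord(q, t, 90.0, qcov, tcov, evalue, bitscore)


class TestFilterHomologyHits:
    def test_retained_via_target_coverage(self):
        assert filter_homology_hits([_hit(qcov=27.8, tcov=63.8)])

    def test_retained_via_query_coverage(self):
        assert filter_homology_hits([_hit(qcov=91.7, tcov=9.8)])

    def test_both_coverages_low_rejected(self):
        assert filter_homology_hits([_hit(qcov=30.0, tcov=30.0, evalue=1e-10)]) == []

    def test_coverage_cutoff_is_strict(self):
        assert filter_homology_hits([_hit(qcov=40.0, tcov=40.0)]) == []
        assert filter_homology_hits([_hit(qcov=40.0001, tcov=10.0)])

    def test_evalue_cutoff_is_strict(self):
        assert filter_homology_hits([_hit(evalue=1e-5)]) == []
        assert filter_homology_hits([_hit(evalue=9.9e-6)])

    def test_both_rule_requires_both(self):
        hits = [_hit(qcov=60.0, tcov=30.0)]
        assert filter_homology_hits(hits, rule="either")
        assert filter_homology_hits(hits, rule="both") == []

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            filter_homology_hits([], rule="any")

    def test_best_hit_tie_breaks(self):
        hits = [
            _hit(t="b", bitscore=100, evalue=1e-10),
            _hit(t="a", bitscore=100, evalue=1e-10),
            _hit(t="c", bitscore=200, evalue=1e-5),
        ]
        best = best_hit_per_query(hits)
        assert best["q"].target_id == "c"  # bitscore first
        best2 = best_hit_per_query(hits[:2])
        assert best2["q"].target_id == "a"  # then lexicographic


def pearson_oracle(x, y):
    """Direct deviation-sum product-moment formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx * dx).sum() * (dy * dy).sum()))


class TestPearsonWithP:
    def test_identity_gives_r_one_cp_zero(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_with_p(x, x) == (1.0, 0.0)

    def test_perfect_negative_affine(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        r, cp = pearson_with_p(x, -2 * x + 7)
        assert (r, cp) == (-1.0, 0.0)

    def test_worked_example_from_summation(self):
        r, _ = pearson_with_p([1, 2, 3, 4], [2, 4, 5, 4])
        assert r == pytest.approx(0.7181848464596079, abs=1e-12)
        assert r == pytest.approx(pearson_oracle([1, 2, 3, 4], [2, 4, 5, 4]), abs=1e-14)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r, cp = pearson_with_p(x, y)
            assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
            # cP is the two-sided t-distribution tail
            t = r * np.sqrt(10 / (1 - r * r))
            assert cp == pytest.approx(2 * stats.t.sf(abs(t), df=10), rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantVectorError):
            pearson_with_p([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 2.0], [2.0, 1.0])

    def test_invariance_under_positive_affine_maps(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r0, _ = pearson_with_p(x, y)
        r1, _ = pearson_with_p(3.5 * x + 10.0, y)
        r2, _ = pearson_with_p(x, 0.2 * y - 4.0)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert r2 == pytest.approx(r0, abs=1e-12)

    def test_cp_gate_non_binding_at_n12(self):
        # at n = 12, |r| >= 0.8 already implies cP < 0.01
        assert cp_from_r(0.8, 12) < 0.01
        assert cp_from_r(-0.8, 12) < 0.01

    def test_cp_matches_permutation_p(self, rng):
        # permutation oracle on an n = 12 fixture, 10^4 permutations
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(scale=0.8, size=12)
        r_obs, cp = pearson_with_p(x, y)
        n_perm = 10_000
        exceed = 0
        for _ in range(n_perm):
            r_p = pearson_oracle(x, rng.permutation(y))
            if abs(r_p) >= abs(r_obs) - 1e-12:
                exceed += 1
        perm_p = (exceed + 1) / (n_perm + 1)
        se = 3 * np.sqrt(max(perm_p * (1 - perm_p), 1e-6) / n_perm)
        assert abs(cp - perm_p) < max(0.01, se + 0.005)


class TestTiers:
    def test_tier_bookkeeping(self):
        strong = CorrelationResult("l", "g", r=0.85, cP=0.001, n=12)
        assert strong.tier == "strong" and strong.sign == "positive"
        intense = CorrelationResult("l", "g", r=-0.95, cP=0.001, n=12)
        assert intense.tier == "intensive" and intense.sign == "negative"
        assert intense.at_least("strong")

    def test_cp_gate_blocks_tier(self):
        res = CorrelationResult("l", "g", r=0.95, cP=0.02, n=5)
        assert res.tier == "none"

    def test_tier_thresholds_sharp(self):
        eps = 1e-9
        assert CorrelationResult("l", "g", r=0.8 - eps, cP=0.0, n=12).tier == "none"
        assert CorrelationResult("l", "g", r=0.8, cP=0.01, n=12).tier == "strong"
        assert CorrelationResult("l", "g", r=0.9 - eps, cP=0.0, n=12).tier == "strong"
        assert CorrelationResult("l", "g", r=0.9, cP=0.01, n=12).tier == "intensive"


class TestPrefilters:
    def test_expressed_in_all_groups(self):
        everywhere = [1.0] * 12
        brain_only = [1.0] * 4 + [0.0] * 8
        expr = make_expr({"a": everywhere, "b": brain_only})
        assert expressed_in_all_groups(expr, "tissue") == ["a"]

    def test_expressed_in_at_least_k_conditions(self):
        # expressed in 3 of 4 conditions in at least one tissue each
        vals = [1.0, 1.0, 1.0, 0.0] * 3
        expr = make_expr({"a": vals, "b": [0.0] * 12})
        assert expressed_in_at_least(expr, 3, "condition") == ["a"]
        assert expressed_in_at_least(expr, 4, "condition") == []


class TestCoexpress:
    def test_sample_mismatch_rejected(self):
        a = make_expr({"l": [1.0] * 12})
        b = make_expr({"g": [1.0] * 12})
        b.values.columns = [c + "_x" for c in b.values.columns]
        b.sample_meta.index = b.values.columns
        with pytest.raises(ValueError, match="sample"):
            coexpress(a, b)

    def test_planted_intensive_pair_called_in_most_replicates(self):
        called = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = SimulationConfig(
                seed=seed, planted_correlations=(("L", "G", 0.95),)
            )
            expr, _ = simulate_expression(cfg, ["G", "L"], lnc_features={"L"})
            results = coexpress(
                expr.subset(["L"]), expr.subset(["G"]), prefilter=None
            )
            if results and results[0].at_least("intensive"):
                called += 1
        assert called >= 0.9 * n_rep

    def test_prefilter_excludes_not_everywhere_expressed(self):
        lnc = make_expr(
            {"l_all": list(np.linspace(0.5, 3.0, 12)), "l_brain": [1.0, 2.0, 1.5, 1.0] + [0.0] * 8}
        )
        gene = make_expr({"g": list(np.linspace(1, 5, 12))})
        results = coexpress(lnc, gene, prefilter="all_groups")
        assert {r.lnc_id for r in results} == {"l_all"}


class TestDualSign:
    def _results(self, table):
        return [
            CorrelationResult.from_r(lnc, gene, r, 12)
            for lnc, gene, r in table
        ]

    def test_mixed_sign_partners_flagged(self):
        results = self._results(
            [("2464", "NF2", -0.811), ("2464", "HYAL2", 0.839)]
        )
        (pat,) = dual_sign_patterns(results, ["NF2", "HYAL2"])
        assert pat.has_pattern(positive_gene="HYAL2", negative_gene="NF2")

    def test_opposite_pattern_flagged(self):
        results = self._results([("691", "NF2", 0.902), ("691", "HYAL2", -0.811)])
        (pat,) = dual_sign_patterns(results, ["NF2", "HYAL2"])
        assert pat.has_pattern(positive_gene="NF2", negative_gene="HYAL2")

    def test_single_qualifying_partner_not_dual(self):
        results = self._results([("x", "NF2", 0.9), ("x", "HYAL2", 0.5)])
        assert dual_sign_patterns(results, ["NF2", "HYAL2"]) == []

    def test_genes_outside_set_ignored(self):
        results = self._results([("x", "NF2", 0.9), ("x", "OTHER", -0.95)])
        assert dual_sign_patterns(results, ["NF2", "HYAL2"]) == []


class TestSpeciesComparison:
    def _res(self, lnc, gene, r):
        return CorrelationResult.from_r(lnc, gene, r, 12)

    def test_fraction_with_qualifying_partner(self):
        a = [
            self._res("l1", "g", 0.85),
            self._res("l2", "g", 0.2),
            self._res("l3", "g", -0.9),
            self._res("l4", "g", 0.1),
        ]
        cmp = species_comparison(a, a)
        assert cmp.fraction_a == pytest.approx(0.5)
        assert cmp.n_qualifying_a == 2 and cmp.n_lnc_a == 4

    def test_identical_inputs_give_empty_contrasts(self):
        a = [self._res("l", "NF2", -0.85), self._res("l", "HYAL2", 0.9)]
        cmp = species_comparison(a, list(a))
        assert cmp.patterns_only_a == set() and cmp.patterns_only_b == set()

    def test_planted_pattern_difference_reported(self):
        nmr = [self._res("l", "NF2", -0.85), self._res("l", "HYAL2", 0.9)]
        rat = [self._res("m", "NF2", 0.85), self._res("m", "HAS2", 0.9),
               self._res("m", "HYAL2", -0.81)]
        cmp = species_comparison(nmr, rat, gene_set=["NF2", "HYAL2", "HAS2"])
        assert (frozenset({"HYAL2"}), frozenset({"NF2"})) in cmp.patterns_only_a
        assert (frozenset({"NF2", "HAS2"}), frozenset({"HYAL2"})) in cmp.patterns_only_b
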
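import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import skinora as sk
from skinora.enrichment import TAIL_TWO_SIDED, ContingencyTable, fisher_p, fisher_point_prob
from skinora.knowledge_base import KnowledgeBase, Pathway


def exact_upper_tail(a, b, c, d):
    """Integer-arithmetic enumeration of P(X >= a) with margins fixed."""
    n, r, s = a + b + c + d, a + c, a + b
    num = sum(math.comb(r, k) * math.comb(n - r, s - k) for k in range(a, min(r, s) + 1))
    return Fraction(num, math.comb(n, s))


def table_strategy(max_count=60):
    return st.tuples(
        st.integers(0, max_count), st.integers(0, max_count),
        st.integers(0, max_count), st.integers(0, max_count),
    ).filter(lambda t: sum(t) > 0)


class TestFisherP:
    def test_no_degs_gives_p_one(self):
        assert fisher_p(ContingencyTable(0, 0, 10, 90)) == 1.0

    def test_single_deg_in_single_gene_pathway(self):
        # universe 10, pathway of 1 gene, the one DEG inside it: chance 1/10
        assert fisher_p(ContingencyTable(1, 0, 0, 9)) == pytest.approx(0.1, rel=1e-12)

    def test_matches_enumeration_on_small_table(self):
        t = ContingencyTable(2, 3, 1, 4)
        expected = float(exact_upper_tail(2, 3, 1, 4))
        assert fisher_p(t) == pytest.approx(expected, rel=1e-12)

    def test_point_probability_equals_factorial_expression(self):
        for a, b, c, d in [(2, 3, 1, 4), (5, 0, 2, 7), (0, 4, 4, 0), (3, 3, 3, 3)]:
            n = a + b + c + d
            f = math.factorial
            expected = Fraction(
                f(a + b) * f(c + d) * f(a + c) * f(b + d),
                f(a) * f(b) * f(c) * f(d) * f(n),
            )
            got = fisher_point_prob(ContingencyTable(a, b, c, d))
            assert got == pytest.approx(float(expected), rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(sk.DataError):
            ContingencyTable(-1, 0, 0, 9)

    def test_non_integer_count_rejected(self):
        with pytest.raises(sk.DataError):
            ContingencyTable(1.5, 0, 0, 9)

    @given(table_strategy())
    def test_agrees_with_scipy_hypergeom_survival(self, counts):
        a, b, c, d = counts
        t = ContingencyTable(a, b, c, d)
        expected = scipy.stats.hypergeom.sf(a - 1, t.n, t.pathway_size, t.n_degs)
        assert fisher_p(t) == pytest.approx(expected, rel=1e-9)

    @given(table_strategy(30))
    def test_two_sided_agrees_with_scipy_fisher_exact(self, counts):
        a, b, c, d = counts
        expected = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        got = fisher_p(ContingencyTable(a, b, c, d), tail=TAIL_TWO_SIDED)
        assert got == pytest.approx(expected, rel=1e-7)

    @given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
    def test_p_monotone_nonincreasing_in_a_at_fixed_margins(self, n, r, s):
        r, s = min(r, n), min(s, n)
        kmin, kmax = max(0, r + s - n), min(r, s)
        ps = [
            fisher_p(ContingencyTable(a, s - a, r - a, n - r - s + a))
            for a in range(kmin, kmax + 1)
        ]
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_uniform_null_draws_significant_at_most_alpha_rate(self):
        # random DEG pools from the universe: one-sided exact test is conservative
        rng = np.random.default_rng(20)
        universe = [f"G{i:03d}" for i in range(200)]
        kb = KnowledgeBase()
        for i in range(5):
            kb.add_pathway(Pathway(f"P{i}", "c", frozenset(universe[i * 40:(i + 1) * 40])))
        n_sig = n_tot = 0
        for _ in range(200):
            pool = rng.choice(universe, size=15, replace=False)
            degs = sk.DEGSet("s", 1.0, frozenset(pool), frozenset())
            for res in sk.enrich_column(degs, kb):
                n_sig += res.enriched
                n_tot += 1
        frac = n_sig / n_tot
        assert frac <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_tot)


class TestBuildContingency:
    def kb10(self):
        kb = KnowledgeBase()
        kb.add_pathway(Pathway("P1", "c", frozenset("ABC")))
        kb.add_pathway(Pathway("P2", "c", frozenset("DEFGHIJ")))
        return kb

    def test_direct_counting(self):
        kb = self.kb10()
        degs = sk.DEGSet("s", 1.0, frozenset("A"), frozenset("D"))
        t = sk.build_contingency(degs, kb["P1"], kb)
        assert (t.a, t.b, t.c, t.d, t.n) == (1, 1, 2, 6, 10)

    def test_degs_outside_universe_ignored(self):
        kb = self.kb10()
        degs = sk.DEGSet("s", 1.0, frozenset({"ZZ1", "ZZ2"}), frozenset())
        t = sk.build_contingency(degs, kb["P1"], kb)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 3, 7)

    def test_up_and_down_pooled_without_direction(self):
        kb = self.kb10()
        split = sk.DEGSet("s", 1.0, frozenset("A"), frozenset("D"))
        pooled = sk.DEGSet("s", 1.0, frozenset("AD"), frozenset())
        assert sk.build_contingency(split, kb["P1"], kb) == sk.build_contingency(
            pooled, kb["P1"], kb
        )

    def test_counts_always_total_universe_size(self):
        kb = self.kb10()
        rng = np.random.default_rng(5)
        for _ in range(20):
            pool = frozenset(rng.choice(sorted(kb.universe), size=4, replace=False))
            t = sk.build_contingency(sk.DEGSet("s", 1.0, pool, frozenset()), kb["P2"], kb)
            assert t.n == 10 and t.pathway_size == 7


class TestEnrichColumn:
    def big_kb(self, rng, n_genes=500, n_pathways=10, size=25):
        universe = [f"G{i:04d}" for i in range(n_genes)]
        kb = KnowledgeBase()
        perm = rng.permutation(n_genes)
        for i in range(n_pathways):
            idx = perm[i * size:(i + 1) * size]
            kb.add_pathway(Pathway(f"P{i:02d}", "c", frozenset(universe[j] for j in idx)))
        # make the universe the full gene list via one catch-all pathway
        kb.add_pathway(Pathway("Rest", "c", frozenset(universe)))
        return kb

    def test_full_pathway_deg_set_has_minimum_p(self):
        rng = np.random.default_rng(0)
        kb = self.big_kb(rng)
        degs = sk.DEGSet("s", 1.0, kb["P03"].genes, frozenset())
        results = sk.enrich_column(degs, kb)
        assert results[0].pathway == "P03"
        assert results[0].p_value == min(r.p_value for r in results)

    def test_empty_deg_set_gives_all_p_one_nothing_enriched(self):
        kb = self.big_kb(np.random.default_rng(1))
        degs = sk.DEGSet("s", 1.0, frozenset(), frozenset())
        results = sk.enrich_column(degs, kb)
        assert all(r.p_value == 1.0 and not r.enriched for r in results)

    def test_alpha_zero_enriches_nothing(self):
        kb = self.big_kb(np.random.default_rng(2))
        degs = sk.DEGSet("s", 1.0, kb["P00"].genes, frozenset())
        assert not any(r.enriched for r in sk.enrich_column(degs, kb, alpha=0.0))

    def test_one_result_per_pathway(self, demo_kb):
        degs = sk.DEGSet("s", 1.0, frozenset({"TNF"}), frozenset())
        assert len(sk.enrich_column(degs, demo_kb)) == len(demo_kb)

    def test_bh_adjustment_never_below_raw_p(self, demo_kb):
        degs = sk.DEGSet("s", 1.0, demo_kb["Inflammation"].genes, frozenset())
        for r in sk.enrich_column(degs, demo_kb, bh=True):
            assert r.p_adjusted >= r.p_value - 1e-15


class TestEnrichAll:
    def test_identical_deg_sets_give_all_or_nothing_counts(self, demo_kb):
        degs = sk.DEGSet("s", 1.0, demo_kb["Inflammation"].genes, frozenset())
        sets = [
            sk.DEGSet(f"s{i}", 1.0, degs.up, degs.down) for i in range(10)
        ]
        summary = sk.enrich_all(sets, demo_kb)
        assert set(summary.counts.index) == set(demo_kb.pathway_names)
        assert set(summary.counts.unique()) <= {0, 10}

    def test_zero_deg_sets_rejected(self, demo_kb):
        with pytest.raises(sk.ConfigError):
            sk.enrich_all([], demo_kb)

    def test_planted_cohort_counts_reach_responder_count(self, small_cohort):
        summary = sk.analyze_cohort(small_cohort, arm="BM")
        n_patients = small_cohort.config.n_patients
        assert summary.counts["P01"] >= n_patients - 1
        # cross-check one column against a direct Fisher computation
        col = summary.pvalues.columns[0]
        m = sk.median_normalize(small_cohort.expression)
        m = sk.filter_by_detection(m, small_cohort.design, arm="BM")
        g = sk.collapse_probes(m, small_cohort.mapping)
        fc = sk.fold_change_per_sample(g, small_cohort.design, "BM")
        degs = [d for d in sk.call_degs(fc, 1.0) if d.column_id == col][0]
        t = sk.build_contingency(degs, small_cohort.kb["P01"], small_cohort.kb)
        expected = float(exact_upper_tail(t.a, t.b, t.c, t.d))
        assert summary.pvalues.loc["P01", col] == pytest.approx(expected, rel=1e-9)
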
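import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from unipseudo.ontology import FunctionalGroup
from unipseudo.stats import (
    bh_fdr,
    conserved_set_validation,
    enriched_group_names,
    enrichment_tests,
    fisher_two_sided,
    overlap_hypergeometric,
    pair_overlap_report,
)

from .oracles import oracle_bh, oracle_fisher_two_sided, oracle_hypergeom_upper


class TestFisher:
    def test_published_pair_comparison(self):
        # (20 of 306) vs (7 of 480) -> p = 0.0002 at one significant figure
        _, p = fisher_two_sided(20, 286, 7, 473)
        assert float(f"{p:.1g}") == 0.0002

    def test_published_bound(self):
        _, p = fisher_two_sided(5, 448, 20, 286)
        assert p < 0.0001

    def test_derived_enumeration_value(self):
        _, p = fisher_two_sided(1, 9, 9, 1)
        assert p == pytest.approx(202 / 184756)

    def test_symmetric_table(self):
        _, p = fisher_two_sided(5, 5, 5, 5)
        assert p == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        _, p = fisher_two_sided(0, 0, 3, 4)
        assert p == 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 2, 3, 4)

    def test_invariance_under_row_and_column_swap(self):
        _, p1 = fisher_two_sided(3, 11, 8, 2)
        _, p2 = fisher_two_sided(2, 8, 11, 3)
        assert p1 == pytest.approx(p2)

    def test_matches_enumeration_oracle_randomized(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_two_sided(a, b, c, d)
            assert p == pytest.approx(oracle_fisher_two_sided(a, b, c, d)), (a, b, c, d)

    def test_matches_scipy(self):
        for table in [(12, 5, 3, 9), (1, 1, 1, 20), (7, 2, 8, 4)]:
            a, b, c, d = table
            _, p = fisher_two_sided(a, b, c, d)
            assert p == pytest.approx(float(sps.fisher_exact([[a, b], [c, d]])[1]))


class TestBH:
    def test_hand_stepped_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == [0.2]

    def test_empty(self):
        assert bh_fdr([]) == []

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_matches_oracle_and_dominates_raw(self, pvals):
        adj = bh_fdr(pvals)
        want = oracle_bh(pvals)
        assert adj == pytest.approx(want)
        for raw, q in zip(pvals, adj):
            assert q >= raw - 1e-12
            assert q <= 1.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        pvals = [0.001, 0.2, 0.03, 0.5, 0.04, 0.9]
        assert bh_fdr(pvals) == pytest.approx(
            multipletests(pvals, method="fdr_bh")[1].tolist()
        )


class TestOverlap:
    def test_derived_example(self):
        t = overlap_hypergeometric(4, 5, 10, 3)
        assert t.expected == pytest.approx(2.0)
        assert t.p_hyper == pytest.approx(11 / 42)

    def test_zero_overlap_p_one(self):
        assert overlap_hypergeometric(4, 5, 10, 0).p_hyper == pytest.approx(1.0)

    def test_paper_shaped_instance(self):
        # structural reference: N chosen so expected ~= 1.42
        n1, n2 = 167, 139
        universe = round(n1 * n2 / 1.42)
        t = overlap_hypergeometric(n1, n2, universe, 20)
        assert t.expected == pytest.approx(1.42, abs=0.01)
        assert t.p_hyper < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            overlap_hypergeometric(11, 5, 10, 3)
        with pytest.raises(ValueError):
            overlap_hypergeometric(4, 5, 10, 5)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            universe = int(rng.integers(5, 41))
            n1 = int(rng.integers(1, universe + 1))
            n2 = int(rng.integers(1, universe + 1))
            obs = int(rng.integers(0, min(n1, n2) + 1))
            got = overlap_hypergeometric(n1, n2, universe, obs).p_hyper
            assert got == pytest.approx(oracle_hypergeom_upper(n1, n2, universe, obs))

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        n1, n2, universe, obs = 6, 8, 20, 4
        draws = 10**5
        hits = 0
        pool = np.arange(universe)
        for _ in range(draws):
            sample = rng.choice(pool, n2, replace=False)
            if (sample < n1).sum() >= obs:
                hits += 1
        mc = hits / draws
        got = overlap_hypergeometric(n1, n2, universe, obs).p_hyper
        se = (mc * (1 - mc) / draws) ** 0.5
        assert abs(got - mc) <= 3 * se


class TestConservedSet:
    def test_published_ratio(self):
        flagged = {f"x{i}" for i in range(41)} | {"other"}
        conserved = {f"x{i}" for i in range(13650)}
        assert conserved_set_validation(flagged, conserved) == pytest.approx(0.30, abs=0.005)

    def test_zero_flagged(self):
        assert conserved_set_validation(set(), {"a", "b"}) == 0.0

    def test_bounds(self):
        assert 0 <= conserved_set_validation({"a"}, {"a", "b"}) <= 100

    def test_empty_conserved_rejected(self):
        with pytest.raises(ValueError):
            conserved_set_validation({"a"}, set())


class TestPairOverlap:
    def test_reproduces_published_comparison(self):
        # homotypic pair 20 of 306 (167+139) vs heterotypic pair 7 of 480
        # (139+341); the comparison p prints as 0.0002
        a = {f"n{i}" for i in range(167)}
        b = {f"n{i}" for i in range(20)} | {f"b{i}" for i in range(119)}
        c = {f"b{i}" for i in range(7)} | {f"c{i}" for i in range(334)}
        lists = {"A": a, "B": b, "C": c}
        assert len(a) == 167 and len(b) == 139 and len(a & b) == 20
        assert len(c) == 341 and len(b & c) == 7
        report = pair_overlap_report(
            lists, [("A", "B", "N-B"), ("B", "C", "B-G")]
        )
        assert report.pair_tests["N-B"] == (20, 306)
        assert report.pair_tests["B-G"] == (7, 480)
        (_, _, p), = report.comparisons
        assert float(f"{p:.1g}") == 0.0002

    def test_identical_lists(self):
        lists = {"A": {"x", "y"}, "B": {"x", "y"}}
        report = pair_overlap_report(lists, [("A", "B", "p")])
        assert report.pair_tests["p"] == (2, 4)

    def test_disjoint_lists(self):
        lists = {"A": {"x"}, "B": {"y"}}
        report = pair_overlap_report(lists, [("A", "B", "p")])
        assert report.pair_tests["p"][0] == 0


class TestEnrichment:
    def _groups(self, rng, n_groups, genes, size=120):
        groups = []
        for gi in range(n_groups):
            members = set(rng.choice(genes, size=size, replace=False))
            groups.append(FunctionalGroup(f"G{gi}", ("kw",), set(), members))
        return groups

    def test_planted_enrichment_recovered_with_power(self):
        """Pseudogenes drawn preferentially (odds ratio 5) from one group of
        10% prevalence; recovery power >= 0.9 at FDR < 0.05."""
        rng = np.random.default_rng(5)
        genes = np.array([f"g{i}" for i in range(1200)])
        q = 0.1
        odds_fg = 5 * q / (1 - q)
        n_in = round(30 * odds_fg / (1 + odds_fg))  # 11 of 30 in-group
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            groups = self._groups(rng, 8, genes)
            target = groups[0]
            inside = np.array(sorted(target.members))
            outside = np.array(sorted(set(genes) - target.members))
            pseudo = set(rng.choice(inside, n_in, replace=False)) | set(
                rng.choice(outside, 30 - n_in, replace=False)
            )
            background = set(genes) - pseudo
            results = enrichment_tests(groups, pseudo, background)
            if "G0" in enriched_group_names(results):
                hits += 1
        assert hits / n_rep >= 0.9

    def test_no_enrichment_under_null(self):
        rng = np.random.default_rng(6)
        genes = np.array([f"g{i}" for i in range(1200)])
        false_hits = 0
        for rep in range(20):
            groups = self._groups(rng, 8, genes)
            pseudo = set(rng.choice(genes, 30, replace=False))
            results = enrichment_tests(groups, pseudo, set(genes) - pseudo)
            false_hits += len(enriched_group_names(results))
        assert false_hits <= 3

    def test_control_comparison_used(self):
        genes = [f"g{i}" for i in range(100)]
        grp = FunctionalGroup("G", ("kw",), set(), set(genes[:50]))
        pseudo = set(genes[:30])  # all inside the group
        control = set(genes[50:80])  # all outside
        results = enrichment_tests([grp], pseudo, set(), control_pseudogenes=control)
        assert any(r.comparison == "control" and r.significant for r in results)
        assert all(r.fdr_p >= r.p - 1e-12 for r in results)
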
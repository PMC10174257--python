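import itertools

import numpy as np
import pytest
from scipy import stats

from tenonet.data_model import InteractionRecord
from tenonet.enrich import (AnnotationCollection, ScoredInteractionSource, Term,
                            enrich_terms, expand_network, hypergeometric_test,
                            macro_category_counts, read_annotations,
                            read_scored_source, write_annotations)
from tenonet.netbuild import build_network
from tenonet.synthetic_data import SyntheticConfig, generate_annotations

from .oracles import (bh_qvalues_by_brute_force, bh_stepup_by_brute_force,
                      hypergeom_upper_tail_by_enumeration)


def chain_network(symbols):
    records = [InteractionRecord(a, b, "physical", "m", "embryo", "r")
               for a, b in zip(symbols, symbols[1:])]
    return build_network(records, {"m"}, label="chain")


class TestHypergeometricTest:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_test(0, 5, 5, 20) == 1.0

    def test_saturated_draw_is_certain(self):
        assert hypergeometric_test(4, 4, 4, 4) == 1.0

    def test_worked_example_exact_value(self):
        # K=5 annotated in N=20, draw n=5, observe k>=4
        from math import comb
        expected = (comb(5, 4) * comb(15, 1) + comb(5, 5)) / comb(20, 5)
        assert hypergeometric_test(4, 5, 5, 20) == pytest.approx(expected)

    def test_exhaustive_enumeration_all_small_universes(self):
        """Agreement with subset enumeration for every parameter combo N<=12."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeometric_test(k, n, K, N) == pytest.approx(
                            hypergeom_upper_tail_by_enumeration(k, n, K, N)
                        ), (k, n, K, N)

    def test_agrees_with_scipy_survival_function(self):
        rng = np.random.default_rng(41)
        for _ in range(200):
            N = int(rng.integers(2, 500))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeometric_test(k, n, K, N) == pytest.approx(
                stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_test(6, 5, 5, 20)
        with pytest.raises(ValueError):
            hypergeometric_test(1, 5, 25, 20)


def make_annotations(term_members: dict, universe=None):
    terms = {tid: Term(tid, tid, "pathway", "unclassified", frozenset(members))
             for tid, members in term_members.items()}
    return AnnotationCollection(terms, frozenset(universe or ()))


class TestEnrichTerms:
    def test_full_term_query_ranked_first_and_significant(self):
        universe = [f"G{i:03d}" for i in range(100)]
        ann = make_annotations(
            {"T1": universe[:10], "T2": universe[40:50], "T3": universe[70:80]},
            universe)
        results = enrich_terms(set(universe[:10]), ann)
        assert results[0].term_id == "T1"
        assert results[0].significant
        assert results[0].overlap == 10

    def test_unannotated_query_empty_result(self):
        ann = make_annotations({"T1": ["A", "B", "C"]})
        assert enrich_terms({"X", "Y"}, ann) == []

    def test_qvalues_monotone_in_p_rank(self):
        cfg = SyntheticConfig(seed=5, planted_effect=0.6, planted_terms=3)
        ann, query, _ = generate_annotations(cfg)
        results = enrich_terms(query, ann, min_overlap=1)
        by_p = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)

    def test_bh_reproduced_by_brute_force(self):
        cfg = SyntheticConfig(seed=6, planted_effect=0.5, planted_terms=2)
        ann, query, _ = generate_annotations(cfg)
        results = enrich_terms(query, ann, min_overlap=1, alpha=0.05)
        pvals = [r.p_value for r in results]
        assert [r.significant for r in results] == bh_stepup_by_brute_force(pvals, 0.05)
        brute_q = bh_qvalues_by_brute_force(pvals)
        for r, q in zip(results, brute_q):
            assert r.q_value == pytest.approx(q)

    def test_planted_term_power(self):
        """Planted term (effect 0.8, size 10, universe 200) recovered at q<0.05."""
        hits = 0
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed)
            ann, query, planted = generate_annotations(cfg)
            results = enrich_terms(query, ann)
            sig = {r.term_id for r in results if r.significant}
            hits += planted[0] in sig
        assert hits >= 95

    def test_null_rejection_rate_controlled(self):
        """With effect 0 the planted term's raw p rejects at ~nominal rate."""
        rejections = 0
        for seed in range(200):
            cfg = SyntheticConfig(seed=seed, planted_effect=0.0)
            ann, query, planted = generate_annotations(cfg)
            results = enrich_terms(query, ann, min_overlap=0)
            p = {r.term_id: r.p_value for r in results}.get(planted[0], 1.0)
            rejections += p < 0.05
        assert 0.01 * 200 <= rejections <= 0.12 * 200


class TestExpandNetwork:
    def test_cutoff_filters_candidates(self):
        base = build_network(
            [InteractionRecord("A", "A0", "physical", "m", "embryo", "r")],
            {"m"}, label="seed")
        source = ScoredInteractionSource([("A", "B", 0.9), ("A", "C", 0.3)])
        enr = expand_network(base, source, cutoff=0.4, cycles=1, per_cycle=10)
        assert "B" in enr.nodes and "C" not in enr.nodes

    def test_frontier_growth_cycle_indices(self):
        base = build_network(
            [InteractionRecord("A", "A0", "physical", "m", "embryo", "r")],
            {"m"}, label="seed")
        source = ScoredInteractionSource(
            [("A", "B", 0.9), ("B", "C", 0.9), ("C", "D", 0.9)])
        enr = expand_network(base, source, cutoff=0.4, cycles=3, per_cycle=1)
        assert enr.cycle_index == {"B": 1, "C": 2, "D": 3}

    def test_zero_cycles_is_identity(self):
        base = chain_network(["A", "B", "C"])
        source = ScoredInteractionSource([("A", "X", 0.9)])
        enr = expand_network(base, source, cycles=0)
        assert enr.nodes == base.nodes
        assert enr.directed_edges() == base.directed_edges()
        assert enr.origin_counts()["enriched"] == 0

    def test_invariant_under_source_row_permutation(self):
        rng = np.random.default_rng(42)
        base = chain_network([f"S{i}" for i in range(5)])
        pairs = []
        symbols = [f"S{i}" for i in range(5)] + [f"X{i}" for i in range(20)]
        for a, b in itertools.combinations(symbols, 2):
            if rng.random() < 0.3:
                pairs.append((a, b, float(rng.uniform(0.2, 1.0))))
        reference = expand_network(base, ScoredInteractionSource(pairs),
                                   cycles=2, per_cycle=3)
        for _ in range(5):
            shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
            enr = expand_network(base, ScoredInteractionSource(shuffled),
                                 cycles=2, per_cycle=3)
            assert enr.nodes == reference.nodes
            assert enr.directed_edges() == reference.directed_edges()
            assert enr.cycle_index == reference.cycle_index

    def test_raising_cutoff_never_adds_candidates(self):
        rng = np.random.default_rng(43)
        base = chain_network([f"S{i}" for i in range(4)])
        for _ in range(100):
            symbols = [f"S{i}" for i in range(4)] + [f"X{i}" for i in range(10)]
            pairs = [(a, b, float(rng.uniform(0, 1)))
                     for a, b in itertools.combinations(symbols, 2)
                     if rng.random() < 0.4]
            if not pairs:
                continue
            source = ScoredInteractionSource(pairs)
            prev = None
            for cutoff in (0.2, 0.4, 0.6, 0.8):
                admitted = expand_network(base, source, cutoff=cutoff,
                                          cycles=1, per_cycle=10**6)
                nodes = {n for n, o in admitted.node_origin.items()
                         if o == "enriched"}
                if prev is not None:
                    assert nodes <= prev
                prev = nodes

    def test_ranking_rule_matches_brute_force(self):
        rng = np.random.default_rng(44)
        seeds = [f"H{i}" for i in range(14)]
        base = chain_network(seeds)
        symbols = seeds + [f"X{i}" for i in range(30)]
        pairs = [(a, b, float(rng.uniform(0, 1)))
                 for a, b in itertools.combinations(symbols, 2)
                 if rng.random() < 0.3]
        source = ScoredInteractionSource(pairs)
        enr = expand_network(base, source, cutoff=0.4, cycles=1, per_cycle=5)
        # brute-force the same ranking rule
        cand = {}
        for a, b, s in source.pairs():
            if s < 0.4:
                continue
            for outside, inside in ((a, b), (b, a)):
                if outside not in base.nodes and inside in base.nodes:
                    links, tot = cand.get(outside, (0, 0.0))
                    cand[outside] = (links + 1, tot + s)
        expected = set(sorted(cand, key=lambda s: (-cand[s][0], -cand[s][1], s))[:5])
        assert {n for n, o in enr.node_origin.items() if o == "enriched"} == expected


class TestMacroCategories:
    def result(self, tid, significant=True):
        from tenonet.enrich import EnrichmentResult
        return EnrichmentResult(tid, tid, 3, 10, 10, 100, 0.001,
                                q_value=0.01, significant=significant)

    def annotations(self):
        return AnnotationCollection({
            "T1": Term("T1", "t1", "pathway", "nervous system", frozenset({"A", "B"})),
            "T2": Term("T2", "t2", "pathway", "nervous system", frozenset({"C", "D"})),
            "T3": Term("T3", "t3", "pathway", "endocrine system", frozenset({"E", "F"})),
        })

    def test_counts_and_unique_total(self):
        out = macro_category_counts(
            {"net": [self.result("T1"), self.result("T2"), self.result("T3")]},
            self.annotations())
        assert out["per_network"]["net"] == {"nervous system": 2,
                                            "endocrine system": 1}
        assert out["unique_totals"]["net"] == 3

    def test_no_significant_terms_all_zero(self):
        out = macro_category_counts(
            {"net": [self.result("T1", significant=False)]}, self.annotations())
        assert out["per_network"]["net"] == {}
        assert out["pooled_unique_total"] == 0

    def test_superset_network_has_larger_unique_total(self):
        lit = {"net": [self.result("T1")]}
        enr = {"Enriched_net": [self.result("T1"), self.result("T2"),
                                self.result("T3")]}
        ann = self.annotations()
        out_l = macro_category_counts(lit, ann)
        out_e = macro_category_counts(enr, ann)
        assert (out_e["unique_totals"]["Enriched_net"]
                > out_l["unique_totals"]["net"])


class TestReaders:
    def test_annotation_tsv_round_trip(self, tmp_path):
        ann = make_annotations({"T1": ["A", "B"], "T2": ["C", "D"]})
        path = tmp_path / "ann.tsv"
        write_annotations(ann, path)
        back = read_annotations(path)
        assert {t: sorted(term.members) for t, term in back.terms.items()} == {
            "T1": ["A", "B"], "T2": ["C", "D"]}

    def test_gmt_reader(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET1\tdesc\tA\tB\tC\nSET2\tdesc\tD\tE\n")
        ann = read_annotations(path)
        assert sorted(ann.terms["SET1"].members) == ["A", "B", "C"]
        assert ann.terms["SET2"].category == "unclassified"

    def test_scored_source_thousand_scale_autodetected(self, tmp_path):
        path = tmp_path / "src.tsv"
        path.write_text("node_a\tnode_b\tcombined_score\nA\tB\t900\nA\tC\t250\n")
        source = read_scored_source(path)
        assert source.score("A", "B") == pytest.approx(0.9)
        assert source.score("A", "C") == pytest.approx(0.25)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            ScoredInteractionSource([("A", "A", 0.5)])
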
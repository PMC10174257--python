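import numpy as np
import pytest
from scipy import stats

from tenonet.data_model import summarize_collection, validate_collection
from tenonet.netbuild import build_network
from tenonet.synthetic_data import (DEFAULT_CELL_COUNTS, SyntheticConfig,
                                    generate_annotations, generate_collection,
                                    generate_scored_source)


class TestGenerateCollection:
    def test_default_config_reproduces_corpus_totals(self):
        records, _ = generate_collection(SyntheticConfig(seed=3))
        summary = summarize_collection(records)
        assert summary.total == 286
        assert summary.stage_totals == {"embryo": 155, "prepubertal": 131}

    def test_per_cell_counts_exact_not_in_expectation(self):
        cfg = SyntheticConfig(seed=4)
        records, _ = generate_collection(cfg)
        summary = summarize_collection(records)
        for cell, count in DEFAULT_CELL_COUNTS.items():
            assert summary.cells.get(cell, 0) == count

    def test_all_counts_zero_gives_empty_collection(self):
        cfg = SyntheticConfig(seed=1, cell_counts={k: 0 for k in DEFAULT_CELL_COUNTS})
        records, layers = generate_collection(cfg)
        assert records == [] and layers == []

    def test_same_seed_identical_different_seeds_differ(self):
        a1, _ = generate_collection(SyntheticConfig(seed=9))
        a2, _ = generate_collection(SyntheticConfig(seed=9))
        assert a1 == a2
        distinct = 0
        for seed in range(20):
            b, _ = generate_collection(SyntheticConfig(seed=100 + seed))
            distinct += b != a1
        assert distinct == 20

    def test_generated_collection_validates_cleanly(self):
        records, layers = generate_collection(SyntheticConfig(seed=6))
        report = validate_collection(records, layers)
        assert report.n_duplicate_groups == 0
        assert report.n_self_interactions == 0
        assert report.multi_layer_symbols == {}

    def test_each_symbol_has_exactly_one_layer(self):
        records, layers = generate_collection(SyntheticConfig(seed=7))
        symbols = ({r.source_symbol for r in records}
                   | {r.target_symbol for r in records})
        assert {a.symbol for a in layers} == symbols
        assert len({a.symbol for a in layers}) == len(layers)

    def test_conserved_core_present_in_first_species(self):
        cfg = SyntheticConfig(seed=8)
        records, _ = generate_collection(cfg)
        core = {f"CORE{i + 1:02d}" for i in range(cfg.conserved_core_size)}
        present = 0
        for sp in ("m", "r", "h", "e"):
            net = build_network(records, {sp})
            present += bool(core & net.nodes)
        assert present == 4

    def test_infeasible_count_rejected(self):
        cfg = SyntheticConfig(seed=1, nodes_per_species=4,
                              cell_counts={("m", "embryo"): 50,
                                           ("m", "prepubertal"): 0})
        with pytest.raises(ValueError, match="infeasible"):
            generate_collection(cfg)


class TestGenerateAnnotations:
    def test_full_effect_plants_recoverable_term(self):
        from tenonet.enrich import enrich_terms
        cfg = SyntheticConfig(seed=2, planted_effect=1.0)
        ann, query, planted = generate_annotations(cfg)
        results = enrich_terms(query, ann)
        assert results[0].term_id == planted[0]

    def test_terms_span_macro_categories(self):
        from tenonet.enrich import MACRO_CATEGORIES
        ann, _, _ = generate_annotations(SyntheticConfig(seed=3))
        seen = {t.macro_category for t in ann.terms.values()}
        assert seen == set(MACRO_CATEGORIES)

    def test_universe_override_is_used(self):
        cfg = SyntheticConfig(seed=4, universe_size=50)
        custom = [f"SYM{i:03d}" for i in range(60)]
        ann, query, _ = generate_annotations(cfg, universe=custom)
        assert ann.universe == frozenset(custom)
        assert query <= ann.universe

    def test_reproducible(self):
        a = generate_annotations(SyntheticConfig(seed=5))
        b = generate_annotations(SyntheticConfig(seed=5))
        assert a[0].terms == b[0].terms and a[1] == b[1]


class TestGenerateScoredSource:
    def test_degenerate_distributions_separate_cleanly(self):
        from tenonet.enrich import expand_network
        cfg = SyntheticConfig(seed=5, true_score_dist=("fixed", 0.9),
                              background_score_dist=("fixed", 0.1),
                              n_novel_interactors=10)
        records, _ = generate_collection(cfg)
        net = build_network(records, {"m"}, label="mNET")
        source = generate_scored_source(cfg, net)
        enr = expand_network(net, source, cutoff=0.4, cycles=3, per_cycle=100)
        # every enriched node must be a planted novel interactor, never a
        # background-pair partner
        enriched = {n for n, o in enr.node_origin.items() if o == "enriched"}
        assert enriched and all(n.startswith("NOV") for n in enriched)

    def test_empty_base_gives_only_background_pairs(self):
        cfg = SyntheticConfig(seed=6, n_novel_interactors=20,
                              background_pair_rate=0.2)
        source = generate_scored_source(cfg, None)
        assert len(source) > 0
        assert all(a.startswith("NOV") and b.startswith("NOV")
                   for a, b, _ in source.pairs())

    def test_no_self_pairs_and_scores_in_range(self):
        cfg = SyntheticConfig(seed=7)
        records, _ = generate_collection(cfg)
        net = build_network(records, {"g"}, label="gNET")
        source = generate_scored_source(cfg, net)
        for a, b, s in source.pairs():
            assert a != b and 0.0 <= s <= 1.0

    def test_background_tail_mass_matches_distribution(self):
        """Fraction of background pairs clearing 0.400 ~ Beta(2,8) tail mass."""
        tail = stats.beta.sf(0.4, 2.0, 8.0)
        admitted = total = 0
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed, n_novel_interactors=0,
                                  background_pair_rate=0.05)
            records, _ = generate_collection(cfg)
            net = build_network(records, {"h"}, label="hNET")
            true_pairs = {frozenset((u, v))
                          for u, v in net.undirected_view().edges}
            source = generate_scored_source(cfg, net)
            for a, b, s in source.pairs():
                if frozenset((a, b)) in true_pairs:
                    continue
                total += 1
                admitted += s >= 0.4
        se = np.sqrt(tail * (1 - tail) / total)
        assert abs(admitted / total - tail) <= 3 * se

    def test_reproducible(self):
        cfg = SyntheticConfig(seed=8)
        records, _ = generate_collection(cfg)
        net = build_network(records, {"e"}, label="eNET")
        assert (generate_scored_source(cfg, net).pairs()
                == generate_scored_source(cfg, net).pairs())
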
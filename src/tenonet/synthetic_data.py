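"""Seeded generators for offline, fully reproducible test data.

Every input the pipeline consumes can be synthesised here: interaction
collections with the composition of the curated literature corpus (per
species and developmental stage), layer annotations, annotation
collections with planted over-represented terms, and scored interaction
sources with separated score distributions for true and background pairs.

Defaults mirror the curated corpus: per-species interaction counts and
embryo/prepubertal splits as in the published composition table (286
interactions: 155 embryo, 131 prepubertal across 7 organisms), a
52:23:24 upstream:TF:downstream layer mixture, and preferential-attachment
topology so generated networks carry the scale-free degree structure the
downstream power-law assessment expects.

Randomness discipline: one integer seed; each sub-generator forks its own
stream by a fixed label (CRC32 of the label mixed with the seed), so adding
one generator never shifts another's output.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .data_model import (InteractionRecord, LayerAnnotation, LAYERS,
                         LINK_TYPES, SPECIES_CODES)
from .enrich import (AnnotationCollection, MACRO_CATEGORIES,
                     ScoredInteractionSource, Term, write_annotations)
from .netbuild import SpeciesNetwork

#: Per-(species, stage) interaction counts of the curated corpus.
DEFAULT_CELL_COUNTS: dict[tuple[str, str], int] = {
    ("m", "embryo"): 71, ("m", "prepubertal"): 74,
    ("r", "embryo"): 0,  ("r", "prepubertal"): 28,
    ("h", "embryo"): 9,  ("h", "prepubertal"): 0,
    ("e", "embryo"): 3,  ("e", "prepubertal"): 25,
    ("b", "embryo"): 0,  ("b", "prepubertal"): 2,
    ("g", "embryo"): 68, ("g", "prepubertal"): 2,
    ("d", "embryo"): 4,  ("d", "prepubertal"): 0,
}

#: Layer mixture of the stratified multi-species node catalogue.
DEFAULT_LAYER_WEIGHTS: dict[str, float] = {
    "upstream": 52.0, "TF": 23.0, "downstream": 24.0,
}


@dataclass
class SyntheticConfig:
    """Parameters of all synthetic generators.

    Only ``seed`` has no default tied to the study conditions; everything
    else defaults to the corpus composition or to a realistic magnitude for
    a literature-scale signaling network.
    """

    seed: int = 0
    cell_counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CELL_COUNTS))
    layer_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_WEIGHTS))
    topology_generator: str = "preferential_attachment"  # | planted_partition | erdos_renyi
    attachment_m: int = 1  # sparse, leaf-heavy networks like curated corpora
    community_size: int = 8
    n_communities: int = 3
    p_intra: float = 0.8
    p_inter: float = 0.02
    er_p: float = 0.1
    nodes_per_species: int | None = None  # None: sized from the edge demand
    physical_fraction: float = 0.5
    conserved_core_size: int = 4
    conserved_core_species: int = 4
    # annotation generator
    universe_size: int = 200
    n_terms: int = 40
    term_size: int = 10
    planted_terms: int = 1
    query_size: int = 20
    planted_effect: float = 0.8
    # scored-source generator
    n_novel_interactors: int = 30
    background_pair_rate: float = 0.01
    true_score_dist: tuple = ("beta", 8.0, 2.0)   # mean 0.8, above the 0.400 cutoff
    background_score_dist: tuple = ("beta", 2.0, 8.0)  # mean 0.2, below the cutoff

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cell_counts.values()):
            raise ValueError("cell counts must be non-negative")
        for p in (self.p_intra, self.p_inter, self.er_p,
                  self.physical_fraction, self.planted_effect,
                  self.background_pair_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _fork(seed: int, label: str) -> np.random.Generator:
    """Fork a deterministic per-label stream off the global seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def _draw_scores(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size=size)
    if kind == "fixed":
        return np.full(size, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=size)
    raise ValueError(f"unknown score distribution {kind!r}")


def synthetic_graph(generator: str, n_edges_min: int, rng: np.random.Generator,
                    config: SyntheticConfig) -> nx.Graph:
    """An undirected base graph with at least ``n_edges_min`` edges."""
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if generator == "preferential_attachment":
        m = max(1, config.attachment_m)
        if config.nodes_per_species is not None:
            n = config.nodes_per_species
        else:
            n = max(m + 2, -(-n_edges_min // m) + m)  # m*(n-m) >= n_edges_min
        g = nx.barabasi_albert_graph(n, m, seed=nx_seed)
    elif generator == "planted_partition":
        g = nx.planted_partition_graph(config.n_communities, config.community_size,
                                       config.p_intra, config.p_inter, seed=nx_seed)
    elif generator == "erdos_renyi":
        n = config.nodes_per_species or max(8, int((2 * n_edges_min / config.er_p) ** 0.5))
        g = nx.gnp_random_graph(n, config.er_p, seed=nx_seed)
    else:
        raise ValueError(f"unknown topology generator {generator!r}")
    if g.number_of_edges() < n_edges_min:
        raise ValueError(
            f"infeasible: {n_edges_min} distinct interactions requested but the "
            f"{generator} graph on {g.number_of_nodes()} nodes has only "
            f"{g.number_of_edges()} edges")
    return g


def generate_collection(config: SyntheticConfig
                        ) -> tuple[list[InteractionRecord], list[LayerAnnotation]]:
    """Synthesise an interaction collection plus its layer annotations.

    Per-(species, stage) record counts equal the config exactly — not in
    expectation.  Each species network follows the configured topology
    generator; a conserved core of shared symbols replaces the
    highest-degree nodes of the first ``conserved_core_species`` organisms,
    so hub-conservation behaviour is testable.
    """
    records: list[InteractionRecord] = []
    symbols: set[str] = set()
    core = [f"CORE{i + 1:02d}" for i in range(config.conserved_core_size)]
    core_species = [
        sp for sp in SPECIES_CODES
        if sum(config.cell_counts.get((sp, st), 0) for st in ("embryo", "prepubertal"))
    ][:config.conserved_core_species]

    for sp in SPECIES_CODES:
        c_embryo = config.cell_counts.get((sp, "embryo"), 0)
        c_prep = config.cell_counts.get((sp, "prepubertal"), 0)
        c = c_embryo + c_prep
        if c == 0:
            continue
        rng = _fork(config.seed, f"collection/{sp}")
        g = synthetic_graph(config.topology_generator, c, rng, config)
        # name nodes; highest-degree nodes take the conserved-core symbols
        by_degree = sorted(g.nodes, key=lambda v: (-g.degree(v), v))
        names: dict = {}
        core_here = core if sp in core_species else []
        for i, v in enumerate(by_degree):
            names[v] = (core_here[i] if i < len(core_here)
                        else f"{sp.upper()}G{i + 1:03d}")
        edges = sorted((min(u, v), max(u, v)) for u, v in g.edges())
        chosen = [edges[i] for i in rng.permutation(len(edges))[:c]]
        stages = ["embryo"] * c_embryo + ["prepubertal"] * c_prep
        stages = [stages[i] for i in rng.permutation(c)]
        for (u, v), stage in zip(chosen, stages):
            if rng.random() < 0.5:
                u, v = v, u
            link = LINK_TYPES[0] if rng.random() < config.physical_fraction else LINK_TYPES[1]
            effect = ("up", "down", "unspecified")[int(rng.integers(0, 3))]
            records.append(InteractionRecord(
                source_symbol=names[u], target_symbol=names[v], link_type=link,
                species=sp, stage=stage,
                reference_id=f"SYN:{sp}{len(records) + 1:04d}",
                direction_effect=effect))
            symbols.update((names[u], names[v]))

    layer_rng = _fork(config.seed, "layers")
    weights = np.array([config.layer_weights[l] for l in LAYERS], dtype=float)
    probs = weights / weights.sum()
    layers = [
        LayerAnnotation(sym, LAYERS[int(layer_rng.choice(len(LAYERS), p=probs))],
                        "literature")
        for sym in sorted(symbols)
    ]
    return records, layers


def generate_annotations(config: SyntheticConfig,
                         universe: Sequence[str] | None = None
                         ) -> tuple[AnnotationCollection, set[str], list[str]]:
    """Synthesise an annotation collection with planted enriched terms.

    Returns ``(collection, query_set, planted_term_ids)``.  Each planted
    term contributes ``round(effect * term_size)`` of its members to the
    query; the remainder of the query is drawn uniformly from the rest of
    the universe (the background rate for unplanted terms).  With
    ``effect = 0`` planted terms are statistically indistinguishable from
    background.

    ``universe`` may name the molecule symbols to annotate (e.g. a generated
    collection's own symbols); by default a synthetic universe of
    ``universe_size`` symbols is used.  A supplied universe smaller than
    ``universe_size`` is padded with synthetic filler symbols.
    """
    rng = _fork(config.seed, "annotations")
    if universe is None:
        universe = [f"GENE{i + 1:04d}" for i in range(config.universe_size)]
    else:
        universe = sorted(set(universe))
        universe += [f"GENE{i + 1:04d}"
                     for i in range(max(0, config.universe_size - len(universe)))]
    terms: dict[str, Term] = {}
    planted_ids: list[str] = []
    for t in range(config.n_terms):
        tid = f"T{t + 1:04d}"
        members = frozenset(
            universe[i] for i in rng.choice(len(universe),
                                            size=min(config.term_size, len(universe)),
                                            replace=False))
        macro = MACRO_CATEGORIES[t % len(MACRO_CATEGORIES)]
        planted = t < config.planted_terms
        terms[tid] = Term(tid, f"synthetic pathway {t + 1}", "pathway", macro, members)
        if planted:
            planted_ids.append(tid)

    query: set[str] = set()
    n_forced = int(round(config.planted_effect * config.term_size))
    for tid in planted_ids:
        members = sorted(terms[tid].members)
        picked = rng.choice(len(members), size=min(n_forced, len(members)),
                            replace=False)
        query.update(members[i] for i in picked)
    remaining = [s for s in universe if s not in query]
    n_background = max(0, config.query_size - len(query))
    picked = rng.choice(len(remaining), size=min(n_background, len(remaining)),
                        replace=False)
    query.update(remaining[i] for i in picked)
    return AnnotationCollection(terms, frozenset(universe)), query, planted_ids


def generate_scored_source(config: SyntheticConfig,
                           base: SpeciesNetwork | nx.Graph | None = None
                           ) -> ScoredInteractionSource:
    """Synthesise a STRING-like scored pair table around a base network.

    True neighbour pairs (the base network's own edges, plus attachments of
    novel interactor symbols to base nodes) draw scores from the high-score
    distribution; background pairs from the low-score distribution.  With
    no base network only background pairs among the novel symbols are
    emitted.
    """
    rng = _fork(config.seed, "scored_source")
    if base is None:
        base_nodes: list[str] = []
        true_pairs: list[tuple[str, str]] = []
    else:
        g = base.undirected_view() if isinstance(base, SpeciesNetwork) else base
        base_nodes = sorted(g.nodes)
        true_pairs = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    novel = [f"NOV{i + 1:03d}" for i in range(config.n_novel_interactors)]

    attach_pairs: list[tuple[str, str]] = []
    if base_nodes:
        for sym in novel:
            n_links = int(rng.integers(1, 4))
            targets = rng.choice(len(base_nodes),
                                 size=min(n_links, len(base_nodes)), replace=False)
            attach_pairs.extend((sym, base_nodes[i]) for i in targets)

    high = list(dict.fromkeys(true_pairs + attach_pairs))
    source = ScoredInteractionSource()
    scores = np.clip(_draw_scores(rng, config.true_score_dist, len(high)), 0.0, 1.0)
    for (a, b), s in zip(high, scores):
        source.add(a, b, float(s))

    all_nodes = sorted(set(base_nodes) | set(novel))
    existing = {frozenset(p) for p in high}
    candidates = [
        (a, b) for a, b in itertools.combinations(all_nodes, 2)
        if frozenset((a, b)) not in existing
    ]
    n_bg = int(round(config.background_pair_rate * len(candidates)))
    if n_bg:
        picked = rng.choice(len(candidates), size=n_bg, replace=False)
        bg_scores = np.clip(
            _draw_scores(rng, config.background_score_dist, n_bg), 0.0, 1.0)
        for i, s in zip(sorted(picked), bg_scores):
            a, b = candidates[i]
            source.add(a, b, float(s))
    return source


def write_scored_source(source: ScoredInteractionSource, path: str | Path) -> None:
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tcombined_score\n")
        for a, b, s in source.pairs():
            fh.write(f"{a}\t{b}\t{s:.6f}\n")


def make_fixtures(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise a canonical fixture directory of all synthetic inputs."""
    from .data_model import write_collection, write_layers
    from .netbuild import build_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, layers = generate_collection(config)
    collection_path = outdir / "collection.tsv"
    layers_path = outdir / "layers.tsv"
    write_collection(records, collection_path)
    # novel interactor symbols get enriched-origin layer annotations so the
    # stratification stage can place them
    novel_rng = _fork(config.seed, "layers/novel")
    weights = np.array([config.layer_weights[l] for l in LAYERS], dtype=float)
    probs = weights / weights.sum()
    layers = layers + [
        LayerAnnotation(f"NOV{i + 1:03d}",
                        LAYERS[int(novel_rng.choice(len(LAYERS), p=probs))],
                        "enriched")
        for i in range(config.n_novel_interactors)
    ]
    write_layers(layers, layers_path)

    symbols = sorted({r.source_symbol for r in records}
                     | {r.target_symbol for r in records}
                     | {f"NOV{i + 1:03d}" for i in range(config.n_novel_interactors)})
    annotations, query, _ = generate_annotations(config, universe=symbols)
    ann_path = outdir / "annotations.tsv"
    write_annotations(annotations, ann_path)
    with (outdir / "query.txt").open("w", newline="\n", encoding="utf-8") as fh:
        fh.writelines(f"{s}\n" for s in sorted(query))

    full = build_network(records, label="allNET")
    source = generate_scored_source(config, full)
    source_path = outdir / "scored_source.tsv"
    write_scored_source(source, source_path)
    return {"collection": collection_path, "layers": layers_path,
            "annotations": ann_path, "scored_source": source_path}
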
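"""Construction, merging and export of species/stage-specific networks.

Each network keeps the full directed, typed edge set (one edge per distinct
``(source, target, link_type)`` triple) and exposes an undirected
simple-graph *view* — self-loops removed, parallel and antiparallel edges
collapsed — on which all topology, hub and clustering computations run.
Direction and link type survive only as edge metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .data_model import InteractionRecord, STAGES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictedEdge:
    """A scored, undirected predicted association (STRING-style)."""

    a: str
    b: str
    score: float
    cycle: int = 1


class SpeciesNetwork:
    """A directed interaction network for one species (optionally one stage).

    Parameters
    ----------
    label:
        Human-readable name, e.g. ``"mTendonNET"``.
    species:
        Species codes whose records populate the network.
    stages:
        Stage filter, or ``None`` for all stages.
    """

    def __init__(self, label: str, species: Iterable[str] = (),
                 stages: Iterable[str] | None = None):
        self.label = label
        self.species = frozenset(species)
        self.stages = frozenset(stages) if stages is not None else frozenset(STAGES)
        self.graph = nx.MultiDiGraph()

    # -- construction ------------------------------------------------------

    def add_record_edge(self, source: str, target: str, link_type: str,
                        origin: str = "literature", score: float | None = None) -> None:
        key = (link_type, origin)
        if not self.graph.has_edge(source, target, key=key):
            attrs = {"link_type": link_type, "origin": origin}
            if score is not None:
                attrs["score"] = score
            self.graph.add_edge(source, target, key=key, **attrs)

    # -- views -------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def directed_edges(self) -> set[tuple[str, str, str]]:
        """Distinct (source, target, link_type) triples."""
        return {(u, v, d["link_type"]) for u, v, d in self.graph.edges(data=True)}

    def self_loops(self) -> set[str]:
        return {u for u, v in self.graph.edges() if u == v}

    def undirected_view(self) -> nx.Graph:
        """Simple undirected graph: no self-loops, no parallel edges.

        Edge attributes keep the maximum score seen over the collapsed
        directed edges (where scores exist) and whether any collapsed edge
        was literature-curated.
        """
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                continue
            if g.has_edge(u, v):
                prev = g[u][v]
                if d.get("score") is not None:
                    prev["score"] = max(prev.get("score", 0.0), d["score"])
                if d.get("origin") == "literature":
                    prev["literature"] = True
            else:
                attrs = {"literature": d.get("origin", "literature") == "literature"}
                if d.get("score") is not None:
                    attrs["score"] = d["score"]
                g.add_edge(u, v, **attrs)
        return g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"<{type(self).__name__} {self.label}: {self.n_nodes} nodes, "
                f"{len(self.directed_edges())} directed edges>")


class EnrichedNetwork(SpeciesNetwork):
    """A literature network merged with predicted interactors.

    Every node carries an origin flag: ``literature`` (curated only),
    ``enriched`` (introduced by prediction only), or ``common`` (curated
    node that the predicted edge set touches as well).  Nodes added by
    iterative expansion also record the cycle at which they entered.
    """

    def __init__(self, label: str, species: Iterable[str] = (),
                 stages: Iterable[str] | None = None):
        super().__init__(label, species, stages)
        self.node_origin: dict[str, str] = {}
        self.cycle_index: dict[str, int] = {}

    def origin_counts(self) -> dict[str, int]:
        counts = {"literature": 0, "common": 0, "enriched": 0}
        for origin in self.node_origin.values():
            counts[origin] += 1
        return counts


def build_network(records: Sequence[InteractionRecord],
                  species: Iterable[str] | None = None,
                  stages: Iterable[str] | None = None,
                  label: str = "") -> SpeciesNetwork:
    """Build a species (and optionally stage) specific network from records.

    Edges are the distinct ``(source, target, link_type)`` triples of the
    records surviving the filters.  An empty filter result yields an empty
    network, which is legitimate (some organisms have no records at a given
    stage) and merely logged.
    """
    species_set = frozenset(species) if species is not None else None
    net = SpeciesNetwork(
        label or "net",
        species_set if species_set is not None else
        {r.species for r in records},
        stages,
    )
    kept = 0
    for r in records:
        if species_set is not None and r.species not in species_set:
            continue
        if r.stage not in net.stages:
            continue
        net.add_record_edge(r.source_symbol, r.target_symbol, r.link_type)
        kept += 1
    if kept == 0:
        logger.info("network %s: no records matched filters (species=%s stages=%s)",
                    net.label, sorted(net.species), sorted(net.stages))
    return net


def merge_enriched(base: SpeciesNetwork,
                   predicted: Iterable[PredictedEdge],
                   cutoff: float = 0.400,
                   label: str | None = None) -> EnrichedNetwork:
    """Merge a literature network with scored predicted associations.

    Predicted edges below ``cutoff`` are rejected (logged).  A predicted
    edge whose node pair already exists in the literature network is never
    allowed to overwrite the curated edge.  Node origin flags follow the
    three-way scheme of :class:`EnrichedNetwork`.
    """
    enriched = EnrichedNetwork(label or f"Enriched {base.label}",
                               base.species, base.stages)
    enriched.graph = base.graph.copy()
    base_nodes = base.nodes
    base_pairs = {frozenset((u, v)) for u, v, _ in base.directed_edges() if u != v}

    touched: set[str] = set()
    for pe in predicted:
        if pe.score < cutoff:
            logger.debug("predicted edge %s-%s rejected: score %.3f < %.3f",
                         pe.a, pe.b, pe.score, cutoff)
            continue
        if pe.a == pe.b:
            continue
        touched.update((pe.a, pe.b))
        for node in (pe.a, pe.b):
            if node not in base_nodes and node not in enriched.cycle_index:
                enriched.cycle_index[node] = pe.cycle
        if frozenset((pe.a, pe.b)) in base_pairs:
            continue  # curated edge takes precedence
        enriched.add_record_edge(pe.a, pe.b, "functional",
                                 origin="predicted", score=pe.score)

    for node in enriched.nodes:
        if node in base_nodes:
            enriched.node_origin[node] = "common" if node in touched else "literature"
        else:
            enriched.node_origin[node] = "enriched"
    return enriched


# ---------------------------------------------------------------------------
# export / import


def export_graph(net: SpeciesNetwork, fmt: str, path: str | Path) -> None:
    """Export a network as SIF, GraphML or edge-TSV.

    SIF lines are ``source<TAB>link_type<TAB>target``.  GraphML carries
    node attributes (``origin`` where known) and edge attributes
    (``link_type``, ``origin``, ``score``).  Edge-TSV round-trips the
    directed edge set through :func:`import_edge_tsv`.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "sif":
        with path.open("w", newline="\n", encoding="utf-8") as fh:
            for u, v, lt in sorted(net.directed_edges()):
                fh.write(f"{u}\t{lt}\t{v}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        origin = getattr(net, "node_origin", {})
        for node in net.graph.nodes:
            g.add_node(node, **({"origin": origin[node]} if node in origin else {}))
        for u, v, d in net.graph.edges(data=True):
            attrs = {"link_type": d["link_type"], "origin": d.get("origin", "literature")}
            if "score" in d:
                attrs["score"] = float(d["score"])
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    elif fmt in ("edge-tsv", "tsv"):
        with path.open("w", newline="\n", encoding="utf-8") as fh:
            fh.write("source\ttarget\tlink_type\n")
            for u, v, lt in sorted(net.directed_edges()):
                fh.write(f"{u}\t{v}\t{lt}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_edge_tsv(path: str | Path, label: str = "imported") -> SpeciesNetwork:
    """Rebuild a network from an edge-TSV export (directed edge set only)."""
    net = SpeciesNetwork(label)
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["source", "target", "link_type"]:
            raise ValueError(f"{path}: not an edge-TSV export")
        for line in fh:
            if not line.strip():
                continue
            u, v, lt = line.rstrip("\n").split("\t")
            net.add_record_edge(u, v, lt)
    return net
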
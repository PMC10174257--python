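"""Topological characterisation of interaction networks.

Computes the standard parameter suite (node/edge counts, mean degree,
diameter, radius, characteristic path length, mean clustering coefficient,
density, connected components), ranked degree tables, and a log-log
least-squares assessment of whether the degree distribution is consistent
with a scale-free (power-law) topology in the Barabási–Albert sense.

Conventions follow the Cytoscape Network Analyzer: everything runs on the
undirected simple-graph view; on disconnected graphs path statistics are
taken over connected node pairs only, the radius over the largest component;
the clustering coefficient is the unweighted mean of local coefficients with
degree<2 nodes contributing 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .netbuild import SpeciesNetwork


@dataclass
class TopologyReport:
    label: str
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    diameter: int
    radius: int
    characteristic_path_length: float
    clustering_coefficient: float
    density: float
    n_connected_components: int
    n_self_loops: int
    degree_distribution: dict[int, int]

    FIELDS = ("n_nodes", "n_edges", "avg_neighbors", "diameter", "radius",
              "characteristic_path_length", "clustering_coefficient",
              "density", "n_connected_components")


@dataclass
class PowerLawFit:
    """Least-squares power-law fit of a degree distribution.

    ``gamma`` is the magnitude of the slope of the ordinary least-squares
    line through ``(log10 k, log10 P(k))`` over the observed degrees k>=1.
    The fit is declined (``declined_reason`` set, ``scale_free`` False)
    when fewer than 3 distinct degrees are observed.
    """

    gamma: float | None
    r_squared: float | None
    n_distinct_degrees: int
    scale_free: bool
    declined_reason: str | None = None


def compute_topology(net: SpeciesNetwork | nx.Graph, label: str | None = None) -> TopologyReport:
    """Compute the full topological parameter suite for a network.

    Accepts either a :class:`~tenonet.netbuild.SpeciesNetwork` (its
    undirected simple view is used) or a plain undirected graph.  Raises
    ``ValueError`` on an empty network.
    """
    if isinstance(net, SpeciesNetwork):
        g = net.undirected_view()
        name = label or net.label
        n_loops = len(net.self_loops())
    else:
        g = net
        name = label or "net"
        n_loops = nx.number_of_selfloops(g)
        if n_loops:
            g = g.copy()
            g.remove_edges_from(nx.selfloop_edges(g))
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    m = g.number_of_edges()

    components = list(nx.connected_components(g))
    ecc_all: dict[str, int] = {}
    path_sum = 0
    path_pairs = 0
    for comp in components:
        sub = g.subgraph(comp)
        if len(comp) == 1:
            ecc_all[next(iter(comp))] = 0
            continue
        ecc = nx.eccentricity(sub)
        ecc_all.update(ecc)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(dists.values())
            path_pairs += len(dists) - 1  # drop the zero self-distance
    diameter = max(ecc_all.values()) if ecc_all else 0
    largest = max(components, key=len)
    radius = (min(nx.eccentricity(g.subgraph(largest)).values())
              if len(largest) > 1 else 0)
    cpl = path_sum / path_pairs if path_pairs else 0.0

    clustering = sum(nx.clustering(g).values()) / n  # degree<2 contributes 0

    return TopologyReport(
        label=name,
        n_nodes=n,
        n_edges=m,
        avg_neighbors=2.0 * m / n,
        diameter=diameter,
        radius=radius,
        characteristic_path_length=cpl,
        clustering_coefficient=clustering,
        density=nx.density(g),
        n_connected_components=len(components),
        n_self_loops=n_loops,
        degree_distribution=dict(Counter(d for _, d in g.degree())),
    )


def degree_table(net: SpeciesNetwork | nx.Graph) -> list[tuple[str, int]]:
    """Node degrees on the undirected simple view, ranked.

    Sorted by degree descending; ties broken lexicographically by symbol.
    """
    g = net.undirected_view() if isinstance(net, SpeciesNetwork) else net
    return sorted(((node, deg) for node, deg in g.degree()),
                  key=lambda it: (-it[1], it[0]))


def fit_power_law(degree_distribution: Mapping[int, int],
                  r_squared_threshold: float = 0.8,
                  gamma_band: tuple[float, float] = (1.0, 4.0)) -> PowerLawFit:
    """Assess scale-freeness of a degree distribution.

    Fits ``log10 P(k) = a - gamma * log10 k`` by ordinary least squares over
    the observed degrees ``k >= 1`` (degree-0 nodes are excluded: they carry
    no connectivity information).  The network is flagged scale-free when
    the fit explains at least ``r_squared_threshold`` of the variance and
    ``gamma`` falls inside ``gamma_band`` — permissive defaults, since a
    small literature-curated network supports only a coarse assessment.
    """
    ks = sorted(k for k, c in degree_distribution.items() if k >= 1 and c > 0)
    total = sum(degree_distribution[k] for k in ks)
    if len(ks) < 3:
        return PowerLawFit(None, None, len(ks), False,
                           declined_reason="fewer than 3 distinct degrees")
    log_k = np.log10(ks)
    log_p = np.log10([degree_distribution[k] / total for k in ks])
    fit = stats.linregress(log_k, log_p)
    gamma = -fit.slope
    r2 = fit.rvalue ** 2
    flag = bool(r2 >= r_squared_threshold and gamma_band[0] <= gamma <= gamma_band[1])
    return PowerLawFit(gamma=float(gamma), r_squared=float(r2),
                       n_distinct_degrees=len(ks), scale_free=flag)


def write_topology_reports(reports: Sequence[TopologyReport], path: str | Path) -> None:
    """One TSV row per network, parameter-table layout."""
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("network\t" + "\t".join(TopologyReport.FIELDS) + "\n")
        for rep in reports:
            vals = []
            for f in TopologyReport.FIELDS:
                v = getattr(rep, f)
                vals.append(f"{v:.6g}" if isinstance(v, float) else str(v))
            fh.write(rep.label + "\t" + "\t".join(vals) + "\n")
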
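"""Hub identification by the mean-plus-k-standard-deviations degree rule.

A *hub* is a hyperconnected node: one whose degree (on the undirected simple
view) is at least ``k`` standard deviations above the network's mean degree,
with ``k = 1`` by default.  The boundary is inclusive — a node sitting
exactly on the threshold is a hub.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .netbuild import SpeciesNetwork


@dataclass
class HubSet:
    label: str
    degree_mean: float
    degree_sd: float
    sd_multiplier: float
    threshold: float
    hubs: list[tuple[str, int]]

    @property
    def symbols(self) -> set[str]:
        return {sym for sym, _ in self.hubs}


def identify_hubs(net: SpeciesNetwork | nx.Graph, k: float = 1.0,
                  sd_kind: str = "population", label: str | None = None) -> HubSet:
    """Select hub nodes: degree >= mean + k * SD of the degree list.

    ``sd_kind`` chooses the population (ddof=0, default) or sample (ddof=1)
    standard deviation; the distinction moves borderline nodes only.  A
    network with fewer than 2 nodes has no defined degree spread and raises
    ``ValueError``.
    """
    if isinstance(net, SpeciesNetwork):
        g = net.undirected_view()
        name = label or net.label
    else:
        g, name = net, label or "net"
    if g.number_of_nodes() < 2:
        raise ValueError("hub identification needs at least 2 nodes")
    if sd_kind not in ("population", "sample"):
        raise ValueError(f"unknown sd_kind {sd_kind!r}")
    if k < 0:
        raise ValueError("sd multiplier must be non-negative")
    degrees = dict(g.degree())
    values = np.array(list(degrees.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=0 if sd_kind == "population" else 1))
    threshold = mean + k * sd
    hubs = sorted(((sym, deg) for sym, deg in degrees.items() if deg >= threshold),
                  key=lambda it: (-it[1], it[0]))
    return HubSet(label=name, degree_mean=mean, degree_sd=sd,
                  sd_multiplier=k, threshold=threshold, hubs=hubs)


def shared_hub_table(hubsets: Sequence[HubSet]) -> list[tuple[str, list[str]]]:
    """Cross-network hub conservation table.

    Each hub symbol is mapped to the networks in which it is a hub, ordered
    by sharing count descending then symbol — surfacing molecules (e.g. a
    transcription factor conserved across organisms) whose hub status is
    reproducible across models.
    """
    if len(hubsets) < 2:
        raise ValueError("need at least 2 hub sets to compare")
    membership: dict[str, list[str]] = {}
    for hs in hubsets:
        for sym in hs.symbols:
            membership.setdefault(sym, []).append(hs.label)
    return sorted(((sym, sorted(labels)) for sym, labels in membership.items()),
                  key=lambda it: (-len(it[1]), it[0]))


def write_hub_report(hubsets: Iterable[HubSet], path: str | Path,
                     layers: Mapping[str, str] | None = None) -> None:
    """Hub report TSV: network, symbol, degree, layer (when annotated)."""
    layers = layers or {}
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("network\tsymbol\tdegree\tlayer\n")
        for hs in hubsets:
            for sym, deg in hs.hubs:
                fh.write(f"{hs.label}\t{sym}\t{deg}\t{layers.get(sym, '')}\n")
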
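"""Set comparisons, signaling-layer stratification and novelty accounting.

Covers the cross-network bookkeeping steps: Venn-style overlap between two
node sets (e.g. the embryo and prepubertal stage networks of one species),
stratification of a network's nodes into the three signaling layers with
the fraction newly contributed by enrichment, and the per-node cluster
cross-tabulation between two stage partitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .data_model import LAYERS, LayerAnnotation
from .mcl import ClusterPartition

logger = logging.getLogger(__name__)


def round_half_down(x: float) -> int:
    """Nearest-integer rounding with exact halves rounded down (62.5 -> 62)."""
    return int(math.ceil(x - 0.5))


@dataclass
class VennResult:
    label_a: str
    label_b: str
    size_a: int
    size_b: int
    shared: int
    union: int
    overlap_percent: int
    only_a: frozenset[str]
    only_b: frozenset[str]
    both: frozenset[str]


@dataclass
class LayerSummary:
    """Per-layer node totals with the enrichment-derived fraction.

    ``percent_new`` is the share of each layer contributed by enrichment
    (origin flag ``enriched``), as a rounded integer percentage.
    """

    totals: dict[str, int]
    new_counts: dict[str, int]
    percent_new: dict[str, int]
    uncovered: frozenset[str]


def venn(set_a: Iterable[str], set_b: Iterable[str],
         labels: tuple[str, str] = ("A", "B")) -> VennResult:
    """Two-set comparison with the overlap expressed as Jaccard x 100.

    The overlap percentage is shared / union (not shared over either set
    alone), rounded to the nearest integer.
    """
    a, b = set(set_a), set(set_b)
    shared = a & b
    union = a | b
    pct = round_half_down(100.0 * len(shared) / len(union)) if union else 0
    return VennResult(
        label_a=labels[0], label_b=labels[1],
        size_a=len(a), size_b=len(b),
        shared=len(shared), union=len(union), overlap_percent=pct,
        only_a=frozenset(a - b), only_b=frozenset(b - a), both=frozenset(shared),
    )


def stratify(nodes: Iterable[str],
             layers: Sequence[LayerAnnotation] | Mapping[str, str],
             origins: Mapping[str, str] | None = None) -> LayerSummary:
    """Stratify nodes into the three signaling layers, counting novelty.

    ``layers`` maps each node to upstream / TF / downstream, either as a
    mapping or as a list of :class:`LayerAnnotation` (whose ``origin``
    field is used unless an explicit ``origins`` mapping is given).  Nodes
    without a layer annotation are excluded from the totals and reported in
    ``uncovered``.
    """
    node_set = set(nodes)
    if isinstance(layers, Mapping):
        layer_of = dict(layers)
        origin_of = dict(origins or {})
    else:
        layer_of = {a.symbol: a.layer for a in layers}
        origin_of = dict(origins) if origins is not None else {
            a.symbol: a.origin for a in layers}
    uncovered = frozenset(n for n in node_set if n not in layer_of)
    if uncovered:
        logger.info("stratify: %d nodes lack a layer annotation", len(uncovered))
    totals = {layer: 0 for layer in LAYERS}
    new_counts = {layer: 0 for layer in LAYERS}
    for n in node_set - uncovered:
        layer = layer_of[n]
        totals[layer] += 1
        if origin_of.get(n, "literature") == "enriched":
            new_counts[layer] += 1
    percent_new = {
        layer: (round_half_down(100.0 * new_counts[layer] / totals[layer])
                if totals[layer] else 0)
        for layer in LAYERS
    }
    return LayerSummary(totals=totals, new_counts=new_counts,
                        percent_new=percent_new, uncovered=uncovered)


def stage_cluster_crosstab(partition_a: ClusterPartition,
                           partition_b: ClusterPartition,
                           shared: Iterable[str]) -> list[dict[str, object]]:
    """Map each shared node to its cluster in each of two partitions.

    One row per shared node, carrying both cluster ids; a node missing
    from either partition is flagged rather than dropped.
    """
    la, lb = partition_a.labels(), partition_b.labels()
    rows = []
    for node in sorted(set(shared)):
        in_a, in_b = node in la, node in lb
        rows.append({
            "node": node,
            "cluster_a": la.get(node),
            "cluster_b": lb.get(node),
            "flagged": not (in_a and in_b),
        })
    return rows


def write_venn(result: VennResult, path: str | Path,
               members: bool = False) -> None:
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("label_a\tlabel_b\tsize_a\tsize_b\tshared\tunion\toverlap_percent\n")
        fh.write(f"{result.label_a}\t{result.label_b}\t{result.size_a}\t"
                 f"{result.size_b}\t{result.shared}\t{result.union}\t"
                 f"{result.overlap_percent}\n")
        if members:
            fh.write(f"# only_{result.label_a}: " + "|".join(sorted(result.only_a)) + "\n")
            fh.write(f"# only_{result.label_b}: " + "|".join(sorted(result.only_b)) + "\n")
            fh.write("# shared: " + "|".join(sorted(result.both)) + "\n")


def write_layer_summary(summary: LayerSummary, path: str | Path) -> None:
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("layer\ttotal\tnew\tpercent_new\n")
        for layer in LAYERS:
            fh.write(f"{layer}\t{summary.totals[layer]}\t"
                     f"{summary.new_counts[layer]}\t{summary.percent_new[layer]}\n")
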
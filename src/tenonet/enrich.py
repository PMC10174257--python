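"""Over-representation analysis and iterative network expansion.

Two pieces of machinery that a live enrichment service would normally
provide, re-expressed over local files so the pipeline is fully
reproducible offline:

* term enrichment — upper-tail hypergeometric tests of a query node set
  against an annotation collection (pathway terms grouped into BRITE-style
  macro-categories), with Benjamini–Hochberg FDR control at alpha 0.05;
* network expansion — iterative growth of a seed network from a scored
  interaction source (STRING-style combined scores in [0, 1]), admitting
  candidate interactors at the medium-confidence cutoff 0.400 over a
  configurable number of cycles (default 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from statsmodels.stats.multitest import multipletests

from .data_model import normalize_symbol
from .netbuild import EnrichedNetwork, PredictedEdge, SpeciesNetwork, merge_enriched

logger = logging.getLogger(__name__)

#: Default macro-category vocabulary (BRITE-style physiological groupings).
MACRO_CATEGORIES: tuple[str, ...] = (
    "growth, differentiation, and survival",
    "morphogenesis and cell motility",
    "nervous system",
    "endocrine system",
)


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    category: str
    macro_category: str
    members: frozenset[str]


@dataclass
class AnnotationCollection:
    """A local term → molecule-set annotation catalogue."""

    terms: dict[str, Term]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            members: set[str] = set()
            for t in self.terms.values():
                members |= t.members
            self.universe = frozenset(members)
        for t in self.terms.values():
            if not t.members:
                raise ValueError(f"term {t.term_id} has no members")
            if not t.members <= self.universe:
                raise ValueError(f"term {t.term_id} has members outside the universe")


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    overlap: int
    query_size: int
    term_size: int
    universe_size: int
    p_value: float
    q_value: float = math.nan
    significant: bool = False


class ScoredInteractionSource:
    """Undirected scored pairs (STRING-style combined scores).

    Scores must lie in [0, 1]; self-pairs are rejected.  When the same pair
    appears more than once the maximum score is kept.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._scores: dict[frozenset[str], float] = {}
        self._neighbors: dict[str, set[str]] = {}
        for a, b, s in pairs:
            self.add(a, b, s)

    def add(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-pair {a!r} not allowed")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1]")
        key = frozenset((a, b))
        self._scores[key] = max(self._scores.get(key, 0.0), score)
        self._neighbors.setdefault(a, set()).add(b)
        self._neighbors.setdefault(b, set()).add(a)

    def __len__(self) -> int:
        return len(self._scores)

    def score(self, a: str, b: str) -> float | None:
        return self._scores.get(frozenset((a, b)))

    def neighbors(self, node: str) -> set[str]:
        return self._neighbors.get(node, set())

    def pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for key, s in self._scores.items():
            a, b = sorted(key)
            out.append((a, b, s))
        return sorted(out)


# ---------------------------------------------------------------------------
# file readers


def read_scored_source(path: str | Path) -> ScoredInteractionSource:
    """Read a 3-column scored pair table (node A, node B, combined score).

    Scores are accepted on [0, 1] or on the 0–1000 integer convention; when
    any score exceeds 1 the whole column is divided by 1000.
    """
    rows: list[tuple[str, str, float]] = []
    with Path(path).open(encoding="utf-8") as fh:
        first = fh.readline()
        parts = first.rstrip("\n").split("\t")
        try:
            float(parts[2])
            fh.seek(0)
        except (ValueError, IndexError):
            pass  # header line, already consumed
        for line in fh:
            if not line.strip():
                continue
            a, b, s = line.rstrip("\n").split("\t")[:3]
            rows.append((normalize_symbol(a), normalize_symbol(b), float(s)))
    if rows and max(s for *_, s in rows) > 1.0:
        rows = [(a, b, s / 1000.0) for a, b, s in rows]
    return ScoredInteractionSource(rows)


def read_annotations(path: str | Path) -> AnnotationCollection:
    """Read an annotation collection.

    Two dialects are accepted:

    * TSV with header ``term_id, name, category, macro_category, members``
      (members pipe-separated);
    * GMT: ``term<TAB>description<TAB>member1<TAB>member2...`` per line
      (category/macro-category then default to "unclassified").
    """
    path = Path(path)
    terms: dict[str, Term] = {}
    with path.open(encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        header = [c.strip().lower() for c in first.split("\t")]
        if header[:5] == ["term_id", "name", "category", "macro_category", "members"]:
            for line in fh:
                if not line.strip():
                    continue
                tid, name, cat, macro, members = line.rstrip("\n").split("\t")[:5]
                terms[tid] = Term(tid, name, cat, macro, frozenset(
                    normalize_symbol(m) for m in members.split("|") if m.strip()))
        else:  # GMT
            for line in [first] + fh.readlines():
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                tid, desc, members = parts[0], parts[1], parts[2:]
                terms[tid] = Term(tid, desc, "unclassified", "unclassified",
                                  frozenset(normalize_symbol(m) for m in members if m.strip()))
    return AnnotationCollection(terms)


def write_annotations(collection: AnnotationCollection, path: str | Path) -> None:
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("term_id\tname\tcategory\tmacro_category\tmembers\n")
        for tid in sorted(collection.terms):
            t = collection.terms[tid]
            fh.write(f"{t.term_id}\t{t.name}\t{t.category}\t{t.macro_category}\t"
                     + "|".join(sorted(t.members)) + "\n")


# ---------------------------------------------------------------------------
# statistics


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), by exact summation.

    X counts the annotated members in a random size-``n`` draw from a
    universe of ``N`` molecules of which ``K`` carry the annotation.  The
    sum runs over integer arithmetic (binomial coefficients), so the result
    is exact to float rounding at the final division.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise ValueError(f"invalid hypergeometric parameters k={k} n={n} K={K} N={N}")
    total = math.comb(N, n)
    upper = sum(math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k, min(n, K) + 1))
    return upper / total


def enrich_terms(query: Iterable[str], annotations: AnnotationCollection,
                 alpha: float = 0.05, min_overlap: int = 2) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query set, BH-adjusted.

    Query symbols absent from the annotation universe are dropped (logged):
    the background for the test is the annotation universe, following the
    usual over-representation convention.  Terms overlapping the effective
    query by fewer than ``min_overlap`` molecules are not tested (singleton
    overlaps are rarely interpretable).  q-values are Benjamini–Hochberg
    adjusted over all tested terms; ``significant`` means q < alpha.
    """
    query_set = {normalize_symbol(s) for s in query}
    effective = query_set & annotations.universe
    dropped = query_set - effective
    if dropped:
        logger.info("enrich_terms: %d query symbols outside the annotation "
                    "universe dropped", len(dropped))
    if not effective:
        logger.warning("enrich_terms: empty effective query")
        return []
    N = len(annotations.universe)
    n = len(effective)
    results: list[EnrichmentResult] = []
    for tid in sorted(annotations.terms):
        t = annotations.terms[tid]
        k = len(effective & t.members)
        if k < min_overlap:
            continue
        p = hypergeometric_test(k, n, len(t.members), N)
        results.append(EnrichmentResult(
            term_id=tid, name=t.name, overlap=k, query_size=n,
            term_size=len(t.members), universe_size=N, p_value=p))
    if results:
        reject, qvals, *_ = multipletests([r.p_value for r in results],
                                          alpha=alpha, method="fdr_bh")
        for r, q, rej in zip(results, qvals, reject):
            r.q_value = float(q)
            r.significant = bool(rej)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results


# ---------------------------------------------------------------------------
# iterative network expansion


def expand_network(base: SpeciesNetwork, source: ScoredInteractionSource,
                   cutoff: float = 0.400, cycles: int = 3,
                   per_cycle: int = 10) -> EnrichedNetwork:
    """Grow a seed network from a scored interaction source.

    Each cycle considers every non-member linked to the current node set by
    at least one source pair with score >= ``cutoff``; candidates are
    ranked by (number of qualifying links into the current set, sum of
    those scores, symbol — descending, descending, ascending) and the top
    ``per_cycle`` are admitted together with all their qualifying edges.
    The ranking depends only on set contents, so the result is invariant to
    the input ordering of the source table.  Expansion stops early when a
    cycle finds no candidate.
    """
    if per_cycle < 1:
        raise ValueError("per_cycle must be >= 1")
    if cycles == 0:  # no expansion requested: the merge is the identity
        return merge_enriched(base, [], cutoff=cutoff)
    current: set[str] = set(base.nodes)
    predicted: list[PredictedEdge] = []
    for cycle in range(1, cycles + 1):
        scored: dict[str, tuple[int, float]] = {}
        for member in current:
            for nb in source.neighbors(member):
                if nb in current:
                    continue
                s = source.score(member, nb)
                if s is None or s < cutoff:
                    continue
                links, total = scored.get(nb, (0, 0.0))
                scored[nb] = (links + 1, total + s)
        if not scored:
            logger.info("expansion stopped at cycle %d: no candidates", cycle)
            break
        ranked = sorted(scored, key=lambda sym: (-scored[sym][0],
                                                 -scored[sym][1], sym))
        admitted = ranked[:per_cycle]
        for sym in admitted:
            for nb in sorted(source.neighbors(sym)):
                if nb not in current and nb not in admitted:
                    continue
                s = source.score(sym, nb)
                if s is not None and s >= cutoff:
                    predicted.append(PredictedEdge(sym, nb, s, cycle))
        current.update(admitted)
    # also record qualifying source edges between original members, so the
    # merged network reflects predicted support among curated nodes
    for a, b, s in source.pairs():
        if s >= cutoff and a in base.nodes and b in base.nodes:
            predicted.append(PredictedEdge(a, b, s, 0))
    return merge_enriched(base, predicted, cutoff=cutoff)


def macro_category_counts(
    results_by_network: Mapping[str, Sequence[EnrichmentResult]],
    annotations: AnnotationCollection,
) -> dict[str, object]:
    """Roll significant terms up into macro-categories.

    Returns per-network counts of distinct significant terms per
    macro-category plus the per-network and pooled unique-term totals.
    Terms lacking a macro-category are counted under "unclassified".
    """
    per_network: dict[str, dict[str, int]] = {}
    unique_totals: dict[str, int] = {}
    pooled: set[str] = set()
    for label, results in results_by_network.items():
        sig = {r.term_id for r in results if r.significant}
        pooled |= sig
        counts: dict[str, int] = {}
        for tid in sig:
            macro = annotations.terms[tid].macro_category or "unclassified"
            if macro == "unclassified":
                logger.info("term %s lacks a macro-category", tid)
            counts[macro] = counts.get(macro, 0) + 1
        per_network[label] = counts
        unique_totals[label] = len(sig)
    return {"per_network": per_network, "unique_totals": unique_totals,
            "pooled_unique_total": len(pooled)}


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("term_id\tname\toverlap\tquery_size\tterm_size\t"
                 "universe_size\tp_value\tq_value\tsignificant\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.name}\t{r.overlap}\t{r.query_size}\t"
                     f"{r.term_size}\t{r.universe_size}\t{r.p_value:.6g}\t"
                     f"{r.q_value:.6g}\t{int(r.significant)}\n")
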
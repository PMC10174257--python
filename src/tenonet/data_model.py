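"""Interaction-collection schema, I/O and composition summaries.

A *collection* is a flat table of directed, literature-curated signaling
interactions: one row per interaction, annotated with the model organism it
was observed in, the developmental stage (embryo — which here includes fetal
records — or prepubertal), whether the link is a direct physical binding or
an indirect functional association, and a citation key.

Seven model organisms are recognised, identified by single-letter codes:

==== ======================
code organism
==== ======================
m    Mus musculus
r    Rattus norvegicus
h    Homo sapiens
e    Equus caballus
b    Bos taurus
g    Gallus gallus
d    Danio rerio
==== ======================

Molecule identifiers are uppercase gene/protein symbols.  Identical symbols
are treated as the same molecule across species; no orthology mapping is
applied.
"""

from __future__ import annotations

import csv
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

SPECIES_CODES: tuple[str, ...] = ("m", "r", "h", "e", "b", "g", "d")
STAGES: tuple[str, ...] = ("embryo", "prepubertal")
LINK_TYPES: tuple[str, ...] = ("physical", "functional")
EFFECTS: tuple[str, ...] = ("up", "down", "unspecified")
LAYERS: tuple[str, ...] = ("upstream", "TF", "downstream")
ORIGINS: tuple[str, ...] = ("literature", "enriched")

#: Columns a collection table must provide (case-insensitive header match).
REQUIRED_COLUMNS: tuple[str, ...] = (
    "source", "target", "link_type", "species", "stage", "reference",
)
#: Optional column: up/down regulation effect of the interaction.
OPTIONAL_COLUMNS: tuple[str, ...] = ("effect",)

_WS = re.compile(r"\s+")


class SchemaError(ValueError):
    """A collection file violates the expected table schema."""


class RowError(ValueError):
    """A single data row is invalid; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def normalize_symbol(raw: str) -> str:
    """Canonicalise a molecule symbol: trim, uppercase, drop internal whitespace."""
    return _WS.sub("", raw.strip()).upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One directed literature-curated interaction.

    Equality is field-by-field, so exact duplicates in a collection are
    detectable by ordinary comparison / hashing.
    """

    source_symbol: str
    target_symbol: str
    link_type: str
    species: str
    stage: str
    reference_id: str = ""
    direction_effect: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.source_symbol or not self.target_symbol:
            raise ValueError("interaction symbols must be non-empty")
        if self.link_type not in LINK_TYPES:
            raise ValueError(f"unknown link_type {self.link_type!r}")
        if self.species not in SPECIES_CODES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.direction_effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.direction_effect!r}")


@dataclass(frozen=True)
class LayerAnnotation:
    """Assignment of a molecule to one of the three signaling layers.

    ``upstream`` covers ligands, receptors and intracellular transducers;
    ``TF`` transcription factors; ``downstream`` ECM and effector molecules.
    ``origin`` records whether the molecule came from the curated literature
    collection or was added by network enrichment.
    """

    symbol: str
    layer: str
    origin: str = "literature"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


def _round_half_up(x: float, decimals: int = 0) -> float:
    f = 10 ** decimals
    return math.floor(x * f + 0.5) / f


def format_share(percent: float) -> float:
    """Format a percentage share: nearest integer at >=2%, one decimal below.

    The mixed precision mirrors how small contributions (<2%) are customarily
    reported with one decimal while larger ones are rounded to integers.
    """
    if percent >= 2.0:
        return float(int(_round_half_up(percent)))
    return _round_half_up(percent, 1)


@dataclass
class CollectionSummary:
    """Composition of a collection by organism and developmental stage."""

    cells: dict[tuple[str, str], int]
    species_totals: dict[str, int]
    stage_totals: dict[str, int]
    total: int
    species_share: dict[str, float]
    stage_share: dict[str, float]

    def as_rows(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for sp in SPECIES_CODES:
            rows.append({
                "species": sp,
                "total": self.species_totals.get(sp, 0),
                "embryo": self.cells.get((sp, "embryo"), 0),
                "prepubertal": self.cells.get((sp, "prepubertal"), 0),
                "share_percent": self.species_share.get(sp, 0.0),
            })
        rows.append({
            "species": "total",
            "total": self.total,
            "embryo": self.stage_totals.get("embryo", 0),
            "prepubertal": self.stage_totals.get("prepubertal", 0),
            "share_percent": 100.0,
        })
        return rows


@dataclass
class ValidationReport:
    """Report-only integrity check of a record collection."""

    n_records: int = 0
    duplicate_groups: list[tuple[InteractionRecord, int]] = field(default_factory=list)
    self_interactions: list[InteractionRecord] = field(default_factory=list)
    multi_layer_symbols: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_duplicate_groups(self) -> int:
        return len(self.duplicate_groups)

    @property
    def n_self_interactions(self) -> int:
        return len(self.self_interactions)

    @property
    def ok(self) -> bool:
        return (not self.duplicate_groups and not self.self_interactions
                and not self.multi_layer_symbols)


# ---------------------------------------------------------------------------
# parsing / writing


def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect:
        return {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    return "," if path.suffix.lower() == ".csv" else "\t"


def parse_collection(path: str | Path, dialect: str | None = None) -> list[InteractionRecord]:
    """Read an interaction collection from a delimited text file.

    Parameters
    ----------
    path:
        TSV (default) or CSV file with a header row naming at least the
        columns ``source, target, link_type, species, stage, reference``
        (case-insensitive).  An ``effect`` column is optional and defaults
        to ``unspecified``.
    dialect:
        ``"tsv"``/``"csv"``, an explicit delimiter character, or ``None`` to
        infer from the file extension.

    Raises
    ------
    SchemaError
        if a required column is missing.
    RowError
        for the first invalid data row (unknown species/stage/link token or
        empty symbol), citing its 1-based row number.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, dialect)
    records: list[InteractionRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        for required in REQUIRED_COLUMNS:
            if required not in cols:
                raise SchemaError(f"{path}: missing required column {required!r}")
        has_effect = "effect" in cols

        def cell(row: Sequence[str], name: str) -> str:
            i = cols[name]
            return row[i].strip() if i < len(row) else ""

        for rownum, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue  # ignore blank lines
            src = normalize_symbol(cell(row, "source"))
            tgt = normalize_symbol(cell(row, "target"))
            if not src or not tgt:
                raise RowError(rownum, "empty molecule symbol")
            link = cell(row, "link_type").lower()
            if link not in LINK_TYPES:
                raise RowError(rownum, f"unknown link_type token {link!r}")
            species = cell(row, "species").lower()
            if species not in SPECIES_CODES:
                raise RowError(rownum, f"unknown species token {species!r}")
            stage = cell(row, "stage").lower()
            if stage not in STAGES:
                raise RowError(rownum, f"unknown stage token {stage!r}")
            effect = cell(row, "effect").lower() if has_effect else "unspecified"
            if not effect:
                effect = "unspecified"
            if effect not in EFFECTS:
                raise RowError(rownum, f"unknown effect token {effect!r}")
            records.append(InteractionRecord(
                source_symbol=src, target_symbol=tgt, link_type=link,
                species=species, stage=stage,
                reference_id=cell(row, "reference"),
                direction_effect=effect,
            ))
    return records


def write_collection(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write records as the canonical tab-delimited table (LF, UTF-8, header)."""
    path = Path(path)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("source\ttarget\tlink_type\teffect\tspecies\tstage\treference\n")
        for r in records:
            fh.write("\t".join((
                r.source_symbol, r.target_symbol, r.link_type,
                r.direction_effect, r.species, r.stage, r.reference_id,
            )) + "\n")


def parse_layers(path: str | Path, dialect: str | None = None) -> list[LayerAnnotation]:
    """Read layer annotations: columns ``symbol, layer`` plus optional ``origin``."""
    path = Path(path)
    delim = _sniff_delimiter(path, dialect)
    out: list[LayerAnnotation] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        if "symbol" not in cols or "layer" not in cols:
            raise SchemaError(f"{path}: layer file needs 'symbol' and 'layer' columns")
        for rownum, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue
            sym = normalize_symbol(row[cols["symbol"]])
            layer = row[cols["layer"]].strip()
            origin = (row[cols["origin"]].strip().lower()
                      if "origin" in cols and cols["origin"] < len(row) and row[cols["origin"]].strip()
                      else "literature")
            try:
                out.append(LayerAnnotation(sym, layer, origin))
            except ValueError as exc:
                raise RowError(rownum, str(exc)) from None
    return out


def write_layers(annotations: Iterable[LayerAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("symbol\tlayer\torigin\n")
        for a in annotations:
            fh.write(f"{a.symbol}\t{a.layer}\t{a.origin}\n")


# ---------------------------------------------------------------------------
# validation / summary


def validate_collection(
    records: Sequence[InteractionRecord],
    layers: Sequence[LayerAnnotation] | None = None,
) -> ValidationReport:
    """Check a record list for duplicates, self-interactions and layer clashes.

    Purely observational: records are never mutated or dropped.  When a set
    of layer annotations is supplied, symbols annotated under more than one
    layer are reported as well.
    """
    report = ValidationReport(n_records=len(records))
    counts = Counter(records)
    report.duplicate_groups = sorted(
        ((rec, n) for rec, n in counts.items() if n > 1),
        key=lambda it: (it[0].source_symbol, it[0].target_symbol),
    )
    report.self_interactions = [
        r for r in records if r.source_symbol == r.target_symbol
    ]
    if layers:
        seen: dict[str, set[str]] = {}
        for ann in layers:
            seen.setdefault(ann.symbol, set()).add(ann.layer)
        report.multi_layer_symbols = {
            sym: ls for sym, ls in seen.items() if len(ls) > 1
        }
    return report


def summarize_collection(records: Sequence[InteractionRecord]) -> CollectionSummary:
    """Tabulate a collection per (species, stage) with percentage shares.

    Shares are percentages of the grand total; each species total equals the
    sum of its embryo and prepubertal cells by construction.
    """
    cells: Counter[tuple[str, str]] = Counter(
        (r.species, r.stage) for r in records
    )
    species_totals = {
        sp: sum(cells.get((sp, st), 0) for st in STAGES) for sp in SPECIES_CODES
    }
    species_totals = {sp: n for sp, n in species_totals.items() if n}
    stage_totals = {
        st: sum(cells.get((sp, st), 0) for sp in SPECIES_CODES) for st in STAGES
    }
    total = sum(species_totals.values())
    species_share = {
        sp: format_share(100.0 * n / total) for sp, n in species_totals.items()
    } if total else {}
    stage_share = {
        st: format_share(100.0 * n / total) for st, n in stage_totals.items()
    } if total else {}
    return CollectionSummary(
        cells=dict(cells), species_totals=species_totals,
        stage_totals=stage_totals, total=total,
        species_share=species_share, stage_share=stage_share,
    )


def write_summary(summary: CollectionSummary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("species\ttotal\tembryo\tprepubertal\tshare_percent\n")
        for row in summary.as_rows():
            fh.write("{species}\t{total}\t{embryo}\t{prepubertal}\t{share_percent:g}\n"
                     .format(**row))
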
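"""The packaged 46-trait functional catalogue and trait calling.

The catalogue transcribes a curated table of functional traits of two
sulphur-oxidizing Gammaproteobacteria — the obligate ciliate ectosymbiont
*Candidatus* Thiobius zoothamnicola and its free-living relative strain
Milos ODIII6 — spanning carbon, nitrogen, sulphur, oxygen, hydrogen and
phosphorus metabolism, storage, motility and interaction machinery.  Each
trait is defined by a boolean gene-composition expression (see
:mod:`thiotraits.dsl`); calling traits for a genome reduces to evaluating
those expressions against the genome's annotated gene symbols.

The transcription keeps the original text verbatim, including the literal
``shdA`` spelling in the cytochrome-bd row; the packaged alias table maps
``shdA`` to the canonical ``sdhA`` (succinate dehydrogenase flavoprotein)
and can be disabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from . import dsl
from .dsl import (
    DEFAULT_MACROS,
    DslError,
    MacroTable,
    TraitExpr,
    EvaluationResult,
)

__all__ = [
    "TraitDefinition",
    "TraitCatalog",
    "GenePresenceTable",
    "TraitMatrix",
    "CatalogError",
    "ParseError",
    "DuplicateId",
    "DuplicateShortName",
    "MissingColumn",
    "UnknownGenome",
    "DEFAULT_ALIASES",
    "load_catalog",
    "load_default_catalog",
    "load_published_calls",
    "read_presence_table",
    "write_presence_table",
    "call_traits",
    "trait_counts",
]

PRESENT = "Present"
ABSENT = "Absent"

#: Canonicalization applied to gene symbols on both sides of an evaluation
#: (gene sets *and* expression atoms).  The single packaged entry repairs
#: the catalogue's ``shdA`` spelling of the succinate dehydrogenase
#: flavoprotein gene ``sdhA``.
DEFAULT_ALIASES: dict[str, str] = {"shdA": "sdhA"}

_CATALOG_COLUMNS = [
    "Id",
    "TraitGroup",
    "TraitName",
    "ShortTraitName",
    "GeneTraitComposition",
]


class CatalogError(ValueError):
    pass


class ParseError(CatalogError):
    pass


class DuplicateId(CatalogError):
    pass


class DuplicateShortName(CatalogError):
    pass


class MissingColumn(CatalogError):
    pass


class UnknownGenome(KeyError):
    pass


@dataclass(frozen=True)
class TraitDefinition:
    id: int
    trait_group: str
    trait_name: str
    short_name: str
    expression_text: str  # verbatim, as printed
    expr: TraitExpr  # parsed + macro-expanded


@dataclass(frozen=True)
class TraitCatalog:
    definitions: tuple[TraitDefinition, ...]
    macros: MacroTable = DEFAULT_MACROS
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def by_short_name(self, short_name: str) -> TraitDefinition:
        for d in self.definitions:
            if d.short_name == short_name:
                return d
        raise KeyError(short_name)

    def short_names(self) -> list[str]:
        return [d.short_name for d in self.definitions]

    def canonical_expr(self, definition: TraitDefinition) -> TraitExpr:
        """The definition's expression with alias canonicalization applied."""
        return dsl.apply_aliases(definition.expr, self.aliases)

    def gene_universe(self) -> frozenset[str]:
        """Union of required/alternative genes of all traits (canonical)."""
        genes: set[str] = set()
        for d in self.definitions:
            required, _ = dsl.genes_mentioned(self.canonical_expr(d))
            genes |= required
        return frozenset(genes)


def _parse_rows(
    rows: Iterable[tuple[int, list[str]]],
    macros: MacroTable,
    aliases: Mapping[str, str],
) -> TraitCatalog:
    definitions: list[TraitDefinition] = []
    seen_ids: set[int] = set()
    seen_short: set[str] = set()
    for lineno, fields in rows:
        if len(fields) < 5:
            raise ParseError(f"row {lineno}: expected 5 columns, got {len(fields)}")
        raw_id, group, name, short, expr_text = (f.strip() for f in fields[:5])
        try:
            trait_id = int(raw_id)
        except ValueError:
            raise ParseError(f"row {lineno}: non-integer Id {raw_id!r}")
        if trait_id in seen_ids:
            raise DuplicateId(f"row {lineno}: duplicate Id {trait_id}")
        if short in seen_short:
            raise DuplicateShortName(f"row {lineno}: duplicate ShortTraitName {short!r}")
        seen_ids.add(trait_id)
        seen_short.add(short)
        try:
            expr = dsl.parse_expression(expr_text, macros=macros)
        except DslError as exc:
            raise ParseError(
                f"row {lineno} ({short!r}): bad expression: {exc}"
            ) from exc
        definitions.append(
            TraitDefinition(trait_id, group, name, short, expr_text, expr)
        )
    return TraitCatalog(tuple(definitions), macros=macros, aliases=dict(aliases))


def load_catalog(
    path: str | Path,
    *,
    macros: MacroTable = DEFAULT_MACROS,
    aliases: Mapping[str, str] | None = None,
) -> TraitCatalog:
    """Load a trait catalogue from a 5-column TSV file.

    Columns (header required): Id, TraitGroup, TraitName, ShortTraitName,
    GeneTraitComposition.  ``#`` lines are comments.  Pass ``aliases={}`` to
    disable symbol canonicalization.
    """
    text = Path(path).read_text(encoding="utf-8")
    return _catalog_from_text(
        text, macros=macros, aliases=DEFAULT_ALIASES if aliases is None else aliases
    )


def _catalog_from_text(
    text: str,
    *,
    macros: MacroTable,
    aliases: Mapping[str, str],
) -> TraitCatalog:
    rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            for col in _CATALOG_COLUMNS:
                if col not in header:
                    raise MissingColumn(f"missing column {col!r} in header")
            continue
        ordered = [fields[header.index(col)] if header.index(col) < len(fields) else ""
                   for col in _CATALOG_COLUMNS]
        rows.append((lineno, ordered))
    if header is None:
        raise MissingColumn("empty catalogue file: no header row")
    return _parse_rows(rows, macros, aliases)


def load_default_catalog(*, use_aliases: bool = True) -> TraitCatalog:
    """Load the packaged 46-trait catalogue."""
    text = (
        resources.files("thiotraits.data")
        .joinpath("trait_catalog.tsv")
        .read_text(encoding="utf-8")
    )
    return _catalog_from_text(
        text,
        macros=DEFAULT_MACROS,
        aliases=DEFAULT_ALIASES if use_aliases else {},
    )


def load_published_calls() -> dict[str, dict[str, str]]:
    """Packaged Present/Absent columns for the two study genomes.

    Returns ``{genome: {short_name: "Present"|"Absent"}}`` with genomes
    ``Thiobius`` and ``ODIII6``.
    """
    text = (
        resources.files("thiotraits.data")
        .joinpath("published_calls.tsv")
        .read_text(encoding="utf-8")
    )
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    genomes = header[1:]
    calls: dict[str, dict[str, str]] = {g: {} for g in genomes}
    for line in lines[1:]:
        fields = line.split("\t")
        for genome, call in zip(genomes, fields[1:]):
            calls[genome][fields[0]] = call
    return calls


# --------------------------------------------------------------------------
# gene presence tables

@dataclass
class GenePresenceTable:
    """Per-genome sets of annotated gene symbols."""

    genomes: dict[str, set[str]]

    def __getitem__(self, genome_id: str) -> set[str]:
        try:
            return self.genomes[genome_id]
        except KeyError:
            raise UnknownGenome(genome_id)

    def genome_ids(self) -> list[str]:
        return list(self.genomes)


def read_presence_table(path: str | Path, *, header: bool = False) -> GenePresenceTable:
    """Read a two-column (genome_id, gene_symbol) TSV; ``#`` lines ignored."""
    genomes: dict[str, set[str]] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if header and body:
        body = body[1:]
    for lineno, line in enumerate(body, start=1):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise CatalogError(
                f"presence table line {lineno}: expected genome_id<TAB>gene_symbol"
            )
        genomes.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return GenePresenceTable(genomes)


def write_presence_table(
    table: GenePresenceTable, path: str | Path, *, comment: str | None = None
) -> None:
    lines: list[str] = []
    if comment:
        lines.extend("# " + ln for ln in comment.splitlines())
    for genome_id in sorted(table.genomes):
        for gene in sorted(table.genomes[genome_id]):
            lines.append(f"{genome_id}\t{gene}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# trait calling

@dataclass
class TraitMatrix:
    """Present/Absent calls (trait x genome) plus per-call explanations."""

    catalog: TraitCatalog
    genome_ids: list[str]
    calls: dict[tuple[str, str], str]  # (short_name, genome_id) -> call
    explanations: dict[tuple[str, str], EvaluationResult]

    def call(self, short_name: str, genome_id: str) -> str:
        if genome_id not in self.genome_ids:
            raise UnknownGenome(genome_id)
        return self.calls[(short_name, genome_id)]

    def present_set(self, genome_id: str) -> set[str]:
        if genome_id not in self.genome_ids:
            raise UnknownGenome(genome_id)
        return {
            d.short_name
            for d in self.catalog
            if self.calls[(d.short_name, genome_id)] == PRESENT
        }

    def column(self, genome_id: str) -> dict[str, str]:
        if genome_id not in self.genome_ids:
            raise UnknownGenome(genome_id)
        return {
            d.short_name: self.calls[(d.short_name, genome_id)]
            for d in self.catalog
        }

    def to_tsv(self) -> str:
        lines = ["ShortTraitName\t" + "\t".join(self.genome_ids)]
        for d in self.catalog:
            row = [d.short_name] + [
                self.calls[(d.short_name, g)] for g in self.genome_ids
            ]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload: dict[str, dict[str, object]] = {}
        for g in self.genome_ids:
            column: dict[str, object] = {}
            for d in self.catalog:
                res = self.explanations[(d.short_name, g)]
                column[d.short_name] = {
                    "call": self.calls[(d.short_name, g)],
                    "missing_required": sorted(res.missing_required),
                    "ignored_optional": sorted(res.ignored_optional),
                }
            payload[g] = column
        return json.dumps(payload, indent=2, sort_keys=True)


def call_traits(catalog: TraitCatalog, table: GenePresenceTable) -> TraitMatrix:
    """Call every catalogue trait for every genome in the presence table.

    Gene symbols (and expression atoms) are canonicalized through the
    catalogue's alias table before matching.  Matching is otherwise exact
    and case-sensitive.  A genome with an empty gene set yields all-Absent
    calls (not an error).
    """
    aliases = catalog.aliases
    genome_ids = table.genome_ids()
    calls: dict[tuple[str, str], str] = {}
    explanations: dict[tuple[str, str], EvaluationResult] = {}
    canonical = {
        d.short_name: catalog.canonical_expr(d) for d in catalog
    }
    for genome_id in genome_ids:
        genes = frozenset(aliases.get(g, g) for g in table.genomes[genome_id])
        for d in catalog:
            result = dsl.evaluate(canonical[d.short_name], genes)
            calls[(d.short_name, genome_id)] = PRESENT if result.present else ABSENT
            explanations[(d.short_name, genome_id)] = result
    return TraitMatrix(catalog, genome_ids, calls, explanations)


def trait_counts(
    matrix: TraitMatrix,
) -> tuple[dict[str, int], dict[tuple[str, str], int]]:
    """Per-genome Present counts and pairwise shared-Present counts.

    The shared map covers every ordered pair including the diagonal, so
    ``shared[(g, g)] == counts[g]``.
    """
    present = {g: matrix.present_set(g) for g in matrix.genome_ids}
    counts = {g: len(s) for g, s in present.items()}
    shared = {
        (a, b): len(present[a] & present[b])
        for a in matrix.genome_ids
        for b in matrix.genome_ids
    }
    return counts, shared
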
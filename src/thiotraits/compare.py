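"""Shared/unique comparison of two genomes at several granularities.

The reporting layer behind genome-reduction comparisons: Euler counts
(only-A, shared, only-B) of feature sets at gene/orthologue, metabolic
pathway, module and trait granularity; the subset fraction
|A∩B| / min(|A|, |B|) that quantifies how far the smaller repertoire is
contained in the larger; COG-category count tables; and keyword-based
mobilome (phage / other mobile genetic element) counting over annotation
product descriptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EulerCounts",
    "MobilomeCounts",
    "FeatureSets",
    "ComparisonReport",
    "BothEmpty",
    "SchemaError",
    "DEFAULT_PHAGE_KEYWORDS",
    "DEFAULT_MGE_KEYWORDS",
    "euler_counts",
    "subset_fraction",
    "count_mobilome",
    "cog_count_table",
    "build_report",
]

GRANULARITIES = ("orthologs", "pathways", "modules", "traits")

#: Keyword vocabularies for mobilome counting (case-insensitive substring
#: match on product descriptions).  A product matching both lists counts as
#: phage only.  Override per call or via configuration.
DEFAULT_PHAGE_KEYWORDS = (
    "phage",
    "prophage",
    "capsid",
    "tail protein",
    "terminase",
    "portal",
)
DEFAULT_MGE_KEYWORDS = (
    "transposase",
    "insertion sequence",
    "integrase",
    "recombinase",
    "mobile element",
    "plasmid",
)


class BothEmpty(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class EulerCounts:
    only_a: int
    shared: int
    only_b: int
    only_a_members: tuple[str, ...] = ()
    shared_members: tuple[str, ...] = ()
    only_b_members: tuple[str, ...] = ()

    def as_triple(self) -> tuple[int, int, int]:
        return (self.only_a, self.shared, self.only_b)

    def mirrored(self) -> "EulerCounts":
        return EulerCounts(
            self.only_b,
            self.shared,
            self.only_a,
            self.only_b_members,
            self.shared_members,
            self.only_a_members,
        )


def euler_counts(set_a: Iterable[str], set_b: Iterable[str]) -> EulerCounts:
    """Exclusive/shared/exclusive counts of two feature sets, with members."""
    a, b = set(set_a), set(set_b)
    return EulerCounts(
        only_a=len(a - b),
        shared=len(a & b),
        only_b=len(b - a),
        only_a_members=tuple(sorted(a - b)),
        shared_members=tuple(sorted(a & b)),
        only_b_members=tuple(sorted(b - a)),
    )


def subset_fraction(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A ∩ B| / min(|A|, |B|): 1.0 iff the smaller set is contained."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise BothEmpty("subset fraction of two empty sets")
    return len(a & b) / min(len(a) or len(b), len(b) or len(a))


# --------------------------------------------------------------------------
# mobilome

@dataclass(frozen=True)
class MobilomeCounts:
    phage_count: int
    other_mge_count: int
    phage_genes: tuple[str, ...] = ()
    mge_genes: tuple[str, ...] = ()

    def as_pair(self) -> tuple[int, int]:
        return (self.phage_count, self.other_mge_count)


def _as_annotation_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(list(table))
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "product"])
    for col in ("gene_id", "product"):
        if col not in df.columns:
            raise SchemaError(f"annotation table lacks column {col!r}")
    return df


def count_mobilome(
    annotation_table,
    phage_keywords: Sequence[str] = DEFAULT_PHAGE_KEYWORDS,
    mge_keywords: Sequence[str] = DEFAULT_MGE_KEYWORDS,
) -> MobilomeCounts:
    """Count phage and other mobile-genetic-element genes by product keyword.

    Case-insensitive substring matching; a gene matching both vocabularies
    counts as phage only, so every matched gene is counted exactly once.
    """
    if not phage_keywords or not mge_keywords:
        raise ValueError("keyword lists must be non-empty")
    df = _as_annotation_frame(annotation_table)
    phage_kw = [k.lower() for k in phage_keywords]
    mge_kw = [k.lower() for k in mge_keywords]
    phage_genes: list[str] = []
    mge_genes: list[str] = []
    for gene_id, product in zip(df.get("gene_id", []), df.get("product", [])):
        text = str(product).lower()
        if any(k in text for k in phage_kw):
            phage_genes.append(str(gene_id))
        elif any(k in text for k in mge_kw):
            mge_genes.append(str(gene_id))
    return MobilomeCounts(
        len(phage_genes), len(mge_genes), tuple(phage_genes), tuple(mge_genes)
    )


# --------------------------------------------------------------------------
# COG categories

def cog_count_table(
    annotations_per_genome: Mapping[str, object],
    orthologs_per_genome: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-genome gene counts by single-letter COG category.

    A gene tagged with several letters (e.g. ``CE``) counts once per
    letter; untagged genes are tallied under ``unassigned``.  Rows are
    categories, columns genomes.  When an orthologue mapping
    (genome -> gene_id -> family id) is supplied, an extra per-category
    ``shared_fraction:<cat>`` table could be derived by the caller from the
    returned membership; here only the counts are produced.
    """
    counts: dict[str, dict[str, int]] = {}
    for genome, table in annotations_per_genome.items():
        df = _as_annotation_frame(table)
        tally: dict[str, int] = {}
        cats = df["categories"] if "categories" in df.columns else [""] * len(df)
        for raw in cats:
            letters = [c for c in str(raw).strip() if c.isalpha()] if not pd.isna(raw) else []
            if not letters:
                tally["unassigned"] = tally.get("unassigned", 0) + 1
            else:
                for letter in letters:
                    tally[letter] = tally.get(letter, 0) + 1
        counts[genome] = tally
    frame = pd.DataFrame(counts).fillna(0).astype(int)
    return frame.sort_index()


# --------------------------------------------------------------------------
# reports

@dataclass
class FeatureSets:
    """Feature sets of one genome at the supported granularities."""

    genome_id: str
    traits: set[str] | None = None
    pathways: set[str] | None = None
    modules: set[str] | None = None
    orthologs: set[str] | None = None
    annotations: object | None = None  # annotation table for mobilome counts


@dataclass
class ComparisonReport:
    genome_a: str
    genome_b: str
    granularities: dict[str, EulerCounts] = field(default_factory=dict)
    subset_fractions: dict[str, float] = field(default_factory=dict)
    mobilome: dict[str, MobilomeCounts] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {
            "schema_version": 1,
            "genome_a": self.genome_a,
            "genome_b": self.genome_b,
            "granularities": {},
        }
        for gran in GRANULARITIES:
            if gran not in self.granularities:
                out["granularities"][gran] = None  # absent, not zero
                continue
            e = self.granularities[gran]
            out["granularities"][gran] = {
                "only_a": e.only_a,
                "shared": e.shared,
                "only_b": e.only_b,
                "only_a_members": list(e.only_a_members),
                "shared_members": list(e.shared_members),
                "only_b_members": list(e.only_b_members),
                "subset_fraction": self.subset_fractions.get(gran),
            }
        if self.mobilome:
            out["mobilome"] = {
                g: {
                    "phage_count": m.phage_count,
                    "other_mge_count": m.other_mge_count,
                    "phage_genes": list(m.phage_genes),
                    "mge_genes": list(m.mge_genes),
                }
                for g, m in self.mobilome.items()
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["granularity\tonly_a\tshared\tonly_b\tsubset_fraction"]
        for gran in GRANULARITIES:
            if gran not in self.granularities:
                continue
            e = self.granularities[gran]
            frac = self.subset_fractions.get(gran)
            frac_str = f"{frac:.4f}" if frac is not None else "NA"
            lines.append(f"{gran}\t{e.only_a}\t{e.shared}\t{e.only_b}\t{frac_str}")
        return "\n".join(lines) + "\n"


def build_report(a: FeatureSets, b: FeatureSets) -> ComparisonReport:
    """Assemble the multi-granularity comparison report for two genomes.

    Granularities missing from either genome are marked absent (``null`` in
    JSON), never reported as zero.
    """
    report = ComparisonReport(genome_a=a.genome_id, genome_b=b.genome_id)
    for gran in GRANULARITIES:
        set_a = getattr(a, gran)
        set_b = getattr(b, gran)
        if set_a is None or set_b is None:
            continue
        counts = euler_counts(set_a, set_b)
        report.granularities[gran] = counts
        if set_a or set_b:
            report.subset_fractions[gran] = subset_fraction(set_a, set_b)
    for fs in (a, b):
        if fs.annotations is not None:
            report.mobilome[fs.genome_id] = count_mobilome(fs.annotations)
    return report
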
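"""Seeded generators for every input class of the pipeline, with ground truth.

Each generator emulates one class of real input — contig assemblies with a
controlled GC content, diverged proteome pairs with a known one-to-one
orthologue map, gene-presence tables that realize a prescribed
Present/Absent trait vector under the packaged catalogue, nucleotide pairs
at a set identity, and annotation tables with planted mobilome genes and a
fixed COG-category distribution.  All randomness flows from an explicit
seed through numpy's PCG64 generator, so identical configurations produce
identical outputs, and every generator returns a truth object that the
consuming analysis can be checked against.

Sequence divergence uses a per-site substitution model without indels:
each position of the copy mutates independently with probability
(100 - target identity)/100 to a uniformly chosen different letter, so the
expected realized identity equals the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import dsl
from .catalog import (
    ABSENT,
    PRESENT,
    GenePresenceTable,
    TraitCatalog,
    call_traits,
)
from .dsl import Alternation, Conjunction, GeneRef, Sign, TraitExpr

__all__ = [
    "InvalidTarget",
    "InvalidCounts",
    "InfeasibleVector",
    "IterationCapExceeded",
    "AssemblyTruth",
    "ProteomePairTruth",
    "PresenceTruth",
    "AnnotationTruth",
    "gen_assembly",
    "gen_proteome_pair",
    "gen_presence_table",
    "gen_nt_pair",
    "gen_annotation_table",
]

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class InvalidTarget(ValueError):
    pass


class InvalidCounts(ValueError):
    pass


class InfeasibleVector(ValueError):
    def __init__(self, message: str, conflicts: list[str]):
        super().__init__(message)
        self.conflicts = conflicts


class IterationCapExceeded(InfeasibleVector):
    pass


# --------------------------------------------------------------------------
# assemblies

@dataclass(frozen=True)
class AssemblyTruth:
    seed: int
    gc_target: float
    contig_lengths: tuple[int, ...]


def _random_lengths(rng, n: int, length_distribution) -> np.ndarray:
    kind = length_distribution[0]
    if kind == "fixed":
        return np.full(n, int(length_distribution[1]))
    if kind == "lognormal":
        _, mean_bp, sigma = length_distribution
        mu = np.log(mean_bp) - sigma**2 / 2
        lengths = rng.lognormal(mu, sigma, size=n)
        return np.maximum(lengths.astype(int), 200)
    raise InvalidTarget(f"unknown length distribution {kind!r}")


def gen_assembly(
    n_contigs: int = 46,
    length_distribution=("lognormal", 52_000, 0.8),
    gc_target: float = 0.494,
    seed: int = 0,
) -> tuple[list[SeqRecord], AssemblyTruth]:
    """Simulate a contig assembly with i.i.d. bases at a target GC.

    P(G) = P(C) = gc_target/2 and P(A) = P(T) = (1-gc_target)/2; with
    >= 100 kb of sequence the realized GC is within about half a
    percentage point of the target.  Defaults mimic a mid-sized reduced
    bacterial genome (46 contigs, ~2.4 Mb, GC 49.4%).
    """
    if n_contigs < 1:
        raise InvalidTarget("n_contigs must be >= 1")
    if not (0 < gc_target < 1):
        raise InvalidTarget("gc_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lengths = _random_lengths(rng, n_contigs, length_distribution)
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    records = []
    for i, length in enumerate(lengths, start=1):
        bases = rng.choice(_NT, size=int(length), p=p)
        records.append(
            SeqRecord(
                Seq("".join(bases)),
                id=f"contig_{i:04d}",
                description=f"simulated gc_target={gc_target} seed={seed}",
            )
        )
    return records, AssemblyTruth(seed, gc_target, tuple(int(x) for x in lengths))


# --------------------------------------------------------------------------
# diverged sequence pairs

def _mutate(rng, seq: np.ndarray, alphabet: np.ndarray, p_sub: float) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(len(seq)) < p_sub
    idx = np.flatnonzero(mask)
    if idx.size:
        # draw a different letter uniformly: shift by 1..k-1 in alphabet order
        pos = np.searchsorted(alphabet, seq[idx])
        shift = rng.integers(1, len(alphabet), size=idx.size)
        out[idx] = alphabet[(pos + shift) % len(alphabet)]
    return out


@dataclass(frozen=True)
class ProteomePairTruth:
    seed: int
    target_identity_pct: float
    #: a-id -> b-id orthologue pairs
    pairs: dict[str, str]
    #: per a-id realized percent identity (direct column comparison)
    realized_identity_pct: dict[str, float]

    @property
    def mean_realized_identity_pct(self) -> float:
        return float(np.mean(list(self.realized_identity_pct.values())))


def gen_proteome_pair(
    n_proteins: int = 100,
    mean_length: int = 300,
    target_identity_pct: float = 70.0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], ProteomePairTruth]:
    """Simulate two proteomes related by per-site substitution.

    Proteome B contains one mutated copy of each protein of A (substitution
    probability ``(100 - target)/100`` per site, no indels), giving a known
    one-to-one orthologue map for benchmarking RBH recovery and AAI
    estimation.  Lengths are Poisson-scattered around ``mean_length``.
    """
    if n_proteins < 1:
        raise InvalidTarget("n_proteins must be >= 1")
    if not (0 < target_identity_pct <= 100):
        raise InvalidTarget("target identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    p_sub = (100.0 - target_identity_pct) / 100.0
    a: dict[str, str] = {}
    b: dict[str, str] = {}
    pairs: dict[str, str] = {}
    realized: dict[str, float] = {}
    lengths = np.maximum(rng.poisson(mean_length, size=n_proteins), 30)
    for i, length in enumerate(lengths, start=1):
        aid, bid = f"a{i:04d}", f"b{i:04d}"
        seq_a = rng.choice(_AA, size=int(length))
        seq_b = _mutate(rng, seq_a, _AA, p_sub)
        a[aid] = "".join(seq_a)
        b[bid] = "".join(seq_b)
        pairs[aid] = bid
        realized[aid] = 100.0 * float(np.mean(seq_a == seq_b))
    return a, b, ProteomePairTruth(seed, target_identity_pct, pairs, realized)


def gen_nt_pair(
    length: int = 1400,
    target_identity_pct: float = 95.0,
    seed: int = 0,
) -> tuple[str, str, float]:
    """A nucleotide pair diverged by per-site substitution; returns realized %."""
    if length < 1:
        raise InvalidTarget("length must be >= 1")
    if not (0 < target_identity_pct <= 100):
        raise InvalidTarget("target identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    p_sub = (100.0 - target_identity_pct) / 100.0
    seq_a = rng.choice(_NT, size=length)
    seq_b = _mutate(rng, seq_a, _NT, p_sub)
    realized = 100.0 * float(np.mean(seq_a == seq_b))
    return "".join(seq_a), "".join(seq_b), realized


# --------------------------------------------------------------------------
# gene presence tables realizing a trait vector

@dataclass(frozen=True)
class PresenceTruth:
    seed: int
    target_vector: dict[str, str]  # short_name -> Present/Absent
    witness_genes: frozenset[str]
    decoy_genes: frozenset[str]
    attempts: int


def _witness(expr: TraitExpr, choose) -> set[str]:
    """Genes satisfying ``expr``: required terms only, one branch per OR."""
    if isinstance(expr, GeneRef):
        return {expr.symbol}
    if isinstance(expr, Conjunction):
        genes: set[str] = set()
        for sign, sub in expr.terms:
            if sign is Sign.REQUIRED:
                genes |= _witness(sub, choose)
        return genes
    branches = [_witness(b, choose) for b in expr.branches]
    return branches[choose(expr, branches)]


def _cheapest_first(expr: Alternation, branches: list[set[str]]) -> int:
    sizes = [len(b) for b in branches]
    return sizes.index(min(sizes))


def gen_presence_table(
    catalog: TraitCatalog,
    target_vector: dict[str, str],
    decoy_genes: int = 25,
    seed: int = 0,
    genome_id: str = "synthetic",
    max_attempts: int = 200,
) -> tuple[GenePresenceTable, PresenceTruth]:
    """Construct a gene set whose trait calls reproduce ``target_vector``.

    For every Present trait a satisfying witness is added (cheapest
    alternation branch first); the union must leave every Absent trait
    unsatisfied.  On conflict, alternation branches are re-chosen (seeded
    random restarts, capped).  The output is verified by running
    :func:`~thiotraits.catalog.call_traits` before returning; decoy gene
    symbols outside the catalogue universe are added for realism.
    """
    short_names = catalog.short_names()
    missing = [s for s in short_names if s not in target_vector]
    if missing:
        raise InvalidTarget(f"target vector lacks traits: {missing}")
    bad = {v for v in target_vector.values()} - {PRESENT, ABSENT}
    if bad:
        raise InvalidTarget(f"target vector values must be Present/Absent, got {bad}")

    rng = np.random.default_rng(seed)
    present_defs = [
        d for d in catalog if target_vector[d.short_name] == PRESENT
    ]
    absent_defs = [d for d in catalog if target_vector[d.short_name] == ABSENT]
    exprs = {d.short_name: catalog.canonical_expr(d) for d in catalog}

    last_conflicts: list[str] = []
    for attempt in range(max_attempts):
        if attempt == 0:
            choose = _cheapest_first
        else:
            def choose(expr, branches, _rng=rng):  # noqa: B023 - fresh rng draw
                return int(_rng.integers(len(branches)))
        genes: set[str] = set()
        for d in present_defs:
            genes |= _witness(exprs[d.short_name], choose)
        conflicts = [
            d.short_name
            for d in absent_defs
            if dsl.evaluate(exprs[d.short_name], genes).present
        ]
        if not conflicts:
            decoys = {
                f"decoy_{int(x):04d}" for x in rng.integers(0, 10_000, decoy_genes)
            }
            table = GenePresenceTable({genome_id: genes | decoys})
            matrix = call_traits(catalog, table)
            realized = matrix.column(genome_id)
            mismatches = {
                s for s in short_names if realized[s] != target_vector[s]
            }
            if mismatches:  # pragma: no cover - construction is verified
                raise InfeasibleVector(
                    f"verification failed for traits {sorted(mismatches)}",
                    sorted(mismatches),
                )
            truth = PresenceTruth(
                seed=seed,
                target_vector=dict(target_vector),
                witness_genes=frozenset(genes),
                decoy_genes=frozenset(decoys),
                attempts=attempt + 1,
            )
            return table, truth
        last_conflicts = conflicts
    raise IterationCapExceeded(
        f"no witness found in {max_attempts} attempts; "
        f"Absent traits still satisfied: {last_conflicts}",
        last_conflicts,
    )


# --------------------------------------------------------------------------
# annotation tables

_NEUTRAL_PRODUCTS = (
    "citrate synthase",
    "ribosomal protein L3",
    "DNA polymerase III subunit alpha",
    "ATP synthase F1 subunit beta",
    "elongation factor Tu",
    "sulfite oxidoreductase",
    "hypothetical protein",
    "ABC transporter permease",
    "chaperonin GroEL",
    "RNA polymerase sigma factor",
)
_PHAGE_PRODUCTS = (
    "phage major capsid protein",
    "prophage repressor",
    "phage terminase large subunit",
    "phage portal protein",
    "phage tail protein",
)
_MGE_PRODUCTS = (
    "transposase, IS5 family",
    "insertion sequence element protein",
    "site-specific recombinase XerD",
    "mobile element protein",
    "plasmid stabilization protein",
)
_COG_LETTERS = tuple("CDEFGHIJKLMNOPQRSTUV")


@dataclass(frozen=True)
class AnnotationTruth:
    seed: int
    phage_gene_ids: tuple[str, ...]
    mge_gene_ids: tuple[str, ...]
    cog_tallies: dict[str, int] = field(default_factory=dict)


def gen_annotation_table(
    n_genes: int = 2000,
    cog_distribution: dict[str, float] | None = None,
    mobilome: tuple[int, int] = (0, 0),
    seed: int = 0,
) -> tuple[pd.DataFrame, AnnotationTruth]:
    """Simulate an annotation table with planted mobilome genes.

    Exactly ``mobilome[0]`` products come from the phage vocabulary and
    ``mobilome[1]`` from the other-MGE vocabulary; the remainder are
    neutral products matching neither keyword list.  COG letters are
    sampled from ``cog_distribution`` (default: uniform over 20 letters
    with a 15% unassigned fraction); a small fraction of genes get two
    letters, and the truth tallies count one per letter.
    """
    phage_n, mge_n = mobilome
    if phage_n < 0 or mge_n < 0 or phage_n + mge_n > n_genes:
        raise InvalidCounts("need phage_n + mge_n <= n_genes, both >= 0")
    rng = np.random.default_rng(seed)
    if cog_distribution is None:
        cog_distribution = {letter: 0.85 / len(_COG_LETTERS) for letter in _COG_LETTERS}
        cog_distribution[""] = 0.15
    letters = list(cog_distribution)
    probs = np.array([cog_distribution[letter] for letter in letters])
    probs = probs / probs.sum()

    gene_ids = [f"gene_{i:05d}" for i in range(1, n_genes + 1)]
    kinds = np.array(["neutral"] * n_genes, dtype=object)
    planted = rng.choice(n_genes, size=phage_n + mge_n, replace=False)
    kinds[planted[:phage_n]] = "phage"
    kinds[planted[phage_n:]] = "mge"

    products: list[str] = []
    categories: list[str] = []
    tallies: dict[str, int] = {}
    for kind in kinds:
        if kind == "phage":
            products.append(_PHAGE_PRODUCTS[int(rng.integers(len(_PHAGE_PRODUCTS)))])
        elif kind == "mge":
            products.append(_MGE_PRODUCTS[int(rng.integers(len(_MGE_PRODUCTS)))])
        else:
            products.append(
                _NEUTRAL_PRODUCTS[int(rng.integers(len(_NEUTRAL_PRODUCTS)))]
            )
        cat = letters[int(rng.choice(len(letters), p=probs))]
        if cat and rng.random() < 0.05:  # occasional dual-category gene
            extra = letters[int(rng.choice(len(letters), p=probs))]
            if extra and extra != cat:
                cat = cat + extra
        for letter in cat if cat else [""]:
            key = letter if letter else "unassigned"
            tallies[key] = tallies.get(key, 0) + 1
        categories.append(cat)

    df = pd.DataFrame(
        {"gene_id": gene_ids, "product": products, "categories": categories}
    )
    truth = AnnotationTruth(
        seed=seed,
        phage_gene_ids=tuple(gene_ids[i] for i in planted[:phage_n]),
        mge_gene_ids=tuple(gene_ids[i] for i in planted[phage_n:]),
        cog_tallies=tallies,
    )
    return df, truth
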
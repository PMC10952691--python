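"""Boolean gene-composition mini-language for functional traits.

A trait (e.g. the Calvin-Benson-Bassham cycle, or a type IV pilus) is called
Present in a genome when a boolean expression over annotated gene symbols is
satisfied by the genome's gene set.  The expression language mirrors the
notation used in comparative-genomics trait tables:

* ``+gene`` — the gene is required (an unsigned gene is also required);
* ``-gene`` — the gene is noted but *not* required; it is ignored during
  evaluation (never treated as a negative constraint);
* ``,``     — interchangeability: any one of the comma-separated
  alternatives satisfies the expression (logical OR);
* ``( )``   — grouping; juxtaposed terms form a conjunction (logical AND),
  which binds tighter than the comma.

Grammar (recursive descent)::

    expr := alt
    alt  := conj (',' conj)*
    conj := term+
    term := ('+' | '-')? atom
    atom := SYMBOL | '(' expr ')'

Macro symbols (e.g. ``ndhA_to_ndhN`` for the fourteen NADH-dehydrogenase
subunit genes) are expanded into explicit conjunctions via a
:class:`MacroTable` before evaluation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "Token",
    "TokenKind",
    "GeneRef",
    "Conjunction",
    "Alternation",
    "TraitExpr",
    "Sign",
    "EvaluationResult",
    "MacroTable",
    "DEFAULT_MACROS",
    "DslError",
    "IllegalCharacter",
    "UnbalancedParentheses",
    "DanglingSign",
    "EmptyBranch",
    "EmptyInput",
    "normalize_text",
    "tokenize",
    "parse",
    "parse_expression",
    "expand_macros",
    "apply_aliases",
    "evaluate",
    "genes_mentioned",
    "to_canonical_string",
]


# --------------------------------------------------------------------------
# errors

class DslError(ValueError):
    """Base class for expression-language errors; carries a char offset."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at offset {position})"
        super().__init__(message)


class IllegalCharacter(DslError):
    pass


class UnbalancedParentheses(DslError):
    pass


class DanglingSign(DslError):
    pass


class EmptyBranch(DslError):
    pass


class EmptyInput(DslError):
    pass


# --------------------------------------------------------------------------
# text normalization

# Unicode hyphen lookalikes that occur in typeset trait tables.
_HYPHEN_VARIANTS = "‐‑‒–−"
_HYPHEN_MAP = {ord(c): "-" for c in _HYPHEN_VARIANTS}


def normalize_text(raw: str) -> str:
    """Strip all whitespace and map Unicode hyphen variants to ASCII ``-``.

    Idempotent; the result is the canonical textual form fed to
    :func:`tokenize`.
    """
    out = raw.translate(_HYPHEN_MAP)
    return "".join(ch for ch in out if not ch.isspace())


# --------------------------------------------------------------------------
# tokens

class TokenKind(enum.Enum):
    PLUS = "+"
    MINUS = "-"
    LPAREN = "("
    RPAREN = ")"
    COMMA = ","
    SYMBOL = "SYMBOL"


_PUNCT = {
    "+": TokenKind.PLUS,
    "-": TokenKind.MINUS,
    "(": TokenKind.LPAREN,
    ")": TokenKind.RPAREN,
    ",": TokenKind.COMMA,
}


def _is_symbol_char(ch: str) -> bool:
    return ch.isascii() and (ch.isalnum() or ch == "_")


@dataclass(frozen=True)
class Token:
    kind: TokenKind
    text: str
    position: int  # 0-based character offset


def tokenize(text: str) -> list[Token]:
    """Tokenize a normalized expression string.

    Symbols are maximal runs of ``[A-Za-z0-9_]``; concatenating token texts
    reproduces the input.  Raises :class:`IllegalCharacter` on anything
    outside ``+-(),`` and symbol characters.
    """
    tokens: list[Token] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in _PUNCT:
            tokens.append(Token(_PUNCT[ch], ch, i))
            i += 1
        elif _is_symbol_char(ch):
            j = i
            while j < n and _is_symbol_char(text[j]):
                j += 1
            tokens.append(Token(TokenKind.SYMBOL, text[i:j], i))
            i = j
        else:
            raise IllegalCharacter(f"illegal character {ch!r}", i)
    return tokens


# --------------------------------------------------------------------------
# AST

class Sign(enum.Enum):
    REQUIRED = "required"
    OPTIONAL = "optional"


@dataclass(frozen=True)
class GeneRef:
    symbol: str

    def __post_init__(self):
        if not self.symbol:
            raise ValueError("GeneRef symbol must be non-empty")


@dataclass(frozen=True)
class Conjunction:
    #: ordered (sign, sub-expression) terms; present iff all REQUIRED
    #: terms are present, OPTIONAL terms are ignored.
    terms: tuple[tuple[Sign, "TraitExpr"], ...]

    def __post_init__(self):
        if not self.terms:
            raise ValueError("Conjunction needs >= 1 term")


@dataclass(frozen=True)
class Alternation:
    branches: tuple["TraitExpr", ...]

    def __post_init__(self):
        if len(self.branches) < 2:
            raise ValueError("Alternation needs >= 2 branches")


TraitExpr = GeneRef | Conjunction | Alternation


# --------------------------------------------------------------------------
# parser

class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> Token | None:
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def parse_expr(self) -> TraitExpr:
        branches = [self.parse_conj()]
        while (tok := self.peek()) is not None and tok.kind is TokenKind.COMMA:
            self.next()
            branches.append(self.parse_conj())
        if len(branches) == 1:
            return branches[0]
        return Alternation(tuple(branches))

    def parse_conj(self) -> TraitExpr:
        terms: list[tuple[Sign, TraitExpr]] = []
        while True:
            tok = self.peek()
            if tok is None or tok.kind in (TokenKind.COMMA, TokenKind.RPAREN):
                break
            terms.append(self.parse_term())
        if not terms:
            tok = self.peek()
            pos = tok.position if tok is not None else None
            raise EmptyBranch("empty alternation branch", pos)
        if len(terms) == 1 and terms[0][0] is Sign.REQUIRED:
            # a lone required atom is just the atom
            return terms[0][1]
        return Conjunction(tuple(terms))

    def parse_term(self) -> tuple[Sign, TraitExpr]:
        tok = self.peek()
        sign = Sign.REQUIRED
        if tok is not None and tok.kind in (TokenKind.PLUS, TokenKind.MINUS):
            self.next()
            if tok.kind is TokenKind.MINUS:
                sign = Sign.OPTIONAL
            nxt = self.peek()
            if nxt is None or nxt.kind in (
                TokenKind.COMMA,
                TokenKind.RPAREN,
                TokenKind.PLUS,
                TokenKind.MINUS,
            ):
                raise DanglingSign(
                    f"sign {tok.text!r} not followed by a gene or group",
                    tok.position,
                )
        return sign, self.parse_atom()

    def parse_atom(self) -> TraitExpr:
        tok = self.next()
        assert tok is not None  # guarded by callers
        if tok.kind is TokenKind.SYMBOL:
            return GeneRef(tok.text)
        if tok.kind is TokenKind.LPAREN:
            inner = self.parse_expr()
            closing = self.next()
            if closing is None or closing.kind is not TokenKind.RPAREN:
                raise UnbalancedParentheses(
                    "unclosed '('", tok.position
                )
            return inner
        raise DslError(f"unexpected token {tok.text!r}", tok.position)


def parse(tokens: list[Token]) -> TraitExpr:
    """Parse a token stream into a :data:`TraitExpr` AST."""
    if not tokens:
        raise EmptyInput("empty expression")
    # classify bracket problems up front, before any structural error
    depth = 0
    for tok in tokens:
        if tok.kind is TokenKind.LPAREN:
            depth += 1
        elif tok.kind is TokenKind.RPAREN:
            depth -= 1
            if depth < 0:
                raise UnbalancedParentheses("unmatched ')'", tok.position)
    if depth:
        raise UnbalancedParentheses("unclosed '('")
    parser = _Parser(tokens)
    try:
        expr = parser.parse_expr()
    except RecursionError:  # pragma: no cover - absurdly deep nesting
        raise UnbalancedParentheses("expression nested too deeply")
    trailing = parser.peek()
    if trailing is not None:
        if trailing.kind is TokenKind.RPAREN:
            raise UnbalancedParentheses("unmatched ')'", trailing.position)
        raise DslError(f"unexpected token {trailing.text!r}", trailing.position)
    return expr


def parse_expression(raw: str, macros: "MacroTable | None" = None) -> TraitExpr:
    """Convenience: normalize, tokenize, parse and (optionally) macro-expand."""
    expr = parse(tokenize(normalize_text(raw)))
    if macros is not None:
        expr = expand_macros(expr, macros)
    return expr


# --------------------------------------------------------------------------
# macros

@dataclass(frozen=True)
class MacroTable:
    """Mapping from a macro symbol to its ordered gene-symbol expansion."""

    mapping: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        for key, genes in self.mapping.items():
            if not genes:
                raise ValueError(f"macro {key!r} has empty expansion")
            if len(set(genes)) != len(genes):
                raise ValueError(f"macro {key!r} expansion has duplicates")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.mapping

    def expansion(self, symbol: str) -> tuple[str, ...]:
        return self.mapping[symbol]


#: The one macro used by the packaged catalogue: the fourteen subunit genes
#: of NADH dehydrogenase (complex I), ndhA through ndhN.
DEFAULT_MACROS = MacroTable(
    {"ndhA_to_ndhN": tuple("ndh" + ch for ch in "ABCDEFGHIJKLMN")}
)


def expand_macros(expr: TraitExpr, macros: MacroTable) -> TraitExpr:
    """Replace macro gene references with conjunctions of required genes.

    Non-macro symbols pass through untouched; idempotent because expansions
    contain no macro keys themselves.
    """
    if isinstance(expr, GeneRef):
        if expr.symbol in macros:
            genes = macros.expansion(expr.symbol)
            if len(genes) == 1:
                return GeneRef(genes[0])
            return Conjunction(
                tuple((Sign.REQUIRED, GeneRef(g)) for g in genes)
            )
        return expr
    if isinstance(expr, Conjunction):
        return Conjunction(
            tuple((sign, expand_macros(sub, macros)) for sign, sub in expr.terms)
        )
    return Alternation(
        tuple(expand_macros(b, macros) for b in expr.branches)
    )


def apply_aliases(expr: TraitExpr, aliases: Mapping[str, str]) -> TraitExpr:
    """Canonicalize every gene symbol in the tree through an alias table."""
    if not aliases:
        return expr
    if isinstance(expr, GeneRef):
        canonical = aliases.get(expr.symbol, expr.symbol)
        return expr if canonical == expr.symbol else GeneRef(canonical)
    if isinstance(expr, Conjunction):
        return Conjunction(
            tuple((sign, apply_aliases(sub, aliases)) for sign, sub in expr.terms)
        )
    return Alternation(tuple(apply_aliases(b, aliases) for b in expr.branches))


# --------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class EvaluationResult:
    """Outcome of evaluating a trait expression against a gene set.

    ``missing_required`` explains a negative call: the required genes absent
    along the minimal failing path (for an alternation, the branch with the
    fewest missing genes).  ``satisfied_branches`` maps the tree path of each
    alternation node (a tuple of child indices from the root) to the index of
    the first satisfied branch; it is empty when the call is negative.
    ``ignored_optional`` lists '-'-signed genes, which never influence the
    call.
    """

    present: bool
    missing_required: frozenset[str] = frozenset()
    satisfied_branches: Mapping[tuple[int, ...], int] = field(
        default_factory=dict
    )
    ignored_optional: frozenset[str] = frozenset()

    @property
    def satisfied_branch(self) -> int | None:
        """First satisfied branch at the root, when the root alternates."""
        return self.satisfied_branches.get(())


def _optional_symbols(expr: TraitExpr) -> set[str]:
    _, optional = genes_mentioned(expr)
    return set(optional)


def _eval(
    expr: TraitExpr,
    genes: frozenset[str],
    path: tuple[int, ...],
    branches: dict[tuple[int, ...], int],
) -> tuple[bool, set[str]]:
    if isinstance(expr, GeneRef):
        ok = expr.symbol in genes
        return ok, (set() if ok else {expr.symbol})
    if isinstance(expr, Conjunction):
        missing: set[str] = set()
        ok = True
        sub_branches: dict[tuple[int, ...], int] = {}
        for i, (sign, sub) in enumerate(expr.terms):
            if sign is Sign.OPTIONAL:
                continue
            sub_ok, sub_missing = _eval(sub, genes, path + (i,), sub_branches)
            if not sub_ok:
                ok = False
                missing |= sub_missing
        if ok:
            branches.update(sub_branches)
        return ok, missing
    # Alternation: first satisfied branch wins; a failing alternation is
    # explained by its least-missing branch (ties: first in printed order).
    best_missing: set[str] | None = None
    for i, branch in enumerate(expr.branches):
        sub_branches: dict[tuple[int, ...], int] = {}
        ok, missing = _eval(branch, genes, path + (i,), sub_branches)
        if ok:
            branches[path] = i
            branches.update(sub_branches)
            return True, set()
        if best_missing is None or len(missing) < len(best_missing):
            best_missing = missing
    assert best_missing is not None
    return False, best_missing


def evaluate(expr: TraitExpr, genes: set[str] | frozenset[str]) -> EvaluationResult:
    """Evaluate a (macro-expanded) trait expression against a gene set.

    The language is positive: '-'-signed genes are ignored entirely, so the
    call is monotone in the gene set.
    """
    gene_set = frozenset(genes)
    branches: dict[tuple[int, ...], int] = {}
    present, missing = _eval(expr, gene_set, (), branches)
    optional = frozenset(_optional_symbols(expr)) - frozenset(missing)
    return EvaluationResult(
        present=present,
        missing_required=frozenset(missing) if not present else frozenset(),
        satisfied_branches=branches if present else {},
        ignored_optional=optional,
    )


def genes_mentioned(expr: TraitExpr) -> tuple[frozenset[str], frozenset[str]]:
    """Partition mentioned symbols into (required-or-alternative, optional).

    A symbol reachable in any required/alternative position lands in the
    first set; symbols that only ever carry the '-' sign land in the second.
    """
    required: set[str] = set()
    optional: set[str] = set()

    def walk(node: TraitExpr, under_optional: bool) -> None:
        if isinstance(node, GeneRef):
            (optional if under_optional else required).add(node.symbol)
        elif isinstance(node, Conjunction):
            for sign, sub in node.terms:
                walk(sub, under_optional or sign is Sign.OPTIONAL)
        else:
            for branch in node.branches:
                walk(branch, under_optional)

    walk(expr, False)
    optional -= required
    return frozenset(required), frozenset(optional)


# --------------------------------------------------------------------------
# serialization

def _atom_str(expr: TraitExpr) -> str:
    if isinstance(expr, GeneRef):
        return expr.symbol
    return "(" + to_canonical_string(expr) + ")"


def to_canonical_string(expr: TraitExpr) -> str:
    """Serialize an AST so that parsing the result reproduces the AST."""
    if isinstance(expr, GeneRef):
        return expr.symbol
    if isinstance(expr, Conjunction):
        parts = []
        for sign, sub in expr.terms:
            parts.append(("+" if sign is Sign.REQUIRED else "-") + _atom_str(sub))
        return "".join(parts)
    # Alternation: conjunction branches need no parentheses (comma binds
    # lower); nested alternations do.
    out = []
    for branch in expr.branches:
        if isinstance(branch, Alternation):
            out.append("(" + to_canonical_string(branch) + ")")
        else:
            out.append(to_canonical_string(branch))
    return ",".join(out)


def iter_gene_refs(expr: TraitExpr) -> Iterator[GeneRef]:
    """Yield every gene reference in the tree (document order)."""
    if isinstance(expr, GeneRef):
        yield expr
    elif isinstance(expr, Conjunction):
        for _, sub in expr.terms:
            yield from iter_gene_refs(sub)
    else:
        for branch in expr.branches:
            yield from iter_gene_refs(branch)
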
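"""Unit and property tests for the trait-expression mini-language."""

import random

import pytest

from thiotraits import dsl
from thiotraits.dsl import (
    Alternation,
    Conjunction,
    DanglingSign,
    EmptyBranch,
    EmptyInput,
    GeneRef,
    IllegalCharacter,
    MacroTable,
    Sign,
    TokenKind,
    UnbalancedParentheses,
    DEFAULT_MACROS,
)

from _oracles import eval_expression_text


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("+sat + aprB+aprA‐aprM", "+sat+aprB+aprA-aprM"),
            ("", ""),
            ("+actP", "+actP"),
            ("a – b\t−c", "a-b-c"),
        ],
    )
    def test_examples(self, raw, expected):
        assert dsl.normalize_text(raw) == expected

    def test_idempotent(self):
        raw = "+sat + aprB+aprA‐aprM"
        once = dsl.normalize_text(raw)
        assert dsl.normalize_text(once) == once


class TestTokenize:
    def test_plus_symbol(self):
        toks = dsl.tokenize("+actP")
        assert [t.kind for t in toks] == [TokenKind.PLUS, TokenKind.SYMBOL]
        assert toks[1].text == "actP"

    def test_alternation_tokens(self):
        kinds = [t.kind for t in dsl.tokenize("apeE,fhaC,yadA")]
        assert kinds == [
            TokenKind.SYMBOL,
            TokenKind.COMMA,
            TokenKind.SYMBOL,
            TokenKind.COMMA,
            TokenKind.SYMBOL,
        ]

    def test_concatenation_reproduces_input(self):
        text = "+((+cbbS+cbbL),cbbL_formII)+pgk"
        assert "".join(t.text for t in dsl.tokenize(text)) == text
        positions = [t.position for t in dsl.tokenize(text)]
        assert positions == sorted(positions)

    def test_illegal_character_offset(self):
        with pytest.raises(IllegalCharacter) as err:
            dsl.tokenize("+act!P")
        assert err.value.position == 4


class TestParse:
    def test_conjunction(self):
        expr = dsl.parse_expression("+glgC+glgA")
        assert expr == Conjunction(
            ((Sign.REQUIRED, GeneRef("glgC")), (Sign.REQUIRED, GeneRef("glgA")))
        )

    def test_nested_grouping(self):
        expr = dsl.parse_expression("+((+cbbS+cbbL),cbbL_formII)+pgk")
        inner = Alternation(
            (
                Conjunction(
                    ((Sign.REQUIRED, GeneRef("cbbS")), (Sign.REQUIRED, GeneRef("cbbL")))
                ),
                GeneRef("cbbL_formII"),
            )
        )
        assert expr == Conjunction(
            ((Sign.REQUIRED, inner), (Sign.REQUIRED, GeneRef("pgk")))
        )

    def test_pure_or_collapses_to_gene_refs(self):
        expr = dsl.parse_expression("apeE,fhaC,yadA")
        assert expr == Alternation(
            (GeneRef("apeE"), GeneRef("fhaC"), GeneRef("yadA"))
        )

    @pytest.mark.parametrize(
        "text,error",
        [
            ("(()", UnbalancedParentheses),
            ("a))", UnbalancedParentheses),
            ("+a+", DanglingSign),
            ("-", DanglingSign),
            ("a,,b", EmptyBranch),
            (",a", EmptyBranch),
            ("a,", EmptyBranch),
            ("", EmptyInput),
        ],
    )
    def test_malformed(self, text, error):
        with pytest.raises(error):
            dsl.parse(dsl.tokenize(text))


class TestMacros:
    def test_default_expansion(self):
        expr = dsl.expand_macros(GeneRef("ndhA_to_ndhN"), DEFAULT_MACROS)
        assert isinstance(expr, Conjunction)
        symbols = [t[1].symbol for t in expr.terms]
        assert symbols == [f"ndh{c}" for c in "ABCDEFGHIJKLMN"]
        assert all(sign is Sign.REQUIRED for sign, _ in expr.terms)

    def test_identity_on_non_macros(self):
        assert dsl.expand_macros(GeneRef("actP"), DEFAULT_MACROS) == GeneRef("actP")

    def test_idempotent(self):
        once = dsl.expand_macros(GeneRef("ndhA_to_ndhN"), DEFAULT_MACROS)
        assert dsl.expand_macros(once, DEFAULT_MACROS) == once

    def test_rejects_duplicate_expansion(self):
        with pytest.raises(ValueError):
            MacroTable({"m": ("a", "a")})


class TestEvaluate:
    def test_missing_required_gene(self):
        expr = dsl.parse_expression("+hydA+hydB+hydC+hydD")
        res = dsl.evaluate(expr, {"hydA", "hydB", "hydC"})
        assert not res.present
        assert res.missing_required == {"hydD"}

    def test_or_satisfied_by_one_alternative(self):
        expr = dsl.parse_expression("apeE,fhaC,yadA")
        res = dsl.evaluate(expr, {"yadA"})
        assert res.present
        assert res.satisfied_branch == 2

    def test_tca_cycle_hand_compiled(self, catalog):
        # independently hand-compiled boolean formula for the TCA-cycle trait
        def tca(g):
            return (
                "CS" in g
                and ("acnA" in g or "acnB" in g)
                and "icd" in g
                and (
                    ("sucA" in g and "sucB" in g and "lpd" in g)
                    or ("korA" in g and "korB" in g)
                )
                and all(x in g for x in ("sucD", "sucC", "sdhA", "sdhB", "sdhC", "sdhD"))
                and ("fumA" in g or "fumC" in g)
                and ("mdh" in g or "mqo" in g)
            )

        genes = {"CS", "acnB", "icd", "korA", "korB", "sucD", "sucC",
                 "sdhA", "sdhB", "sdhC", "sdhD", "fumC", "mqo"}
        expr = catalog.by_short_name("TcaC").expr
        assert tca(genes)
        assert dsl.evaluate(expr, genes).present
        for missing in ("icd", "sucC", "korA"):
            reduced = genes - {missing}
            assert dsl.evaluate(expr, reduced).present == tca(reduced)

    def test_crispr_optional_genes_ignored(self, catalog):
        expr = catalog.by_short_name("Cas").expr
        res = dsl.evaluate(expr, {"cas1", "cas2", "cas9"})
        assert res.present
        assert "cas4" in res.ignored_optional
        assert not dsl.evaluate(expr, {"cas1", "cas2"}).present

    def test_result_invariants(self, catalog):
        rng = random.Random(7)
        for d in catalog:
            required, optional = dsl.genes_mentioned(d.expr)
            universe = sorted(required | optional)
            genes = {g for g in universe if rng.random() < 0.5}
            res = dsl.evaluate(d.expr, genes)
            assert res.present == (not res.missing_required)
            assert not (res.ignored_optional & res.missing_required)


class TestGenesMentioned:
    def test_single_required(self):
        req, opt = dsl.genes_mentioned(dsl.parse_expression("+actP"))
        assert (req, opt) == ({"actP"}, frozenset())

    def test_optional_partition(self):
        req, opt = dsl.genes_mentioned(dsl.parse_expression("+sat+aprB+aprA-aprM"))
        assert req == {"sat", "aprB", "aprA"}
        assert opt == {"aprM"}

    def test_alternatives_count_as_required(self):
        req, opt = dsl.genes_mentioned(dsl.parse_expression("apeE,fhaC,yadA"))
        assert req == {"apeE", "fhaC", "yadA"}
        assert not opt


class TestCanonicalString:
    def test_conjunction(self):
        assert dsl.to_canonical_string(dsl.parse_expression("+glgC+glgA")) == "+glgC+glgA"

    def test_alternation(self):
        assert (
            dsl.to_canonical_string(dsl.parse_expression("apeE,fhaC,yadA"))
            == "apeE,fhaC,yadA"
        )

    def test_round_trip_preserves_ast_and_evaluation(self, catalog):
        rng = random.Random(11)
        for d in catalog:
            reparsed = dsl.parse_expression(dsl.to_canonical_string(d.expr))
            assert reparsed == d.expr
            required, optional = dsl.genes_mentioned(d.expr)
            universe = sorted(required | optional)
            for _ in range(20):
                genes = {g for g in universe if rng.random() < 0.5}
                assert (
                    dsl.evaluate(reparsed, genes).present
                    == dsl.evaluate(d.expr, genes).present
                )


class TestAgainstTextOracle:
    """The AST evaluator agrees with a direct string interpreter."""

    def test_random_subsets_all_catalogue_rows(self, catalog):
        rng = random.Random(3)
        for d in catalog:
            text = d.expression_text.replace(
                "ndhA_to_ndhN",
                "(" + "".join("+ndh" + c for c in "ABCDEFGHIJKLMN") + ")",
            )
            required, optional = dsl.genes_mentioned(d.expr)
            universe = sorted(required | optional)
            for _ in range(50):
                genes = {g for g in universe if rng.random() < 0.5}
                assert dsl.evaluate(d.expr, genes).present == eval_expression_text(
                    text, genes
                ), (d.short_name, sorted(genes))
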
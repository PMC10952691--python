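"""Generator determinism, target-hitting and closed-loop truth tests."""

import random

import pytest

from thiotraits.catalog import ABSENT, PRESENT, call_traits, trait_counts
from thiotraits.seqstats import assembly_stats
from thiotraits.simulate import (
    InvalidCounts,
    InvalidTarget,
    gen_annotation_table,
    gen_assembly,
    gen_nt_pair,
    gen_presence_table,
    gen_proteome_pair,
)


class TestGenAssembly:
    def test_gc_target_hit(self):
        records, truth = gen_assembly(
            n_contigs=20, length_distribution=("fixed", 10_000), gc_target=0.50, seed=1
        )
        stats = assembly_stats(records)
        assert stats.total_bp == 200_000
        assert abs(stats.gc_fraction - 0.50) <= 0.005

    def test_tiny_assembly(self):
        records, _ = gen_assembly(1, ("fixed", 4), 0.5, seed=0)
        assert len(records) == 1
        assert len(records[0].seq) == 4

    def test_determinism(self):
        r1, _ = gen_assembly(5, ("lognormal", 5000, 0.8), 0.45, seed=9)
        r2, _ = gen_assembly(5, ("lognormal", 5000, 0.8), 0.45, seed=9)
        assert [str(r.seq) for r in r1] == [str(r.seq) for r in r2]
        r3, _ = gen_assembly(5, ("lognormal", 5000, 0.8), 0.45, seed=10)
        assert [str(r.seq) for r in r1] != [str(r.seq) for r in r3]

    def test_truth_matches_emitted_lengths(self):
        records, truth = gen_assembly(8, ("lognormal", 3000, 0.5), 0.6, seed=2)
        assert tuple(len(r.seq) for r in records) == truth.contig_lengths

    def test_invalid_target(self):
        with pytest.raises(InvalidTarget):
            gen_assembly(0, ("fixed", 10), 0.5, seed=0)
        with pytest.raises(InvalidTarget):
            gen_assembly(1, ("fixed", 10), 1.5, seed=0)


class TestGenProteomePair:
    def test_target_100_identical(self):
        a, b, truth = gen_proteome_pair(5, 100, 100.0, seed=0)
        assert list(a.values()) == list(b.values())
        assert truth.mean_realized_identity_pct == 100.0

    def test_realized_identity_near_target(self):
        _, _, truth = gen_proteome_pair(100, 300, 70.0, seed=3)
        assert abs(truth.mean_realized_identity_pct - 70.0) <= 1.0

    def test_truth_verifiable_by_recount(self):
        a, b, truth = gen_proteome_pair(10, 200, 80.0, seed=4)
        for aid, bid in truth.pairs.items():
            sa, sb = a[aid], b[bid]
            assert len(sa) == len(sb)
            recount = 100.0 * sum(x == y for x, y in zip(sa, sb)) / len(sa)
            assert recount == pytest.approx(truth.realized_identity_pct[aid])

    def test_determinism(self):
        a1, b1, _ = gen_proteome_pair(5, 100, 70.0, seed=6)
        a2, b2, _ = gen_proteome_pair(5, 100, 70.0, seed=6)
        assert a1 == a2 and b1 == b2


class TestGenNtPair:
    def test_target_100(self):
        a, b, realized = gen_nt_pair(100, 100.0, seed=0)
        assert a == b and realized == 100.0

    def test_realized_recount(self):
        a, b, realized = gen_nt_pair(1400, 95.0, seed=11)
        recount = 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
        assert recount == pytest.approx(realized)
        assert abs(realized - 95.0) <= 1.0

    def test_determinism(self):
        assert gen_nt_pair(50, 90.0, seed=3) == gen_nt_pair(50, 90.0, seed=3)


class TestGenPresenceTable:
    def test_published_thiobius_column(self, catalog, published_calls):
        table, truth = gen_presence_table(
            catalog, published_calls["Thiobius"], seed=43, genome_id="Thiobius"
        )
        counts, _ = trait_counts(call_traits(catalog, table))
        assert counts["Thiobius"] == 31

    def test_published_odiii6_column(self, catalog, published_calls):
        table, truth = gen_presence_table(
            catalog, published_calls["ODIII6"], seed=6, genome_id="ODIII6"
        )
        counts, _ = trait_counts(call_traits(catalog, table))
        assert counts["ODIII6"] == 39

    def test_all_absent_vector(self, catalog):
        vector = {d.short_name: ABSENT for d in catalog}
        table, truth = gen_presence_table(catalog, vector, seed=1, genome_id="g")
        counts, _ = trait_counts(call_traits(catalog, table))
        assert counts["g"] == 0
        assert not truth.witness_genes
        # only decoys remain, and they sit outside the catalogue universe
        assert table["g"] <= truth.decoy_genes
        assert not truth.decoy_genes & catalog.gene_universe()

    def test_random_vector_round_trip(self, catalog):
        rng = random.Random(17)
        for _ in range(10):
            vector = {
                d.short_name: PRESENT if rng.random() < 0.5 else ABSENT
                for d in catalog
            }
            table, _ = gen_presence_table(catalog, vector, seed=rng.randrange(2**31))
            matrix = call_traits(catalog, table)
            assert matrix.column("synthetic") == vector

    def test_incomplete_vector_rejected(self, catalog):
        with pytest.raises(InvalidTarget):
            gen_presence_table(catalog, {"ActP": PRESENT}, seed=0)


class TestGenAnnotationTable:
    def test_planted_mobilome_counts(self):
        from thiotraits.compare import count_mobilome

        df, truth = gen_annotation_table(3452, mobilome=(2, 58), seed=6)
        assert count_mobilome(df).as_pair() == (2, 58)
        assert len(truth.phage_gene_ids) == 2
        assert len(truth.mge_gene_ids) == 58

    def test_zero_mobilome(self):
        from thiotraits.compare import count_mobilome

        df, _ = gen_annotation_table(10, mobilome=(0, 0), seed=0)
        assert count_mobilome(df).as_pair() == (0, 0)

    def test_invalid_counts(self):
        with pytest.raises(InvalidCounts):
            gen_annotation_table(5, mobilome=(4, 3), seed=0)

    def test_determinism(self):
        d1, t1 = gen_annotation_table(100, mobilome=(3, 7), seed=2)
        d2, t2 = gen_annotation_table(100, mobilome=(3, 7), seed=2)
        assert d1.equals(d2)
        assert t1 == t2
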
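"""GO annotation store and identifier mapping."""

import pytest

from gliomanet.annotations import (
    AnnotationTable,
    GoTerm,
    IdMap,
    manual_patch,
    map_ids,
    merge_idmaps,
)
from gliomanet.core import GeneSet


class TestGoTerm:
    @pytest.mark.parametrize(
        "accession,name,namespace",
        [
            ("GO:123", "x", "biological_process"),
            ("GO:0000001", "", "biological_process"),
            ("GO:0000001", "x", "nonsense"),
        ],
    )
    def test_invalid_terms_rejected(self, accession, name, namespace):
        with pytest.raises(ValueError):
            GoTerm(accession, name, namespace)


class TestAnnotationTable:
    def test_pairs_deduplicated(self):
        table = AnnotationTable()
        table.add_term(GoTerm("GO:0000001", "thing"))
        table.annotate("G1", "GO:0000001")
        table.annotate("G1", "GO:0000001")
        assert len(table.entries) == 1

    def test_unknown_accession_rejected(self):
        with pytest.raises(KeyError):
            AnnotationTable().annotate("G1", "GO:0000001")

    def test_tsv_pair_roundtrip(self, tmp_path):
        table = AnnotationTable()
        table.add_term(GoTerm("GO:0000001", "alpha", "molecular_function"))
        table.add_term(GoTerm("GO:0000002", "beta"))
        table.annotate("G1", "GO:0000001")
        table.annotate("G2", "GO:0000002")
        g2t, meta = tmp_path / "g2t.tsv", tmp_path / "terms.tsv"
        table.to_tsv_pair(g2t, meta)
        back = AnnotationTable.from_tsv_pair(g2t, meta)
        assert back.entries == table.entries
        assert back.terms["GO:0000001"].namespace == "molecular_function"

    def test_gmt_dialect(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("GO:0000001\tcell proliferation\tG1\tG2\n", encoding="utf-8")
        table = AnnotationTable.from_gmt(p)
        assert table.genes_for_term("GO:0000001") == {"G1", "G2"}
        assert table.genes_with_keyword("prolif") == {"G1", "G2"}


def simple_map(n_resolving, n_total, provenance="test"):
    """Symbols SYM0..SYM{n_total-1}; first n_resolving rows carry an Ensembl id."""
    idmap = IdMap()
    for i in range(n_total):
        idmap.add_row(
            ensembl_gene=f"ENSG{i:04d}" if i < n_resolving else "",
            symbol=f"SYM{i}",
            provenance=provenance,
        )
    return idmap


class TestMapIds:
    def test_partial_resolution_counts(self):
        # 10 symbols, 8 resolvable: mapped 8, unmapped 2, nothing lost
        genes = GeneSet(frozenset(f"SYM{i}" for i in range(10)), "symbol")
        mapped, unmapped = map_ids(genes, simple_map(8, 10), "ensembl_gene")
        assert len(mapped) == 8
        assert sorted(unmapped) == ["SYM8", "SYM9"]

    def test_conservation(self):
        genes = GeneSet(frozenset(f"SYM{i}" for i in range(10)), "symbol")
        idmap = simple_map(7, 10)
        result = idmap.translate(genes, "ensembl_gene")
        assert len(result.mapping) + len(result.unmapped) == len(genes)

    def test_duplicate_rows_collapse(self):
        idmap = IdMap()
        idmap.add_row(ensembl_gene="ENSG1", symbol="A")
        idmap.add_row(ensembl_gene="ENSG1", symbol="A")
        mapped, unmapped = map_ids(GeneSet(frozenset(["A"]), "symbol"), idmap, "ensembl_gene")
        assert mapped.ids == {"ENSG1"} and not unmapped

    def test_symbol_case_normalized(self):
        idmap = IdMap()
        idmap.add_row(ensembl_gene="ENSG1", symbol="BrCa2")
        mapped, _ = map_ids(GeneSet(frozenset([" brca2 "]), "symbol"), idmap, "ensembl_gene")
        assert mapped.ids == {"ENSG1"}

    def test_same_space_rejected(self):
        with pytest.raises(ValueError):
            map_ids(GeneSet(frozenset(["A"]), "symbol"), IdMap(), "symbol")

    def test_empty_map_all_unmapped(self):
        genes = GeneSet(frozenset(["A", "B"]), "symbol")
        mapped, unmapped = map_ids(genes, IdMap(), "ensembl_gene")
        assert not mapped.ids and len(unmapped) == 2

    def test_ambiguity_lexicographic_and_logged(self):
        idmap = IdMap()
        idmap.add_row(ensembl_gene="ENSG2", symbol="A")
        idmap.add_row(ensembl_gene="ENSG1", symbol="A")
        result = idmap.translate(GeneSet(frozenset(["A"]), "symbol"), "ensembl_gene")
        assert result.mapping == {"A": "ENSG1"}
        assert result.ambiguous == {"A": ["ENSG1", "ENSG2"]}

    def test_roundtrip_when_unambiguous(self):
        idmap = simple_map(5, 5)
        genes = GeneSet(frozenset(f"SYM{i}" for i in range(5)), "symbol")
        forward = idmap.translate(genes, "ensembl_gene")
        back = idmap.translate(forward.mapped, "symbol")
        assert {back.mapping[v] for v in forward.mapping.values()} == genes.ids


class TestMergeIdmaps:
    def test_disjoint_coverage_adds_up(self):
        # one source resolves 40%, a disjoint one 45%: merged resolves 85%
        a = IdMap()
        b = IdMap()
        for i in range(100):
            if i < 40:
                a.add_row(ensembl_gene=f"ENSG{i:04d}", symbol=f"SYM{i}", provenance="a")
            elif i < 85:
                b.add_row(ensembl_gene=f"ENSG{i:04d}", symbol=f"SYM{i}", provenance="b")
        genes = GeneSet(frozenset(f"SYM{i}" for i in range(100)), "symbol")
        mapped, unmapped = map_ids(genes, merge_idmaps([a, b]), "ensembl_gene")
        assert len(mapped) == 85 and len(unmapped) == 15

    def test_merge_rate_at_least_max_of_inputs(self):
        a = simple_map(6, 10, "a")
        b = simple_map(3, 10, "b")
        genes = GeneSet(frozenset(f"SYM{i}" for i in range(10)), "symbol")
        merged_rate = len(map_ids(genes, merge_idmaps([a, b]), "ensembl_gene")[0])
        assert merged_rate >= max(
            len(map_ids(genes, a, "ensembl_gene")[0]),
            len(map_ids(genes, b, "ensembl_gene")[0]),
        )

    def test_self_merge_is_identity(self):
        a = simple_map(5, 5)
        genes = GeneSet(frozenset(f"SYM{i}" for i in range(5)), "symbol")
        assert (
            map_ids(genes, merge_idmaps([a, a]), "ensembl_gene")[0].ids
            == map_ids(genes, a, "ensembl_gene")[0].ids
        )

    def test_conflict_first_source_wins_and_recorded(self):
        a = IdMap()
        a.add_row(ensembl_gene="ENSG_A", symbol="X", provenance="first")
        b = IdMap()
        b.add_row(ensembl_gene="ENSG_B", symbol="X", provenance="second")
        merged = merge_idmaps([a, b])
        mapped, _ = map_ids(GeneSet(frozenset(["X"]), "symbol"), merged, "ensembl_gene")
        assert mapped.ids == {"ENSG_A"}
        assert any(c["id"] == "X" for c in merged.conflicts)


class TestManualPatch:
    def test_patch_fills_holes(self):
        idmap = simple_map(70, 100)
        patches = [
            {"ensembl_gene": f"ENSG{i:04d}", "symbol": f"SYM{i}"} for i in range(70, 100)
        ]
        genes = GeneSet(frozenset(f"SYM{i}" for i in range(100)), "symbol")
        before = len(map_ids(genes, idmap, "ensembl_gene")[1])
        after = len(map_ids(genes, manual_patch(idmap, patches), "ensembl_gene")[1])
        assert before - after == 30

    def test_empty_patch_is_identity(self):
        idmap = simple_map(5, 5)
        genes = GeneSet(frozenset(f"SYM{i}" for i in range(5)), "symbol")
        assert (
            map_ids(genes, manual_patch(idmap, []), "ensembl_gene")[0].ids
            == map_ids(genes, idmap, "ensembl_gene")[0].ids
        )

    def test_patch_overrides_existing(self):
        idmap = IdMap()
        idmap.add_row(ensembl_gene="ENSG_OLD", symbol="X")
        patched = manual_patch(idmap, [{"ensembl_gene": "ENSG_NEW", "symbol": "X"}])
        mapped, _ = map_ids(GeneSet(frozenset(["X"]), "symbol"), patched, "ensembl_gene")
        assert mapped.ids == {"ENSG_NEW"}

    def test_malformed_patch_reports_row(self):
        with pytest.raises(ValueError, match="row 1"):
            manual_patch(IdMap(), [{"ensembl_gene": "E1"}, {"bogus_field": "x"}])
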
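"""Supermatrix concatenation, RY-coding, translation and partitioning."""

import pytest
from Bio.Data import IUPACData
from Bio.Seq import Seq

from pelagia import demo, supermatrix
from pelagia.supermatrix import GeneAlignment


@pytest.fixture
def toy_genes():
    # two in-frame protein genes, one rRNA, one tRNA, plus ND6 to exclude
    return [
        GeneAlignment("ND1", "protein", {"t1": "ATGAAA", "t2": "ATGCCC"}),
        GeneAlignment("ND6", "protein", {"t1": "ATGGGG", "t2": "ATGGGG"}),
        GeneAlignment("COI", "protein", {"t1": "TTCTGA", "t2": "TTCTGG"}),
        GeneAlignment("rrnS", "rRNA", {"t1": "ACGT", "t2": "ACGA"}),
        GeneAlignment("trnV", "tRNA", {"t1": "GG", "t2": "GT"}),
    ]


class TestGeneAlignment:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            GeneAlignment("g", "protein", {"a": "ATG", "b": "ATGATG"})

    def test_out_of_frame_protein_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            GeneAlignment("g", "protein", {"a": "ATGA"})

    def test_frame_offset_allows_leading_bases(self):
        g = GeneAlignment("g", "protein", {"a": "AATG"}, frame=1)
        assert g.width == 4


class TestDedupLongest:
    def test_longest_retained(self):
        out = supermatrix.dedup_longest(
            [("sp1", "coi", "A" * 300), ("sp1", "coi", "A" * 450)]
        )
        assert out == [("sp1", "coi", "A" * 450)]

    def test_tie_keeps_first_and_warns(self, caplog):
        first = ("sp1", "coi", "A" * 400)
        with caplog.at_level("WARNING"):
            out = supermatrix.dedup_longest([first, ("sp1", "coi", "C" * 400)])
        assert out == [first]
        assert any("tie" in rec.message for rec in caplog.records)

    def test_gaps_do_not_count_toward_length(self):
        short_ungapped = ("sp1", "coi", "AAAA" + "-" * 100)
        longer = ("sp1", "coi", "AAAAAAAA")
        assert supermatrix.dedup_longest([short_ungapped, longer]) == [longer]

    def test_distinct_species_never_collapse(self):
        rows = [("sp1", "coi", "AAA"), ("sp2", "coi", "CCC")]
        assert supermatrix.dedup_longest(rows) == rows


class TestConcatenate:
    def test_widths_and_gene_order(self, toy_genes):
        scaffold = supermatrix.concatenate(toy_genes)
        # ND6 dropped: 6 + 6 protein + 4 rRNA + 2 tRNA
        assert scaffold.width == 18
        assert scaffold.col_gene[:6] == ["ND1"] * 6
        assert scaffold.col_cls[-2:] == ["tRNA"] * 2
        assert "ND6" not in scaffold.col_gene
        assert any("excluded gene ND6" in entry for entry in scaffold.log)

    def test_codon_phase_map_cycles(self, toy_genes):
        scaffold = supermatrix.concatenate(toy_genes)
        assert scaffold.col_phase[:6] == [1, 2, 3, 1, 2, 3]
        assert scaffold.col_phase[-6:] == [0] * 6

    def test_missing_taxon_gap_filled(self, toy_genes):
        toy_genes[3].sequences.pop("t2")
        scaffold = supermatrix.concatenate(toy_genes)
        assert scaffold.matrix["t2"][12:16] == "----"

    def test_empty_after_exclusion_rejected(self):
        with pytest.raises(ValueError):
            supermatrix.concatenate(
                [GeneAlignment("ND6", "protein", {"a": "ATG"})]
            )


class TestRyCoding:
    def test_codon_examples(self, toy_genes):
        scaffold = supermatrix.concatenate(toy_genes)
        coded = supermatrix.ry_code_third_positions(scaffold)
        # ATG AAA -> ATA AAA ; TTC TGA -> TTC TGA (C pyrimidine, A purine->A)
        assert coded.matrix["t1"][:6] == "ATAAAA"
        assert coded.matrix["t1"][6:12] == "TTCTGA"

    def test_exhaustive_iupac_partition(self):
        """Derived from the purine/pyrimidine partition of every IUPAC
        symbol: pure-purine sets -> A, pure-pyrimidine -> C, mixed -> N."""
        for sym, bases in IUPACData.ambiguous_dna_values.items():
            expected = (
                "A" if set(bases) <= {"A", "G"}
                else "C" if set(bases) <= {"C", "T"}
                else "N"
            )
            assert supermatrix.ry_code_symbol(sym) == expected, sym

    def test_gap_symbols_preserved(self):
        assert supermatrix.ry_code_symbol("-") == "-"
        assert supermatrix.ry_code_symbol("?") == "?"

    def test_idempotent(self, toy_genes):
        scaffold = supermatrix.concatenate(toy_genes)
        once = supermatrix.ry_code_third_positions(scaffold)
        twice = supermatrix.ry_code_third_positions(once)
        assert once.matrix == twice.matrix

    def test_third_positions_alphabet_after_coding(self):
        genes = demo.demo_genes()
        coded = supermatrix.ry_code_third_positions(supermatrix.concatenate(genes))
        thirds = {
            seq[i]
            for seq in coded.matrix.values()
            for i, ph in enumerate(coded.col_phase)
            if ph == 3
        }
        assert thirds <= {"A", "C", "N", "-"}


class TestTranslation:
    def test_vertebrate_mito_departures_from_standard_code(self, toy_genes):
        scaffold = supermatrix.concatenate(toy_genes)
        aa = supermatrix.translate_vertmito(scaffold)
        # ATG AAA -> MK ; TTC TGA -> FW (TGA is Trp, not stop, in vert-mito)
        assert aa.matrix["t1"][:2] == "MK"
        assert aa.matrix["t1"][2:4] == "FW"
        # cross-check against Biopython's table-2 translation
        assert str(Seq("ATAAAATGA").translate(table=2)) == "MKW"
        assert supermatrix.translate_codon("ATA") == "M"

    def test_gap_codons(self):
        assert supermatrix.translate_codon("---") == "-"
        assert supermatrix.translate_codon("A-G") == "X"
        assert supermatrix.translate_codon("ANN") == "X"

    def test_internal_stop_warns_with_position(self, caplog):
        genes = [
            GeneAlignment("g", "protein", {"a": "AGAATG"}),  # AGA = vert-mito stop
            GeneAlignment("r", "rRNA", {"a": "AC"}),
        ]
        with caplog.at_level("WARNING"):
            aa = supermatrix.translate_vertmito(supermatrix.concatenate(genes, exclude=set()))
        assert aa.matrix["a"][0] == "*"
        assert any("internal stop" in rec.message for rec in caplog.records)


class TestVariants:
    @pytest.mark.parametrize(
        "variant,n_parts",
        [("12n3rRTn", 5), ("123nRTn", 5), ("12nRTn", 4), ("123aRTn", 3)],
    )
    def test_partition_counts(self, toy_genes, variant, n_parts):
        built = supermatrix.build_variant(toy_genes, variant)
        assert len(built.partitions) == n_parts

    def test_partitions_tile_matrix(self, toy_genes):
        for variant in supermatrix.VARIANTS:
            built = supermatrix.build_variant(toy_genes, variant)
            spans = sorted((s, e) for _, s, e in built.partitions)
            assert spans[0][0] == 1
            assert spans[-1][1] == built.width
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 == e1 + 1
            assert all(len(seq) == built.width for seq in built.matrix.values())

    def test_width_conservation(self, toy_genes):
        w123 = supermatrix.build_variant(toy_genes, "123nRTn").width
        w12 = supermatrix.build_variant(toy_genes, "12nRTn").width
        protein_cols = 12  # two kept genes x 6
        assert w123 == w12 + protein_cols // 3

    def test_already_ry_coded_thirds_make_ry_a_noop(self):
        # third positions confined to {A, C} are fixed points of RY-coding
        genes = [
            GeneAlignment("g1", "protein", {"a": "ATAACC", "b": "TTAGCC"}),
            GeneAlignment("r", "rRNA", {"a": "ACGT", "b": "ACGT"}),
        ]
        ry = supermatrix.build_variant(genes, "12n3rRTn")
        plain = supermatrix.build_variant(genes, "123nRTn")
        assert ry.matrix == plain.matrix

    def test_unknown_variant_rejected(self, toy_genes):
        with pytest.raises(ValueError, match="variant"):
            supermatrix.build_variant(toy_genes, "124nRTn")


class TestIo:
    def test_partition_file_roundtrip(self, toy_genes, tmp_path):
        built = supermatrix.build_variant(toy_genes, "12n3rRTn")
        path = tmp_path / "parts.txt"
        supermatrix.write_partitions(built, path)
        assert supermatrix.read_partitions(path) == built.partitions

    def test_gene_fasta_roundtrip(self, tmp_path):
        genes = demo.demo_genes(n_taxa=3)
        paths = supermatrix.write_gene_alignments(genes, tmp_path / "genes")
        back = supermatrix.read_gene_alignments(
            paths, tmp_path / "genes" / "annotations.tsv"
        )
        assert {g.gene: g.sequences for g in back} == {
            g.gene: g.sequences for g in genes
        }
        assert {g.gene: (g.cls, g.frame) for g in back} == {
            g.gene: (g.cls, g.frame) for g in genes
        }

    def test_phylip_header(self, toy_genes, tmp_path):
        built = supermatrix.build_variant(toy_genes, "123nRTn")
        path = tmp_path / "m.phy"
        supermatrix.write_phylip(built, path)
        ntax, nchar = path.read_text().splitlines()[0].split()
        assert (int(ntax), int(nchar)) == (2, built.width)
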
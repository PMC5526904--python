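"""Sequence/alignment/tree data model, back-translation and domain mapping."""

import pytest
from hypothesis import given, settings, strategies as st

from wgdtrace.core_io import (
    Alignment,
    BacktranslationError,
    CodonAlignment,
    DomainPartition,
    SequenceRecord,
    backtranslate_alignment,
    map_residue_ranges,
    read_alignment,
    read_fasta,
    read_newick,
    write_fasta,
    write_newick,
)


def aln(*rows, moltype="protein"):
    return Alignment(
        [SequenceRecord(f"s{i}", s, moltype) for i, s in enumerate(rows)]
    )


class TestContainers:
    def test_rows_must_be_equal_length(self):
        with pytest.raises(ValueError, match="length"):
            aln("MK-", "MKL F".replace(" ", ""))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Alignment([SequenceRecord("x", "MK"), SequenceRecord("x", "ML")])

    def test_codon_alignment_validates_frame_and_stops(self):
        CodonAlignment([SequenceRecord("a", "ATGAAA", "dna")])
        with pytest.raises(ValueError, match="divisible"):
            CodonAlignment([SequenceRecord("a", "ATGA", "dna")])
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment([SequenceRecord("a", "ATGTAAAAA", "dna")])
        with pytest.raises(ValueError, match="partial-codon"):
            CodonAlignment([SequenceRecord("a", "ATGA--", "dna")])

    def test_ambiguous_codons_allowed(self):
        ca = CodonAlignment([SequenceRecord("a", "ATGANN", "dna")])
        assert ca.translate()["a"].seq == "MX"


class TestBacktranslate:
    def test_gap_becomes_gap_codon(self):
        prot = aln("M-KF")
        cds = {"s0": SequenceRecord("s0", "ATGAAATTT", "dna")}
        out = backtranslate_alignment(prot, cds)
        assert out["s0"].seq == "ATG---AAATTT"

    def test_translation_mismatch_reports_residue(self):
        prot = aln("MK")
        cds = {"s0": SequenceRecord("s0", "ATGTTT", "dna")}
        with pytest.raises(BacktranslationError,
                           match=r"residue 2 \(expected K, codon TTT=F\)"):
            backtranslate_alignment(prot, cds)

    def test_terminal_stop_stripped(self):
        prot = aln("MK")
        cds = {"s0": SequenceRecord("s0", "ATGAAATAA", "dna")}
        assert backtranslate_alignment(prot, cds)["s0"].seq == "ATGAAA"

    def test_missing_cds_and_length_mismatch(self):
        prot = aln("MK")
        with pytest.raises(BacktranslationError, match="missing CDS"):
            backtranslate_alignment(prot, {})
        with pytest.raises(BacktranslationError, match="length"):
            backtranslate_alignment(
                prot, {"s0": SequenceRecord("s0", "ATGAAAG", "dna")}
            )

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.sampled_from(list("ACDEFGHIKLMNPQRSTVWY-")),
                    min_size=1, max_size=30).filter(
                        lambda s: any(c != "-" for c in s)))
    def test_roundtrip_translate_backtranslate(self, residues):
        """translate(backtranslate(A)) == A, gaps included."""
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        by_aa = {}
        for codon, a in table.forward_table.items():
            by_aa.setdefault(a, codon)
        prot_row = "".join(residues)
        cds = "".join(by_aa[c] for c in prot_row if c != "-")
        out = backtranslate_alignment(
            aln(prot_row), {"s0": SequenceRecord("s0", cds, "dna")}
        )
        assert out.translate()["s0"].seq == prot_row


class TestDomainMapping:
    def test_range_to_codon_columns_is_3x(self):
        prot = "M" * 60
        cds = "ATG" * 60
        ca = backtranslate_alignment(
            aln(prot), {"s0": SequenceRecord("s0", cds, "dna")}
        )
        sub = map_residue_ranges(ca, DomainPartition("Nterm", 1, 49), "s0")
        assert len(sub) == 147

    def test_gap_in_reference_shifts_columns(self):
        # reference has a gap at alignment column 3; residues 3-4 of the
        # reference sit at protein alignment columns 4-5 = codon cols 10..15
        rows = [
            SequenceRecord("ref", "MK-LF"),
            SequenceRecord("oth", "MKALF"),
        ]
        prot = Alignment(rows)
        cds = {
            "ref": SequenceRecord("ref", "ATGAAACTTTTT", "dna"),
            "oth": SequenceRecord("oth", "ATGAAAGCACTTTTT", "dna"),
        }
        ca = backtranslate_alignment(prot, cds)
        sub = map_residue_ranges(ca, DomainPartition("d", 3, 4), "ref")
        assert sub["ref"].seq == "CTTTTT"
        assert sub["oth"].seq == "CTTTTT"
        assert len(sub) == 6

    def test_partition_scheme_covers_reference_exactly_once(self):
        parts = [DomainPartition("Cyto1", 1, 49),
                 DomainPartition("Mito", 50, 96),
                 DomainPartition("Cyto2", 97, 155)]
        assert sum(len(p) for p in parts) == 155
        prot = "M" * 155
        ca = backtranslate_alignment(
            aln(prot), {"s0": SequenceRecord("s0", "ATG" * 155, "dna")}
        )
        pieces = [map_residue_ranges(ca, p, "s0") for p in parts]
        assert "".join(p["s0"].seq for p in pieces) == ca["s0"].seq

    def test_range_beyond_reference_errors(self):
        ca = backtranslate_alignment(
            aln("MK"), {"s0": SequenceRecord("s0", "ATGAAA", "dna")}
        )
        with pytest.raises(ValueError, match="exceeds"):
            map_residue_ranges(ca, DomainPartition("d", 1, 3), "s0")
        with pytest.raises(KeyError):
            map_residue_ranges(ca, DomainPartition("d", 1, 2), "nope")


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        recs = [SequenceRecord("a", "MKLV"), SequenceRecord("b", "MELF")]
        path = tmp_path / "x.fasta"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]
        assert read_alignment(path).ids == ["a", "b"]

    def test_newick_roundtrip_with_branch_marks(self, tmp_path):
        text = "((a:0.1,b:0.2) #1 :0.05,(c:0.3,d:0.1):0.07,e:0.4);"
        tree = read_newick(text)
        assert set(tree.leaf_names) == {"a", "b", "c", "d", "e"}
        classes = {
            n.name: n.branch_class for n in tree.postorder() if n.is_leaf
        }
        assert classes == {"a": 0, "b": 0, "c": 0, "d": 0, "e": 0}
        marked = [n for n in tree.postorder()
                  if n.parent is not None and n.branch_class == 1]
        assert len(marked) == 1 and not marked[0].is_leaf
        # round trip preserves topology, lengths and the mark
        again = read_newick(write_newick(tree))
        assert again.leaf_names == tree.leaf_names
        assert again.branch_classes() == tree.branch_classes()
        lengths = {n.name: n.length for n in tree.leaves()}
        assert {n.name: n.length for n in again.leaves()} == lengths

    def test_clade_mark_propagates(self):
        tree = read_newick("((a:0.1,b:0.2) $1 :0.05,(c:0.3,d:0.1):0.07);")
        cls = {n.name: n.branch_class for n in tree.leaves()}
        assert cls == {"a": 1, "b": 1, "c": 0, "d": 0}

    def test_sidecar_class_map(self, tmp_path):
        sidecar = tmp_path / "classes.tsv"
        sidecar.write_text("a\t1\nb\t1\n")
        tree = read_newick("((a:0.1,b:0.2):0.05,c:0.3);",
                           branch_class_tsv=sidecar)
        cls = {n.name: n.branch_class for n in tree.leaves()}
        assert cls == {"a": 1, "b": 1, "c": 0}

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            read_newick("(a:-0.1,b:0.2);")

    def test_extract_subtree_sums_unary_lengths(self):
        tree = read_newick("((a:0.1,b:0.2):0.3,(c:0.4,d:0.5):0.6);")
        sub = tree.extract_subtree(["a", "c", "d"])
        assert sorted(sub.leaf_names) == ["a", "c", "d"]
        lengths = {n.name: round(n.length, 6) for n in sub.leaves()}
        assert lengths["a"] == pytest.approx(0.4)  # 0.1 + suppressed 0.3

    def test_phylip_writer_is_parseable(self, tmp_path):
        from Bio import AlignIO

        from wgdtrace.core_io import write_phylip

        a = Alignment([SequenceRecord("alpha", "MKLV"),
                       SequenceRecord("beta", "MELF")])
        path = tmp_path / "x.phy"
        write_phylip(a, path)
        back = AlignIO.read(str(path), "phylip-relaxed")
        assert [(r.id, str(r.seq)) for r in back] == [
            ("alpha", "MKLV"), ("beta", "MELF")
        ]

    def test_gene_loci_from_bed_and_gff3(self, tmp_path):
        from wgdtrace.core_io import read_gene_loci
        from wgdtrace.synteny import loci_from_table

        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t500\t900\tgeneB\t0\t-\n"
                       "chr1\t100\t400\tgeneA\t0\t+\n")
        rows = read_gene_loci(bed)
        assert [r[0] for r in rows] == ["geneA", "geneB"]  # sorted by start
        loci = loci_from_table(rows)
        assert [(l.gene_id, l.order_index, l.strand) for l in loci] == [
            ("geneA", 0, "+"), ("geneB", 1, "-")
        ]

        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\n"
                       "chr2\tsrc\tgene\t10\t90\t.\t+\t.\tID=geneC\n"
                       "chr2\tsrc\tmRNA\t10\t90\t.\t+\t.\tID=t1;Parent=geneC\n")
        rows = read_gene_loci(gff)
        assert rows == [("geneC", "chr2", 10, "+")]
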
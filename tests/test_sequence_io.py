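"""FASTA/GFF3 I/O, gene-body extraction, and genome tiling."""

import gzip

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpgoe.sequence_io import (
    ExtractionError,
    FastaFormatError,
    GeneModel,
    GffFormatError,
    SequenceRecord,
    extract_gene_bodies,
    read_fasta,
    read_gff_genes,
    tile_genome,
    write_fasta,
    write_gff_genes,
)

dna = st.text(alphabet="ACGTacgtn", min_size=1, max_size=80)
seq_ids = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd")),
    min_size=1,
    max_size=12,
)


class TestSequenceRecord:
    def test_upper_cases_and_validates(self):
        rec = SequenceRecord("a", "acgtN")
        assert rec.residues == "ACGTN"
        with pytest.raises(ValueError, match="non-IUPAC"):
            SequenceRecord("a", "ACGX")
        with pytest.raises(ValueError, match="non-empty"):
            SequenceRecord("", "ACGT")

    def test_reverse_complement_handles_ambiguity(self):
        assert SequenceRecord("a", "ACGTN").reverse_complement().residues == "NACGT"


class TestReadFasta:
    def test_parses_and_uppercases(self, fasta_file):
        recs = read_fasta(fasta_file(">a\nacgt\n>b\nNNGC\n"))
        assert [(r.id, r.residues) for r in recs] == [("a", "ACGT"), ("b", "NNGC")]

    def test_header_token_stops_at_whitespace(self, fasta_file):
        recs = read_fasta(fasta_file(">a description here\nACGT\n"))
        assert recs[0].id == "a"

    def test_empty_file_warns_and_returns_empty(self, fasta_file, caplog):
        with caplog.at_level("WARNING"):
            assert read_fasta(fasta_file("")) == []
        assert "no FASTA records" in caplog.text

    def test_duplicate_ids_rejected(self, fasta_file):
        with pytest.raises(FastaFormatError, match=r"duplicate.*\['a'\]"):
            read_fasta(fasta_file(">a\nACGT\n>a\nGGCC\n"))

    def test_sequence_before_header_names_line(self, fasta_file):
        with pytest.raises(FastaFormatError, match="line 1"):
            read_fasta(fasta_file("ACGT\n>a\nACGT\n"))

    def test_reads_gzip(self, tmp_path):
        path = tmp_path / "seqs.fa.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(">a\nACGT\n")
        assert read_fasta(path)[0].residues == "ACGT"

    @given(entries=st.lists(st.tuples(seq_ids, dna), min_size=1, max_size=8,
                            unique_by=lambda e: e[0]))
    def test_write_read_round_trip(self, tmp_path, entries):
        records = [SequenceRecord(i, s) for i, s in entries]
        path = tmp_path / "rt.fa"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.residues) for r in back] == [
            (r.id, r.residues) for r in records
        ]


class TestReadGffGenes:
    def test_coordinates_converted_to_half_open(self, gff_file):
        path = gff_file([
            "s1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1",
            "s1\tsrc\texon\t101\t200\t.\t+\t.\tParent=g1",
            "s1\tsrc\texon\t301\t400\t.\t+\t.\tParent=g1",
        ])
        (model,) = read_gff_genes(path)
        assert model.gene_id == "g1"
        assert model.exons == ((100, 200), (300, 400))
        assert model.strand == "+"

    def test_end_before_start_cites_line(self, gff_file):
        path = gff_file([
            "s1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1",
            "s1\tsrc\texon\t200\t101\t.\t+\t.\tParent=g1",
        ])
        with pytest.raises(GffFormatError, match="line 3"):
            read_gff_genes(path)

    def test_orphan_exon_skipped_with_warning(self, gff_file, caplog):
        path = gff_file([
            "s1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1",
            "s1\tsrc\texon\t1\t100\t.\t+\t.\tParent=g1",
            "s1\tsrc\texon\t150\t200\t.\t+\t.\tID=orphan",
        ])
        with caplog.at_level("WARNING"):
            models = read_gff_genes(path)
        assert len(models) == 1
        assert "skipped" in caplog.text

    def test_opposite_strands_on_one_scaffold(self, gff_file):
        path = gff_file([
            "s1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1",
            "s1\tsrc\texon\t1\t100\t.\t+\t.\tParent=g1",
            "s1\tsrc\tgene\t201\t300\t.\t-\t.\tID=g2",
            "s1\tsrc\texon\t201\t300\t.\t-\t.\tParent=g2",
        ])
        strands = {m.gene_id: m.strand for m in read_gff_genes(path)}
        assert strands == {"g1": "+", "g2": "-"}

    def test_exon_resolves_through_mrna_parent(self, gff_file):
        path = gff_file([
            "s1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1",
            "s1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1",
            "s1\tsrc\texon\t1\t100\t.\t+\t.\tParent=t1",
        ])
        (model,) = read_gff_genes(path)
        assert model.gene_id == "g1"

    def test_write_read_identity(self, tmp_path):
        models = [
            GeneModel("g1", "s1", "+", ((100, 200), (300, 400))),
            GeneModel("g2", "s1", "-", ((500, 650),)),
        ]
        path = tmp_path / "out.gff3"
        write_gff_genes(models, path)
        back = sorted(read_gff_genes(path), key=lambda m: m.gene_id)
        assert back == models


class TestExtractGeneBodies:
    genome = [SequenceRecord("s1", "AACCGGTTAACC")]

    def test_spliced_concatenates_exons(self):
        gene = GeneModel("g", "s1", "+", ((0, 4), (8, 12)))
        (out,) = extract_gene_bodies(self.genome, [gene], mode="spliced")
        assert out.residues == "AACCAACC"

    def test_span_takes_contiguous_region(self):
        gene = GeneModel("g", "s1", "+", ((0, 4), (8, 12)))
        (out,) = extract_gene_bodies(self.genome, [gene], mode="span")
        assert out.residues == "AACCGGTTAACC"

    def test_minus_strand_reverse_complemented(self):
        palindromic = GeneModel("g", "s1", "-", ((0, 4),))
        genome = [SequenceRecord("s1", "ACGTAAAA")]
        (out,) = extract_gene_bodies(genome, [palindromic], mode="spliced")
        assert out.residues == "ACGT"  # reverse complement of ACGT
        nonpal = GeneModel("g", "s1", "-", ((4, 8),))
        (out,) = extract_gene_bodies(genome, [nonpal], mode="spliced")
        assert out.residues == "TTTT"

    def test_truncation_is_five_prime_anchored(self):
        gene = GeneModel("g", "s1", "+", ((0, 12),))
        (out,) = extract_gene_bodies(self.genome, [gene], truncate_to=5)
        assert out.residues == "AACCG"
        (short,) = extract_gene_bodies(self.genome, [gene], truncate_to=100)
        assert short.residues == "AACCGGTTAACC"

    def test_minus_strand_truncation_after_orientation(self):
        gene = GeneModel("g", "s1", "-", ((0, 12),))
        (out,) = extract_gene_bodies(self.genome, [gene], truncate_to=4)
        assert out.residues == "GGTT"  # 5' end of the sense strand

    def test_unknown_scaffold_names_gene(self):
        gene = GeneModel("gX", "missing", "+", ((0, 4),))
        with pytest.raises(ExtractionError, match="gX"):
            extract_gene_bodies(self.genome, [gene])

    def test_span_beyond_scaffold_bounds(self):
        gene = GeneModel("gY", "s1", "+", ((0, 4), (10, 20)))
        with pytest.raises(ExtractionError, match="gY"):
            extract_gene_bodies(self.genome, [gene])

    @given(
        exon_lens=st.lists(st.integers(1, 10), min_size=1, max_size=5),
        gaps=st.lists(st.integers(1, 5), min_size=5, max_size=5),
    )
    def test_spliced_length_is_sum_of_exons(self, exon_lens, gaps):
        pos, exons = 0, []
        for length, gap in zip(exon_lens, gaps):
            exons.append((pos, pos + length))
            pos += length + gap
        genome = [SequenceRecord("s", "A" * pos)]
        gene = GeneModel("g", "s", "+", tuple(exons))
        (out,) = extract_gene_bodies(genome, [gene], mode="spliced")
        assert len(out) == sum(exon_lens)


class TestTileGenome:
    def test_partial_trailing_window_dropped(self):
        genome = [SequenceRecord("s", "ACGT" * 625)]  # 2500 bp
        result = tile_genome(genome, window=1000)
        assert len(result.windows) == 2
        assert [w.id for w in result.windows] == ["s:0", "s:1000"]
        assert result.n_partial_dropped == 1

    def test_ambiguous_window_discarded_and_counted(self):
        residues = "N" * 300 + "ACGT" * 175  # 1000 bp, 30% N
        result = tile_genome([SequenceRecord("s", residues)], window=1000)
        assert result.windows == []
        assert result.n_discarded_ambiguous == 1

    def test_scaffold_shorter_than_window(self):
        result = tile_genome([SequenceRecord("s", "A" * 999)], window=1000)
        assert result.windows == []

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError, match="window"):
            tile_genome([SequenceRecord("s", "ACGT")], window=1)

    @given(
        lengths=st.lists(st.integers(0, 50), min_size=1, max_size=4),
        window=st.integers(2, 12),
    )
    def test_window_count_and_lengths(self, lengths, window):
        genome = [
            SequenceRecord(f"s{i}", ("ACGT" * (n // 4 + 1))[:n])
            for i, n in enumerate(lengths)
            if n > 0
        ]
        result = tile_genome(genome, window=window)
        expected = sum(len(r) // window for r in genome)
        assert len(result.windows) == expected - result.n_discarded_ambiguous
        assert all(len(w) == window for w in result.windows)
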
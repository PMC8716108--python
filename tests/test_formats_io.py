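import numpy as np
import pytest

from termtte.formats_io import (
    EndCoverageTrack,
    FormatError,
    GenomeSequence,
    extract_rna_window,
    read_bedgraph,
    read_fasta,
    read_gff3,
    read_tts_table,
    rel_to_genomic,
    write_bedgraph,
    write_fasta,
    write_gff3,
    write_tts_table,
)
from termtte.formats_io import TranscriptionUnitAnnotation
from termtte.tts_caller import TTSRecord


class TestFasta:
    def test_case_and_rna_normalization(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nacgu\n")
        (g,) = read_fasta(p)
        assert g.chrom_id == "c"
        assert g.sequence == "ACGT"

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nACGT\n>c\nGGGG\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_write_read_round_trip(self, tmp_path):
        g = GenomeSequence("chrZ", "ACGTN" * 40)
        write_fasta([g], tmp_path / "g.fa")
        assert read_fasta(tmp_path / "g.fa") == [g]


GFF = """##gff-version 3
c\tsrc\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID=g1
{cds}
"""


def _write_gff(tmp_path, strand, cds_lines, gs=50, ge=400):
    p = tmp_path / "a.gff3"
    p.write_text(GFF.format(gs=gs, ge=ge, strand=strand, cds=cds_lines))
    return p


class TestGff3:
    GENOME = [GenomeSequence("c", "A" * 500)]

    def test_stop3_plus_is_max_cds_end(self, tmp_path):
        p = _write_gff(tmp_path, "+",
                       "c\tsrc\tCDS\t101\t400\t.\t+\t0\tID=c1;Parent=g1")
        (tu,) = read_gff3(p, self.GENOME)
        assert tu.stop3 == 400 and tu.biotype == "coding"

    def test_stop3_minus_is_min_cds_start(self, tmp_path):
        p = _write_gff(tmp_path, "-",
                       "c\tsrc\tCDS\t101\t400\t.\t-\t0\tID=c1;Parent=g1")
        (tu,) = read_gff3(p, self.GENOME)
        assert tu.stop3 == 101

    def test_stop3_uses_three_prime_most_segment(self, tmp_path):
        cds = ("c\tsrc\tCDS\t101\t200\t.\t+\t0\tID=c1;Parent=g1\n"
               "c\tsrc\tCDS\t250\t400\t.\t+\t0\tID=c2;Parent=g1")
        p = _write_gff(tmp_path, "+", cds)
        (tu,) = read_gff3(p, self.GENOME)
        assert tu.stop3 == 400

    def test_unknown_seqid_rejected(self, tmp_path):
        p = _write_gff(tmp_path, "+",
                       "c\tsrc\tCDS\t101\t400\t.\t+\t0\tID=c1;Parent=g1")
        with pytest.raises(FormatError, match="seqid"):
            read_gff3(p, [GenomeSequence("other", "A" * 500)])

    def test_gene_without_cds_becomes_ncrna(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\nc\tsrc\tgene\t50\t120\t.\t+\t.\tID=g1\n")
        with pytest.warns(UserWarning, match="no CDS"):
            (tu,) = read_gff3(p, self.GENOME)
        assert tu.biotype == "ncRNA" and tu.stop3 is None

    def test_write_read_round_trip(self, tmp_path):
        tus = [
            TranscriptionUnitAnnotation("g1", "c", "+", 50, 400, 400),
            TranscriptionUnitAnnotation("g2", "c", "-", 420, 480, 420),
        ]
        write_gff3(tus, self.GENOME, tmp_path / "a.gff3")
        back = read_gff3(tmp_path / "a.gff3", self.GENOME)
        assert [(t.tu_id, t.strand, t.stop3) for t in back] == [
            ("g1", "+", 400), ("g2", "-", 420)]


class TestBedgraph:
    def test_half_open_expansion(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("c\t0\t3\t5\nc\t10\t11\t7\n")
        t = read_bedgraph(p, "WT", 1, "+")
        assert [t[i] for i in (1, 2, 3)] == [5, 5, 5]
        assert t[11] == 7
        assert t[4] == 0  # sparse default

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("c\t0\t3\t5\nc\t2\t4\t1\n")
        with pytest.raises(FormatError, match="overlap"):
            read_bedgraph(p, "WT", 1, "+")

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("c\t0\t3\t-5\n")
        with pytest.raises(FormatError, match="negative"):
            read_bedgraph(p, "WT", 1, "+")

    def test_beyond_genome_rejected(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("c\t95\t105\t2\n")
        with pytest.raises(FormatError, match="beyond"):
            read_bedgraph(p, "WT", 1, "+", genome_length=100)

    def test_round_trip_conserves_counts(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = {int(p): float(v) for p, v in
                  zip(rng.choice(1000, 150, replace=False) + 1,
                      rng.integers(1, 50, 150))}
        track = EndCoverageTrack("WT", 1, "+", counts, chrom="c")
        write_bedgraph(track, tmp_path / "t.bg")
        back = read_bedgraph(tmp_path / "t.bg", "WT", 1, "+")
        assert back.counts == track.counts
        assert back.total() == track.total()


class TestRelativeCoordinates:
    def test_no_position_zero(self):
        with pytest.raises(ValueError):
            rel_to_genomic(100, 0, "+")

    def test_mapping_is_bijective_and_adjacent(self):
        rels = [r for r in range(-31, 6) if r != 0]
        for strand in "+-":
            gs = [rel_to_genomic(100, r, strand) for r in rels]
            assert len(set(gs)) == len(gs)
            step = 1 if strand == "+" else -1
            assert all(b - a == step for a, b in zip(gs, gs[1:]))
            assert rel_to_genomic(100, -1, strand) == 100

    def test_plus_strand_window(self, toy_genome):
        # window -2..+1 around TTS at 100 covers bases 99, 100, 101
        expect = toy_genome.sequence[98:101].replace("T", "U")
        assert extract_rna_window(toy_genome, "+", 100, -2, 1) == expect

    def test_minus_strand_hand_reverse_complement(self):
        g = GenomeSequence("c", "AAAATTTT")
        # TTS at 5 on '-': positions 5,4,3 read 5'->3' = complement of T,A,A
        assert extract_rna_window(g, "-", 5, -1, 2) == "AUU"

    def test_u4_window_has_length_31(self, toy_genome):
        assert len(extract_rna_window(toy_genome, "+", 60, -31, -1)) == 31

    def test_out_of_bounds_is_error(self, toy_genome):
        with pytest.raises(FormatError):
            extract_rna_window(toy_genome, "+", 10, -31, -1)

    def test_strand_symmetry(self, toy_genome):
        """Reverse-complementing the genome and flipping strand/position
        yields the identical RNA window."""
        rc = toy_genome.sequence[::-1].translate(str.maketrans("ACGT", "TGCA"))
        flipped = GenomeSequence("c", rc)
        n = len(toy_genome)
        for tts, strand in [(60, "+"), (60, "-"), (80, "+")]:
            other = "-" if strand == "+" else "+"
            a = extract_rna_window(toy_genome, strand, tts, -10, 3)
            b = extract_rna_window(flipped, other, n - tts + 1, -10, 3)
            assert a == b


class TestTtsTable:
    def _records(self):
        return [
            TTSRecord("tuA", "c", "+", 240, True, 40,
                      {"WT": (100.0, 300.0, 40.0, 40.0),
                       "dep": (100.0, 200.0, 70.0, 70.0)}),
            TTSRecord("tuB", "c", "-", 900, True, 12,
                      {"WT": (50.0, 80.0, 30.0, 25.0),
                       "dep": (50.0, 60.0, 40.0, 42.0)}),
        ]

    def test_round_trip(self, tmp_path):
        recs = self._records()
        write_tts_table(recs, tmp_path / "tts.tsv")
        back = read_tts_table(tmp_path / "tts.tsv")
        assert [(r.tu_id, r.strand, r.pos, r.is_primary, r.utr3_len,
                 r.quadruplet) for r in back] == \
               [(r.tu_id, r.strand, r.pos, r.is_primary, r.utr3_len,
                 r.quadruplet) for r in recs]

    def test_empty_list_writes_header_only(self, tmp_path):
        write_tts_table([], tmp_path / "tts.tsv")
        lines = (tmp_path / "tts.tsv").read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("tu_id\t")
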
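"""Transcript model, 5'UTR extraction, and c.-coordinate mapping."""

import pytest

from fiveutr.errors import OutOfRangeError, UnsupportedBiotypeError
from fiveutr.genome_model import (
    CPosition,
    GenomicInterval,
    TranscriptModel,
    five_prime_utr,
    intersection_length,
    load_annotation,
    map_c_to_genomic,
    map_genomic_to_c,
    merge_intervals,
    reverse_complement,
    utr5_length,
)


def tx_plus(cds_start=350, exons=((100, 200), (300, 400))):
    return TranscriptModel(
        "TXP", "G1", "GENE1", "+",
        [GenomicInterval("chr1", s, e, "+") for s, e in exons],
        cds_start_genomic=cds_start, cds_end_genomic=395,
    )


def tx_minus(cds_start=150, exons=((300, 400), (100, 200))):
    # exons given 5'->3' (descending start on the minus strand)
    return TranscriptModel(
        "TXM", "G2", "GENE2", "-",
        [GenomicInterval("chr1", s, e, "-") for s, e in exons],
        cds_start_genomic=cds_start, cds_end_genomic=105,
    )


class TestIntervals:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_merge_and_intersection(self):
        a = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 250)]
        assert merge_intervals(a) == [GenomicInterval("chr1", 100, 250)]
        b = [GenomicInterval("chr1", 240, 300)]
        assert intersection_length(a, b) == 10
        assert intersection_length(a, [GenomicInterval("chr2", 100, 300)]) == 0


class TestFivePrimeUtr:
    def test_plus_strand_split_exon(self):
        assert five_prime_utr(tx_plus()) == [
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 300, 350, "+"),
        ]

    def test_empty_when_cds_at_transcript_start(self):
        tx = tx_plus(cds_start=100)
        assert five_prime_utr(tx) == []

    def test_minus_strand_boundary(self):
        # first AUG base at 150 read leftward: UTR is everything rightward
        assert five_prime_utr(tx_minus()) == [
            GenomicInterval("chr1", 300, 400, "-"),
            GenomicInterval("chr1", 151, 200, "-"),
        ]

    def test_non_coding_rejected(self):
        tx = TranscriptModel(
            "NC", "G", "G", "+", [GenomicInterval("chr1", 0, 50, "+")], biotype="lncRNA"
        )
        with pytest.raises(UnsupportedBiotypeError):
            five_prime_utr(tx)

    def test_utr_length_equals_cds_transcript_index(self):
        for tx in (tx_plus(), tx_minus()):
            assert utr5_length(tx) == tx.cds_start_tindex


class TestCMapping:
    def test_minus_one_abuts_aug(self):
        tx = tx_plus()
        assert map_genomic_to_c(tx, 349) == CPosition("utr5", -1)
        assert map_genomic_to_c(tx, 350) == CPosition("cds", 1)

    def test_near_splice_donor_plus_one(self):
        # last exonic base of the upstream exon is c.-9 (8 UTR bases remain
        # in the downstream exon); the first intronic base is c.-9+1
        tx = tx_plus(cds_start=308, exons=((100, 200), (300, 400)))
        assert map_genomic_to_c(tx, 199) == CPosition("utr5", -9)
        assert map_genomic_to_c(tx, 200) == CPosition("utr5_intronic", -9, 1)

    def test_acceptor_side_notation(self):
        tx = tx_plus(cds_start=308, exons=((100, 200), (300, 400)))
        assert map_genomic_to_c(tx, 299) == CPosition("utr5_intronic", -8, -1)

    def test_out_of_range(self):
        with pytest.raises(OutOfRangeError):
            map_genomic_to_c(tx_plus(), 5000)

    @pytest.mark.parametrize("tx", [tx_plus(), tx_minus(), tx_plus(cds_start=309)])
    def test_round_trip_every_position(self, tx):
        """Exhaustive genomic -> c. -> genomic identity over the toy span."""
        span = tx.span
        n_checked = 0
        for pos in range(span.start, span.end):
            try:
                cpos = map_genomic_to_c(tx, pos)
            except OutOfRangeError:
                continue
            assert map_c_to_genomic(tx, cpos) == pos
            n_checked += 1
        assert n_checked > 100

    def test_intron_midpoint_ties_to_donor(self):
        # odd-length intron [200, 301): at the exact midpoint the donor side wins
        tx = tx_plus(cds_start=350, exons=((100, 200), (301, 400)))
        cp = map_genomic_to_c(tx, 250)  # k_donor = 51 == k_acceptor
        assert cp.intron_offset == 51
        cp = map_genomic_to_c(tx, 251)  # k_acceptor = 50 < k_donor = 52
        assert cp.intron_offset == -50

    def test_strand_symmetry_under_mirroring(self, annotation):
        """Reverse-complementing the genome and flipping strands leaves all
        c. positions unchanged (checked structurally on synthetic models)."""
        L = 10_000_000
        for tid in list(annotation.transcripts)[:8]:
            tx = annotation[tid]
            flipped = "-" if tx.strand == "+" else "+"
            mirror = TranscriptModel(
                tx.transcript_id, tx.gene_id, tx.gene_symbol, flipped,
                [
                    GenomicInterval(e.chrom, L - e.end, L - e.start, flipped)
                    for e in tx.exons
                ],
                cds_start_genomic=L - 1 - tx.cds_start_genomic,
                cds_end_genomic=L - 1 - tx.cds_end_genomic,
            )
            span = tx.span
            for pos in range(span.start, span.end, 7):
                try:
                    orig = map_genomic_to_c(tx, pos)
                except OutOfRangeError:
                    continue
                assert map_genomic_to_c(mirror, L - 1 - pos) == orig


class TestLoadAnnotation:
    def test_toy_gtf_parse_and_conversion(self, tmp_path):
        # GTF is 1-based inclusive: exon "101 200" -> internal [100, 200)
        gtf = tmp_path / "toy.gtf"
        fa = tmp_path / "toy.fa"
        fa.write_text(">chr1\n" + "ACGT" * 150 + "\n")
        attrs = 'gene_id "g1"; transcript_id "t1"; gene_name "TOY"; transcript_biotype "protein_coding"; tag "Ensembl_canonical";'
        gtf.write_text(
            "\n".join(
                [
                    f"chr1\tx\tgene\t101\t400\t.\t+\t.\t" + attrs,
                    f"chr1\tx\ttranscript\t101\t400\t.\t+\t.\t" + attrs,
                    f"chr1\tx\texon\t101\t200\t.\t+\t.\t" + attrs,
                    f"chr1\tx\texon\t301\t400\t.\t+\t.\t" + attrs,
                    f"chr1\tx\tCDS\t351\t400\t.\t+\t0\t" + attrs,
                ]
            )
            + "\n"
        )
        ann = load_annotation(gtf, fa)
        tx = ann["t1"]
        assert [(e.start, e.end) for e in tx.exons] == [(100, 200), (300, 400)]
        assert tx.cds_start_genomic == 350
        assert tx.is_canonical and not tx.is_mane

    def test_minus_strand_exon_reordering(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        fa = tmp_path / "toy.fa"
        fa.write_text(">chr1\n" + "ACGT" * 150 + "\n")
        attrs = 'gene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";'
        gtf.write_text(
            "\n".join(
                [
                    "chr1\tx\tgene\t101\t400\t.\t-\t.\t" + attrs,
                    "chr1\tx\ttranscript\t101\t400\t.\t-\t.\t" + attrs,
                    "chr1\tx\texon\t101\t200\t.\t-\t.\t" + attrs,
                    "chr1\tx\texon\t301\t400\t.\t-\t.\t" + attrs,
                    "chr1\tx\tCDS\t101\t151\t.\t-\t0\t" + attrs,
                ]
            )
            + "\n"
        )
        tx = load_annotation(gtf, fa)["t1"]
        assert [(e.start, e.end) for e in tx.exons] == [(300, 400), (100, 200)]
        assert tx.cds_start_genomic == 150

    def test_sequence_accessor_strand(self, tmp_path):
        fa = tmp_path / "toy.fa"
        fa.write_text(">chr1\nAACCGGTT\n")
        gtf = tmp_path / "toy.gtf"
        attrs = 'gene_id "g"; transcript_id "t"; transcript_biotype "protein_coding";'
        gtf.write_text(
            "chr1\tx\ttranscript\t1\t8\t.\t+\t.\t" + attrs + "\n"
            "chr1\tx\texon\t1\t8\t.\t+\t.\t" + attrs + "\n"
            "chr1\tx\tCDS\t5\t8\t.\t+\t0\t" + attrs + "\n"
        )
        ann = load_annotation(gtf, fa)
        iv = GenomicInterval("chr1", 0, 4, "+")
        assert ann.sequence(iv) == "AACC"
        assert ann.sequence(GenomicInterval("chr1", 0, 4, "-")) == reverse_complement("AACC")

    def test_non_coding_transcripts_dropped(self, annotation):
        assert "TSYN0003L" not in annotation
        assert all(t.is_coding for t in annotation.transcripts.values())
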
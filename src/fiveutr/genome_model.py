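"""Transcript and genome data model.

Internal coordinates are 0-based half-open throughout; GTF/VCF input is
converted at the boundary.  A :class:`TranscriptModel` stores its exons in
5'->3' transcript order (descending genomic coordinate on the minus strand)
and provides the genomic <-> transcript <-> HGVS c. coordinate mappings used
by every downstream stage.

HGVS c. numbering follows the standard convention: there is no position 0,
c.-1 is the base immediately 5' of the A of the main AUG, and intronic bases
inside a 5'UTR intron are reported relative to the nearer exon edge
(c.-N+k from the donor, c.-N-k from the acceptor; ties break to the donor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from pyfaidx import Fasta

from .errors import AnnotationError, OutOfRangeError, UnsupportedBiotypeError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self!r}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def padded(self, bp: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - bp), self.end + bp, self.strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, non-overlapping list (strand dropped)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out.pop()
            iv = GenomicInterval(iv.chrom, prev.start, max(prev.end, iv.end))
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Genomic intersection of two interval sets (each internally unioned)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    for x in a:
        for y in b:
            if x.overlaps(y):
                out.append(GenomicInterval(x.chrom, max(x.start, y.start), min(x.end, y.end)))
    return merge_intervals(out)


def intersection_length(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]) -> int:
    return total_length(intersect_intervals(a, b))


@dataclass(frozen=True)
class CPosition:
    """HGVS-style c. position restricted to the 5'UTR/CDS kinds used here.

    ``kind`` is one of ``utr5`` (exonic, ``c_offset`` < 0), ``cds``
    (``c_offset`` >= 1) or ``utr5_intronic`` (``c_offset`` anchors the nearer
    exon edge, ``intron_offset`` is +k from a donor / -k from an acceptor).
    """

    kind: str
    c_offset: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("utr5", "cds", "utr5_intronic"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind != "utr5_intronic" and self.intron_offset:
            raise ValueError("intron_offset only valid for utr5_intronic")
        if self.kind == "utr5" and self.c_offset >= 0:
            raise ValueError("utr5 positions are negative")
        if self.kind == "cds" and self.c_offset < 1:
            raise ValueError("cds positions start at 1")

    def __str__(self) -> str:
        if self.kind == "utr5_intronic":
            sign = "+" if self.intron_offset > 0 else "-"
            return f"c.{self.c_offset}{sign}{abs(self.intron_offset)}"
        return f"c.{self.c_offset}"


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` are ordered 5'->3' along the strand.  ``cds_start_genomic`` is
    the genomic 0-based position of the first base of the main AUG (on the
    minus strand this is the highest-coordinate base of the codon);
    ``cds_end_genomic`` the position of the last CDS base.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    strand: str
    exons: list[GenomicInterval]
    cds_start_genomic: int | None = None
    cds_end_genomic: int | None = None
    biotype: str = "protein_coding"
    is_canonical: bool = False
    is_mane: bool = False
    canonical_evidence: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        starts = [e.start for e in self.exons]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise AnnotationError(
                f"{self.transcript_id}: exons not ordered 5'->3' along {self.strand} strand"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a, b) if a.start < b.start else (b, a)
            if lo.end > hi.start:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        if self.is_coding and self.transcript_index(self.cds_start_genomic) is None:
            raise AnnotationError(
                f"{self.transcript_id}: CDS start {self.cds_start_genomic} "
                "lies outside every exon"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def is_coding(self) -> bool:
        return self.cds_start_genomic is not None

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def _cumulative(self) -> list[int]:
        offs, total = [], 0
        for e in self.exons:
            offs.append(total)
            total += len(e)
        return offs

    def transcript_index(self, pos: int) -> int | None:
        """0-based index of a genomic base along the spliced transcript.

        Returns None for intronic or out-of-span positions.
        """
        for off, e in zip(self._cumulative(), self.exons):
            if e.contains(pos):
                if self.strand == "+":
                    return off + (pos - e.start)
                return off + (e.end - 1 - pos)
        return None

    def genomic_position(self, tindex: int) -> int:
        if tindex < 0 or tindex >= self.length:
            raise OutOfRangeError(f"{self.transcript_id}: transcript index {tindex}")
        for off, e in zip(self._cumulative(), self.exons):
            if off <= tindex < off + len(e):
                if self.strand == "+":
                    return e.start + (tindex - off)
                return e.end - 1 - (tindex - off)
        raise AssertionError("unreachable")

    @property
    def cds_start_tindex(self) -> int:
        if not self.is_coding:
            raise UnsupportedBiotypeError(f"{self.transcript_id} is non-coding")
        ti = self.transcript_index(self.cds_start_genomic)
        assert ti is not None
        return ti

    def introns(self) -> list[GenomicInterval]:
        """Introns in transcript order (unstranded genomic intervals)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.chrom, a.end, b.start))
            else:
                out.append(GenomicInterval(self.chrom, b.end, a.start))
        return out


def five_prime_utr(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Exonic intervals strictly 5' of the CDS start, in 5'->3' order.

    Empty when the annotated transcript start coincides with the CDS start.
    """
    if not transcript.is_coding:
        raise UnsupportedBiotypeError(
            f"{transcript.transcript_id}: 5'UTR undefined for non-coding transcript"
        )
    cds = transcript.cds_start_genomic
    out: list[GenomicInterval] = []
    for e in transcript.exons:
        if transcript.strand == "+":
            if e.end <= cds:
                out.append(e)
            elif e.start < cds:
                out.append(GenomicInterval(e.chrom, e.start, cds, e.strand))
        else:
            if e.start > cds:
                out.append(e)
            elif e.end > cds + 1:
                out.append(GenomicInterval(e.chrom, cds + 1, e.end, e.strand))
    return out


def utr5_length(transcript: TranscriptModel) -> int:
    return sum(len(iv) for iv in five_prime_utr(transcript))


def map_genomic_to_c(transcript: TranscriptModel, pos: int, flank: int = 1000) -> CPosition:
    """Map a genomic position to a 5'UTR/CDS c. position.

    Exonic bases 5' of the AUG map to c.-N (c.-1 abuts the A of AUG); CDS
    bases to c.N; intronic bases in 5'UTR introns to nearest-edge notation.
    Positions outside the transcript span +- ``flank``, upstream of the
    transcription start, or inside CDS introns raise :class:`OutOfRangeError`.
    """
    ti = transcript.transcript_index(pos)
    t_cds = transcript.cds_start_tindex
    if ti is not None:
        d = ti - t_cds
        return CPosition("utr5", d) if d < 0 else CPosition("cds", d + 1)

    span = transcript.span
    if transcript.chrom and not (span.start - flank <= pos < span.end + flank):
        raise OutOfRangeError(
            f"{transcript.transcript_id}: {pos} outside span +- {flank} bp"
        )
    for i, intron in enumerate(transcript.introns()):
        if not intron.contains(pos):
            continue
        donor_exon, acceptor_exon = transcript.exons[i], transcript.exons[i + 1]
        if transcript.strand == "+":
            k_donor = pos - donor_exon.end + 1
            k_acceptor = acceptor_exon.start - pos
            donor_base, acceptor_base = donor_exon.end - 1, acceptor_exon.start
        else:
            k_donor = donor_exon.start - pos
            k_acceptor = pos - acceptor_exon.end + 1
            donor_base, acceptor_base = donor_exon.start, acceptor_exon.end - 1

        def _c(p: int) -> int | None:
            t = transcript.transcript_index(p)
            d = t - t_cds
            return d if d < 0 else None  # only UTR bases anchor here

        cand = []
        cd = _c(donor_base)
        ca = _c(acceptor_base)
        if cd is not None:
            cand.append((k_donor, 0, CPosition("utr5_intronic", cd, k_donor)))
        if ca is not None:
            cand.append((k_acceptor, 1, CPosition("utr5_intronic", ca, -k_acceptor)))
        if not cand:
            raise OutOfRangeError(
                f"{transcript.transcript_id}: {pos} lies in a CDS intron"
            )
        cand.sort(key=lambda t: (t[0], t[1]))  # tie -> donor side
        return cand[0][2]
    raise OutOfRangeError(f"{transcript.transcript_id}: {pos} not in transcript or introns")


def map_c_to_genomic(transcript: TranscriptModel, cpos: CPosition) -> int:
    """Exact inverse of :func:`map_genomic_to_c`."""
    t_cds = transcript.cds_start_tindex
    if cpos.kind == "utr5":
        return transcript.genomic_position(t_cds + cpos.c_offset)
    if cpos.kind == "cds":
        return transcript.genomic_position(t_cds + cpos.c_offset - 1)
    anchor = transcript.genomic_position(t_cds + cpos.c_offset)
    k = cpos.intron_offset
    step = 1 if transcript.strand == "+" else -1
    # +k walks 3' into the intron from the donor edge, -k walks 5' from the
    # acceptor edge; both are the same genomic direction flip on minus strand.
    return anchor + step * k


class GenomeAnnotation:
    """Transcript collection plus a genomic sequence accessor."""

    def __init__(self, transcripts: Sequence[TranscriptModel], fasta_path: str | Path):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        self.by_symbol: dict[str, list[TranscriptModel]] = {}
        for tx in transcripts:
            self.transcripts[tx.transcript_id] = tx
            self.by_gene.setdefault(tx.gene_id, []).append(tx)
            self.by_symbol.setdefault(tx.gene_symbol, []).append(tx)
        self._fasta = Fasta(str(fasta_path))

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def sequence(self, interval: GenomicInterval) -> str:
        """Genomic sequence of an interval, reverse-complemented on '-'."""
        if interval.chrom not in self._fasta:
            raise OutOfRangeError(f"unknown chromosome {interval.chrom!r}")
        raw = str(self._fasta[interval.chrom][interval.start : interval.end]).upper()
        if len(raw) != len(interval):
            raise OutOfRangeError(f"{interval} extends past the end of {interval.chrom}")
        return reverse_complement(raw) if interval.strand == "-" else raw

    def spliced_utr_sequence(self, transcript: TranscriptModel) -> str:
        """5'->3' mRNA-sense (DNA alphabet) spliced 5'UTR sequence."""
        parts = []
        for iv in five_prime_utr(transcript):
            parts.append(
                self.sequence(GenomicInterval(iv.chrom, iv.start, iv.end, transcript.strand))
            )
        return "".join(parts)

    def cds_sequence(self, transcript: TranscriptModel, max_len: int = 999) -> str:
        """Spliced CDS sequence from the main AUG, truncated to ``max_len``."""
        t0 = transcript.cds_start_tindex
        t1 = transcript.transcript_index(transcript.cds_end_genomic)
        if t1 is None:
            raise AnnotationError(f"{transcript.transcript_id}: CDS end outside exons")
        n = min(t1 - t0 + 1, max_len)
        return "".join(
            self.sequence(
                GenomicInterval(
                    transcript.chrom, g := transcript.genomic_position(t0 + i), g + 1, transcript.strand
                )
            )
            for i in range(n)
        )


def load_annotation(gtf_path: str | Path, fasta_path: str | Path) -> GenomeAnnotation:
    """Load protein-coding transcripts from an Ensembl-dialect GTF + FASTA.

    Non-coding transcripts are dropped with a logged count.  Either an
    ``Ensembl_canonical`` or a ``MANE_Select`` tag marks a transcript
    canonical; which tag was seen is recorded on the model.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[TranscriptModel] = []
    n_dropped = 0
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        gid = t.attributes["gene_id"][0]
        symbol = t.attributes.get("gene_name", [gid])[0]
        biotype = t.attributes.get("transcript_biotype", ["protein_coding"])[0]
        exons = sorted(
            (
                GenomicInterval(e.seqid, e.start - 1, e.end, t.strand)
                for e in db.children(t, featuretype="exon")
            ),
            key=lambda iv: iv.start,
            reverse=t.strand == "-",
        )
        cds = list(db.children(t, featuretype="CDS"))
        if biotype != "protein_coding" or not cds:
            n_dropped += 1
            continue
        cds_lo = min(c.start - 1 for c in cds)
        cds_hi = max(c.end for c in cds)
        if t.strand == "+":
            cds_start, cds_end = cds_lo, cds_hi - 1
        else:
            cds_start, cds_end = cds_hi - 1, cds_lo
        tags = t.attributes.get("tag", [])
        is_mane = "MANE_Select" in tags
        is_canon = "Ensembl_canonical" in tags or is_mane
        evidence = ",".join(tag for tag in tags if tag in ("Ensembl_canonical", "MANE_Select"))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                gene_symbol=symbol,
                strand=t.strand,
                exons=exons,
                cds_start_genomic=cds_start,
                cds_end_genomic=cds_end,
                biotype=biotype,
                is_canonical=is_canon,
                is_mane=is_mane,
                canonical_evidence=evidence,
            )
        )
    if n_dropped:
        log.info("dropped %d non-coding transcripts at load", n_dropped)
    return GenomeAnnotation(models, fasta_path)


def write_bed(intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    """Write (interval, name) pairs as BED6 (score 0)."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            strand = iv.strand or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals (strand kept when a 6th column exists)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out
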
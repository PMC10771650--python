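"""The 5'UTR analysis file and the exome-capture audit.

``build_analysis_regions`` turns the selected transcripts into a sorted
list of regions searched for variants: every 5'UTR exon plus, for every
splice junction internal to the 5'UTR, 25 bp of intronic sequence on the
donor and acceptor sides.  No flank is emitted upstream of the
transcription start (promoter side), flanks never extend past their intron,
and no region base overlaps CDS.

``capture_coverage`` intersects per-gene 5'UTR unions with a capture
design's bait intervals (optionally padded) and reports the captured
length proportion per gene, mirroring how commercial exome kits are
audited against non-coding target regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError
from .genome_model import (
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
    five_prime_utr,
    intersection_length,
    merge_intervals,
    read_bed,
    total_length,
)

log = logging.getLogger(__name__)

KIND_UTR_EXON = "utr_exon"
KIND_DONOR = "near_splice_donor"
KIND_ACCEPTOR = "near_splice_acceptor"


@dataclass(frozen=True)
class AnalysisRegion:
    interval: GenomicInterval
    kind: str
    transcript_id: str
    gene_symbol: str

    @property
    def name(self) -> str:
        return f"{self.gene_symbol}|{self.transcript_id}|{self.kind}"


def _clip(lo: int, hi: int, bound: GenomicInterval) -> tuple[int, int]:
    return max(lo, bound.start), min(hi, bound.end)


def build_analysis_regions(
    transcripts: list[TranscriptModel], flank_bp: int = 25
) -> list[AnalysisRegion]:
    """Sorted analysis regions for the selected transcripts."""
    if flank_bp <= 0:
        raise ConfigurationError(f"flank_bp must be positive, got {flank_bp}")
    regions: list[AnalysisRegion] = []
    for tx in transcripts:
        utr = five_prime_utr(tx)
        for iv in utr:
            regions.append(
                AnalysisRegion(
                    GenomicInterval(iv.chrom, iv.start, iv.end, tx.strand),
                    KIND_UTR_EXON,
                    tx.transcript_id,
                    tx.gene_symbol,
                )
            )
        # Flanks: one donor + one acceptor per intron whose flanking exonic
        # bases are both 5'UTR (junction internal to the 5'UTR).  An exon
        # that begins with CDS gets no acceptor flank, an exon whose 3' end
        # is CDS gets no donor flank, and the promoter-side flank upstream
        # of the first exon is never emitted.
        cds_t = tx.cds_start_tindex
        for i, intron in enumerate(tx.introns()):
            donor_exon, acceptor_exon = tx.exons[i], tx.exons[i + 1]
            if tx.strand == "+":
                donor_base, acceptor_base = donor_exon.end - 1, acceptor_exon.start
            else:
                donor_base, acceptor_base = donor_exon.start, acceptor_exon.end - 1
            donor_is_utr = tx.transcript_index(donor_base) < cds_t
            acceptor_is_utr = tx.transcript_index(acceptor_base) < cds_t
            if donor_is_utr:
                if tx.strand == "+":
                    lo, hi = _clip(intron.start, intron.start + flank_bp, intron)
                else:
                    lo, hi = _clip(intron.end - flank_bp, intron.end, intron)
                regions.append(
                    AnalysisRegion(
                        GenomicInterval(intron.chrom, lo, hi, tx.strand),
                        KIND_DONOR,
                        tx.transcript_id,
                        tx.gene_symbol,
                    )
                )
            if acceptor_is_utr:
                if tx.strand == "+":
                    lo, hi = _clip(intron.end - flank_bp, intron.end, intron)
                else:
                    lo, hi = _clip(intron.start, intron.start + flank_bp, intron)
                regions.append(
                    AnalysisRegion(
                        GenomicInterval(intron.chrom, lo, hi, tx.strand),
                        KIND_ACCEPTOR,
                        tx.transcript_id,
                        tx.gene_symbol,
                    )
                )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.name))
    return regions


def write_regions_bed(regions: list[AnalysisRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            strand = r.interval.strand or "."
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.name}\t0\t{strand}\n"
            )


def read_regions_bed(path: str | Path) -> list[AnalysisRegion]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            gene, tid, kind = name.split("|")
            out.append(
                AnalysisRegion(
                    GenomicInterval(chrom, int(start), int(end), strand if strand in "+-" else None),
                    kind,
                    tid,
                    gene,
                )
            )
    return out


@dataclass
class CaptureDesign:
    name: str
    intervals: list[GenomicInterval]
    padding_bp: int = 0

    def __post_init__(self) -> None:
        if self.padding_bp < 0:
            raise ConfigurationError("padding_bp must be >= 0")

    @property
    def padded_intervals(self) -> list[GenomicInterval]:
        return merge_intervals(iv.padded(self.padding_bp) for iv in self.intervals)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None, padding_bp: int = 0):
        return cls(name or Path(path).stem, read_bed(path), padding_bp)


@dataclass
class CoverageReport:
    design: str
    padding_bp: int
    per_gene: pd.DataFrame  # gene_symbol, utr_length_bp, captured_bp, percent_captured
    union_rule: str = "genomic union over the gene's selected (<=2) transcripts"

    @property
    def mean_percent(self) -> float:
        return float(self.per_gene["percent_captured"].mean())

    @property
    def n_fully_captured(self) -> int:
        return int((self.per_gene["percent_captured"] == 100.0).sum())


def gene_utr_unions(
    annotation: GenomeAnnotation, selected: dict[str, list[str]]
) -> dict[str, list[GenomicInterval]]:
    """Per-gene genomic union of the selected transcripts' 5'UTR exons."""
    out = {}
    for symbol, tx_ids in selected.items():
        ivs = []
        for tid in tx_ids:
            ivs.extend(five_prime_utr(annotation[tid]))
        out[symbol] = merge_intervals(ivs)
    return out


def capture_coverage(
    gene_utrs: dict[str, list[GenomicInterval]], design: CaptureDesign
) -> CoverageReport:
    """Captured 5'UTR length proportion per gene for one capture design."""
    if not design.intervals:
        log.warning("capture design %s is empty; reporting zero coverage", design.name)
    baits = design.padded_intervals
    rows = []
    for symbol in sorted(gene_utrs):
        utr = gene_utrs[symbol]
        utr_len = total_length(utr)
        captured = intersection_length(utr, baits) if baits else 0
        pct = 100.0 * captured / utr_len if utr_len else 0.0
        rows.append(
            {
                "gene_symbol": symbol,
                "utr_length_bp": utr_len,
                "captured_bp": captured,
                "percent_captured": round(pct, 2),
            }
        )
    return CoverageReport(design.name, design.padding_bp, pd.DataFrame(rows))
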
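"""Per-gene isoform selection from a transcript TPM matrix.

For each panel gene the canonical protein-coding transcript is always
retained; additionally, the protein-coding transcript with the highest mean
TPM across all samples is retained when it is non-canonical ("tissue
enriched"), so at most two isoforms survive per gene.  Ties at identical
means resolve to the canonical transcript (and among non-canonical ties to
the lexicographically smallest id) so the selection is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ContractViolation, InputError
from .genome_model import (
    GenomeAnnotation,
    five_prime_utr,
    intersection_length,
    total_length,
)

log = logging.getLogger(__name__)

OVERLAP_FULLY_DISTINCT = "fully_distinct"
OVERLAP_PARTLY = "partly_overlapping"
OVERLAP_FULLY = "fully_overlapping"


def read_expression(path: str | Path) -> pd.DataFrame:
    """TPM matrix as a DataFrame (rows: transcript_id, columns: samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise InputError("negative TPM values in expression matrix")
    return df


def mean_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean and standard deviation of TPM per transcript."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InputError("empty expression matrix")
    return pd.DataFrame(
        {"mean_tpm": matrix.mean(axis=1), "sd_tpm": matrix.std(axis=1, ddof=1).fillna(0.0)}
    )


@dataclass
class IsoformSelection:
    gene_id: str
    gene_symbol: str
    canonical_id: str
    enriched_id: str  # equals canonical_id when no non-canonical top isoform
    canonical_mean_tpm: float
    enriched_mean_tpm: float
    has_noncanonical_enriched: bool

    @property
    def retained_ids(self) -> list[str]:
        if self.has_noncanonical_enriched:
            return [self.canonical_id, self.enriched_id]
        return [self.canonical_id]


def select_isoforms(
    annotation: GenomeAnnotation,
    means: pd.DataFrame,
    gene_list: list[str],
) -> list[IsoformSelection]:
    """One :class:`IsoformSelection` per panel gene symbol.

    Expression rows whose transcript id is absent from the annotation are
    skipped with a log message; genes without any expression row keep the
    canonical transcript with mean 0.
    """
    unresolved = [t for t in means.index if t not in annotation.transcripts]
    if unresolved:
        log.info("skipping %d expression rows with unknown transcript ids", len(unresolved))
    mean_of = means["mean_tpm"]
    out: list[IsoformSelection] = []
    for symbol in gene_list:
        txs = [t for t in annotation.by_symbol.get(symbol, []) if t.biotype == "protein_coding"]
        if not txs:
            raise ConfigurationError(f"gene {symbol!r} has no protein-coding transcript")
        canonical = [t for t in txs if t.is_canonical]
        if not canonical:
            raise ConfigurationError(f"gene {symbol!r} has no canonical transcript")
        can = canonical[0]
        if not can.is_coding:
            log.warning("gene %s: canonical transcript is non-coding; gene excluded", symbol)
            continue

        def gene_mean(tx_id: str) -> float:
            return float(mean_of.get(tx_id, 0.0))

        if all(gene_mean(t.transcript_id) == 0.0 for t in txs):
            log.warning("gene %s has no expressed transcripts; canonical retained", symbol)
        # Highest mean wins; canonical wins ties, then smallest id.
        top = max(
            txs,
            key=lambda t: (gene_mean(t.transcript_id), t.is_canonical, _neg_id(t.transcript_id)),
        )
        has_nc = top.transcript_id != can.transcript_id
        out.append(
            IsoformSelection(
                gene_id=can.gene_id,
                gene_symbol=symbol,
                canonical_id=can.transcript_id,
                enriched_id=top.transcript_id if has_nc else can.transcript_id,
                canonical_mean_tpm=gene_mean(can.transcript_id),
                enriched_mean_tpm=gene_mean(top.transcript_id),
                has_noncanonical_enriched=has_nc,
            )
        )
    return out


class _neg_id(str):
    """Reverse lexicographic key so that max() prefers the smallest id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str(self) > str(other)


@dataclass
class UtrOverlapClass:
    gene_id: str
    gene_symbol: str
    overlap_class: str
    shared_bases: int
    len_canonical: int
    len_noncanonical: int


def classify_utr_overlap(
    selection: IsoformSelection, annotation: GenomeAnnotation
) -> UtrOverlapClass:
    """Overlap class of canonical vs enriched 5'UTRs for one gene.

    ``fully_overlapping`` means the shorter 5'UTR is genomically contained
    in the longer one; zero shared bases is ``fully_distinct``; anything
    else is ``partly_overlapping``.
    """
    if not selection.has_noncanonical_enriched:
        raise ContractViolation(f"gene {selection.gene_symbol} has no non-canonical isoform")
    utr_can = five_prime_utr(annotation[selection.canonical_id])
    utr_enr = five_prime_utr(annotation[selection.enriched_id])
    len_can = total_length(utr_can)
    len_enr = total_length(utr_enr)
    shared = intersection_length(utr_can, utr_enr)
    if shared == 0:
        cls = OVERLAP_FULLY_DISTINCT
    elif shared == min(len_can, len_enr):
        cls = OVERLAP_FULLY
    else:
        cls = OVERLAP_PARTLY
    return UtrOverlapClass(
        gene_id=selection.gene_id,
        gene_symbol=selection.gene_symbol,
        overlap_class=cls,
        shared_bases=shared,
        len_canonical=len_can,
        len_noncanonical=len_enr,
    )


def selection_table(selections: list[IsoformSelection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "gene_symbol": s.gene_symbol,
                "canonical_id": s.canonical_id,
                "enriched_id": s.enriched_id,
                "canonical_mean_tpm": round(s.canonical_mean_tpm, 4),
                "enriched_mean_tpm": round(s.enriched_mean_tpm, 4),
                "has_noncanonical_enriched": s.has_noncanonical_enriched,
            }
            for s in selections
        ]
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Panel gene symbols, one per line, '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out
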
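"""Variant parsing, quality/region filtering, and evidence attachment.

Variants are read from VCF with per-carrier sequencing-quality gates
(DP > 10 and GQ > 15 in at least one carrier sample, strict thresholds)
and restricted to the 5'UTR analysis regions.  External evidence —
population allele frequencies, SpliceAI delta scores, translational-
efficiency log2 fold changes, minimum-free-energy fold changes, and
TSS/IRES interval sets — is attached from pre-computed tables keyed by
(chrom, pos, ref, alt); a variant absent from a table keeps the field
absent (None), never a fabricated zero.  Absence from every population
table is itself informative: the rarity filter treats it as a pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .errors import InputError
from .genome_model import CPosition, GenomicInterval
from .sequence_effects import UaugDiff
from .utr_regions import AnalysisRegion

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CarrierCall:
    sample: str
    genotype: str  # het | hom | hemi
    dp: int
    gq: int


@dataclass(frozen=True)
class Variant:
    """One normalized bi-allelic variant with its carrier calls."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    carriers: tuple[CarrierCall, ...] = ()

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InputError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def region_tree(regions: list[AnalysisRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, r
        )
    return trees


def overlapping_regions(
    trees: dict[str, IntervalTree], span: GenomicInterval
) -> list[AnalysisRegion]:
    tree = trees.get(span.chrom)
    if tree is None:
        return []
    hits = [iv.data for iv in tree.overlap(span.start, span.end)]
    hits.sort(key=lambda r: (r.interval.start, r.name))
    return hits


def read_region_variants(
    vcf_path: str | Path,
    regions: list[AnalysisRegion],
    dp_min: int = 10,
    gq_min: int = 15,
) -> list[Variant]:
    """Variants overlapping analysis regions with a quality-passing carrier.

    Multi-allelic records are split; a variant is retained iff DP > dp_min
    AND GQ > gq_min in at least one carrier sample (the gate is
    per-carrier, not per-site).  Records missing DP or GQ are dropped with
    a logged reason.
    """
    trees = region_tree(regions)
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    out: list[Variant] = []
    for rec in vcf:
        depths = rec.format("DP")
        quals = rec.format("GQ")
        if depths is None or quals is None:
            log.info("dropped %s:%s: missing DP/GQ FORMAT fields", rec.CHROM, rec.POS)
            continue
        for ai, alt in enumerate(rec.ALT):
            var_span = GenomicInterval(rec.CHROM, rec.POS - 1, rec.POS - 1 + len(rec.REF))
            if not overlapping_regions(trees, var_span):
                continue
            carriers = []
            for si, sample in enumerate(samples):
                gt = rec.genotypes[si]
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                if (ai + 1) not in alleles:
                    continue
                dp = int(depths[si][0])
                gq = int(quals[si][0])
                if dp < 0 or gq < 0:
                    log.info(
                        "dropped carrier %s at %s:%s: missing DP/GQ", sample, rec.CHROM, rec.POS
                    )
                    continue
                if len(alleles) == 1:
                    genotype = "hemi"
                elif all(a == ai + 1 for a in alleles):
                    genotype = "hom"
                else:
                    genotype = "het"
                carriers.append(CarrierCall(sample, genotype, dp, gq))
            passing = tuple(c for c in carriers if c.dp > dp_min and c.gq > gq_min)
            if passing:
                out.append(Variant(rec.CHROM, rec.POS, rec.REF, alt, passing))
    return out


@dataclass
class VariantAnnotations:
    """All per-variant evidence consumed by the classifier."""

    variant: Variant
    gene_symbol: str | None = None
    transcript_id: str | None = None
    max_population_af: float | None = None
    spliceai: dict[str, float] | None = None  # DS_AG, DS_DG, DS_AL, DS_DL
    te_log2fc: float | None = None
    mfe_fc: float | None = None
    overlaps_tss: bool = False
    overlaps_ires: bool = False
    sequence_events: UaugDiff | None = None
    c_position: CPosition | None = None
    within_near_splice: bool = False
    distance_to_junction: int | None = None
    cohorts: tuple[str, ...] = ()

    @property
    def key(self) -> str:
        return self.variant.key

    @property
    def max_spliceai(self) -> float | None:
        if not self.spliceai:
            return None
        return max(self.spliceai.values())


def _keyed_table(path_or_df, value_cols: list[str] | None = None) -> pd.DataFrame:
    if path_or_df is None:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, sep="\t", dtype={"chrom": str})
    )
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise InputError(f"evidence table missing columns {required - set(df.columns)}")
    df = df.dropna(subset=["chrom", "pos", "ref", "alt"])
    return df


def _lookup(df: pd.DataFrame, v: Variant) -> pd.Series | None:
    if df.empty:
        return None
    hit = df[
        (df["chrom"] == v.chrom)
        & (df["pos"] == v.pos)
        & (df["ref"] == v.ref)
        & (df["alt"] == v.alt)
    ]
    if hit.empty:
        return None
    return hit.iloc[0]


def _point_in(intervals: list[GenomicInterval] | None, chrom: str, pos0: int) -> bool:
    if not intervals:
        return False
    return any(iv.chrom == chrom and iv.contains(pos0) for iv in intervals)


def attach_evidence(
    variants: list[Variant],
    af_table=None,
    spliceai_table=None,
    te_table=None,
    mfe_table=None,
    tss_intervals: list[GenomicInterval] | None = None,
    ires_intervals: list[GenomicInterval] | None = None,
) -> list[VariantAnnotations]:
    """Attach external evidence; missing keys stay absent (None)."""
    af = _keyed_table(af_table)
    sai = _keyed_table(spliceai_table)
    te = _keyed_table(te_table)
    mfe = _keyed_table(mfe_table)
    out = []
    for v in variants:
        ann = VariantAnnotations(variant=v)
        row = _lookup(af, v)
        if row is not None:
            af_cols = [c for c in af.columns if c.startswith("af")]
            vals = [row[c] for c in af_cols if pd.notna(row[c])]
            if vals:
                ann.max_population_af = float(max(vals))
        row = _lookup(sai, v)
        if row is not None:
            ann.spliceai = {
                k: float(row[k.lower()]) for k in ("DS_AG", "DS_DG", "DS_AL", "DS_DL")
            }
        row = _lookup(te, v)
        if row is not None and pd.notna(row.get("te_log2fc")):
            ann.te_log2fc = float(row["te_log2fc"])
        row = _lookup(mfe, v)
        if row is not None and pd.notna(row.get("mfe_fc")):
            ann.mfe_fc = float(row["mfe_fc"])
        ann.overlaps_tss = _point_in(tss_intervals, v.chrom, v.pos - 1)
        ann.overlaps_ires = _point_in(ires_intervals, v.chrom, v.pos - 1)
        out.append(ann)
    return out


_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def internal_mfe_proxy(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested Watson-Crick/GU pairs (Nussinov DP).

    A fixture-only stand-in used by the synthetic generator to manufacture
    self-consistent fold-change tables; production MFE values are always
    table-supplied.  Hairpin loops shorter than ``min_loop`` are forbidden.
    """
    if len(seq) > 500:
        raise InputError("internal_mfe_proxy refuses sequences longer than 500 nt")
    s = seq.upper()
    n = len(s)
    if n == 0:
        return 0
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            if (s[i], s[j]) in _WC_PAIRS:
                best = max(best, dp[i + 1][j - 1] + 1)
            for k in range(i + 1, j + 1):
                if (s[i], s[k]) in _WC_PAIRS and k - i > min_loop:
                    inner = dp[i + 1][k - 1] + 1
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    best = max(best, inner + right)
            dp[i][j] = best
    return dp[0][n - 1]


# --- ClinVar-style table filtering -----------------------------------------

SIG_BUCKETS = {
    "pathogenic": "P/LP",
    "likely pathogenic": "P/LP",
    "pathogenic/likely pathogenic": "P/LP",
    "benign": "B/LB",
    "likely benign": "B/LB",
    "benign/likely benign": "B/LB",
    "conflicting interpretations of pathogenicity": "conflicting",
    "conflicting classifications of pathogenicity": "conflicting",
    "uncertain significance": "VUS",
}
PROTEIN_ALTERING = {
    "missense",
    "missense_variant",
    "frameshift",
    "frameshift_variant",
    "nonsense",
    "stop_gained",
    "start_lost",
    "stop_lost",
    "inframe_deletion",
    "inframe_insertion",
    "synonymous",
    "synonymous_variant",
}


def read_clinvar(path: str | Path, assembly: str = "GRCh38") -> pd.DataFrame:
    """ClinVar-style tab-delimited table, restricted to one assembly."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "assembly" in df.columns:
        df = df[df["assembly"] == assembly].reset_index(drop=True)
    return df


def filter_clinvar_utr(
    records: pd.DataFrame,
    regions: list[AnalysisRegion],
    cds_intervals: list[GenomicInterval] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Restrict ClinVar records to the 5'UTR search space.

    Retains records that overlap an analysis region, are not copy-number
    events extending into CDS, and have no protein-altering or synonymous
    consequence on the canonical transcript.  Returns the retained rows and
    a clinical-significance tally over {P/LP, B/LB, conflicting, VUS,
    other}; the buckets partition the retained set.
    """
    trees = region_tree(regions)
    keep_rows = []
    tally = {"P/LP": 0, "B/LB": 0, "conflicting": 0, "VUS": 0, "other": 0}
    for idx, row in records.iterrows():
        try:
            if pd.notna(row.get("start")):
                start = int(row["start"])
            else:
                start = int(row["pos"]) - 1
            if pd.notna(row.get("stop")):
                stop = int(row["stop"])
            else:
                stop = start + len(str(row.get("ref", "N")))
        except (KeyError, TypeError, ValueError):
            log.info("skipped malformed ClinVar row %d", idx)
            continue
        span = GenomicInterval(str(row["chrom"]), start, max(stop, start + 1))
        if not overlapping_regions(trees, span):
            continue
        vtype = str(row.get("variant_type", "")).lower()
        if "copy number" in vtype and cds_intervals:
            if any(span.overlaps(c) and span.intersection_length(c) > 0 for c in cds_intervals):
                continue
        csq = str(row.get("molecular_consequence", "")).lower().replace(" ", "_")
        if csq in PROTEIN_ALTERING:
            continue
        sig = str(row.get("clinical_significance", "")).strip().lower()
        bucket = SIG_BUCKETS.get(sig)
        if bucket is None:
            bucket = "other"
            log.info("unknown significance %r bucketed as other", sig)
        tally[bucket] += 1
        keep_rows.append(idx)
    return records.loc[keep_rows].reset_index(drop=True), tally
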
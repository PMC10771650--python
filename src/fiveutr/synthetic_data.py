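"""Synthetic reference, expression, variant, and case generation.

Every pipeline input (FASTA, GTF, TPM matrix, VCF, evidence tables,
TSS/IRES/capture BEDs, gene panel, case metadata) is generated with
planted, machine-readable ground truth so each stage is testable offline.
All outputs are deterministic functions of :class:`SimulationConfig`
(identical config => byte-identical files): every file draws from its own
pseudo-random stream derived from the master seed, so adding one output
never perturbs another.

Design notes.  Synthetic 5'UTRs are low-complexity (A/C filler) so that
planted start/stop codons are the only ones present and every variant's
intended consequence is unambiguous; the generator plants, for each of the
seven functional categories, at least one variant on the passing and one
on the failing side of its threshold, plus rarity (MAF 0.019 / 0.02 /
absent) and sequencing-quality (DP 11/10, GQ 16/15) boundary plants.
Chromosomes stay under 100 kb so whole runs finish in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify_prioritize import (
    CaseRecord,
    CaseVariantCall,
    GenePanelEntry,
)
from .errors import ConfigurationError, PlanError
from .genome_model import (
    CPosition,
    GenomicInterval,
    TranscriptModel,
    five_prime_utr,
    map_c_to_genomic,
    reverse_complement,
)
from .sequence_effects import UorfRecord, UaugDiff, ORF_OORF, ORF_UORF
from .variant_annotation import VariantAnnotations, Variant, internal_mfe_proxy

_CHROM_CAPACITY = 100_000
_GENE_GAP = 500
_N_PLANT_GENES = 22
_N_CONTROL_GENES = 4
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real study's shape: ~1/3 of genes carry spliced
    (multi-exon) 5'UTRs, ~20% of genes have a non-canonical isoform that
    tops retinal expression, and the expression matrix has 102 samples.
    """

    seed: int = 0
    n_genes: int = 60
    fraction_noncanonical_enriched: float = 0.2
    fraction_spliced_utrs: float = 1 / 3
    n_samples: int = 102
    cohorts: tuple[str, ...] = ("GE", "CMGG")
    enriched_multiplier: float = 4.0

    def __post_init__(self) -> None:
        for f in (self.fraction_noncanonical_enriched, self.fraction_spliced_utrs):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.n_genes < 1 or self.n_samples < 1:
            raise ConfigurationError("n_genes and n_samples must be positive")

    @property
    def n_spliced(self) -> int:
        return round(self.fraction_spliced_utrs * self.n_genes)

    @property
    def n_enriched(self) -> int:
        return round(self.fraction_noncanonical_enriched * self.n_genes)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _filler(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(np.array(["A", "C"]), size=n))


_SAFE_CODONS = np.array(["CAC", "CCA", "ACC", "CAA", "AAC", "CCC"])


@dataclass
class _TxSpec:
    tid: str
    exons_local: list[tuple[int, int]]
    cds_lo: int | None
    cds_hi: int | None
    canonical: bool
    biotype: str = "protein_coding"
    mane: bool = False


@dataclass
class _Plant:
    name: str
    gene_index: int
    kind: str  # snv_utr | del_utr | snv_intron
    utr_offset: int | None = None
    intron_k: int | None = None
    mrna_ref: str = ""
    mrna_alt: str = ""
    evidence: dict = field(default_factory=dict)
    carrier: tuple[str, str, int, int] = ("N1", "0/1", 30, 99)  # sample, GT, DP, GQ
    categories: dict = field(default_factory=dict)  # category -> filter pass
    rarity_pass: bool = True
    retained_at_read: bool = True
    case_id: str | None = None
    # filled at materialization:
    chrom: str = ""
    pos: int = 0  # 1-based
    ref: str = ""
    alt: str = ""

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def in_summary(self) -> bool:
        return self.retained_at_read and self.rarity_pass and any(self.categories.values())


@dataclass
class _GeneBuild:
    index: int
    gene_id: str
    symbol: str
    strand: str
    local_seq: str
    tx_specs: list[_TxSpec]
    utr_len: int
    role: str
    spliced_canonical: bool
    overlap_class: str | None = None
    expected_enriched: bool = False
    lead_exon_len: int | None = None
    intron1_seq: str = ""
    chrom: str = ""
    offset: int = 0


def _build_cds(rng: np.random.Generator, plus4: str) -> str:
    n = int(rng.integers(25, 41))
    second = ("G" if plus4 == "G" else "C") + "CC"
    body = "".join(rng.choice(_SAFE_CODONS, size=n))
    return "ATG" + second + body + "TAA"


def _main_kozak(gi: int) -> tuple[str, str]:
    # cycle strong / moderate / weak contexts for the main AUG
    return [("A", "G"), ("A", "C"), ("C", "C")][gi % 3]


def _apply_unspliced_plant(name: str, U: list[str], L: int) -> _Plant | None:
    """Plant one engineered variant (and its UTR motifs) on an unspliced gene."""
    p = _Plant(name=name, gene_index=-1, kind="snv_utr")
    if name == "uaug_gain_strong":
        o = L - 123
        U[o], U[o + 1], U[o + 2] = "A", "C", "G"
        U[o - 3], U[o + 3] = "A", "G"
        U[o + 75 : o + 78] = list("TAA")
        p.utr_offset, p.mrna_ref, p.mrna_alt = o + 1, "C", "T"
        p.categories = {"uaug_gained": True}
    elif name == "uaug_gain_weak":
        o = L - 100
        U[o], U[o + 1], U[o + 2] = "A", "C", "G"
        U[o - 3], U[o + 3] = "C", "C"
        U[o + 30 : o + 33] = list("TAA")
        p.utr_offset, p.mrna_ref, p.mrna_alt = o + 1, "C", "T"
        p.categories = {"uaug_gained": False}
    elif name == "uaug_gain_oorf":
        o = L - 40  # (L - o) % 3 == 1 -> out of frame with the CDS
        U[o], U[o + 1], U[o + 2] = "A", "C", "G"
        U[o - 3], U[o + 3] = "A", "G"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o + 1, "C", "T"
        p.categories = {"uaug_gained": True}
    elif name == "uaug_loss":
        o = L - 90
        U[o : o + 3] = list("ATG")
        U[o - 3], U[o + 3] = "A", "G"
        U[o + 30 : o + 33] = list("TAA")
        p.utr_offset, p.mrna_ref, p.mrna_alt = o + 1, "T", "C"
        p.categories = {"uorf_change": True}
    elif name == "ustop_loss":
        o = L - 90
        U[o : o + 3] = list("ATG")
        U[o + 30 : o + 33] = list("TAA")
        p.utr_offset, p.mrna_ref, p.mrna_alt = o + 30, "T", "C"
        p.categories = {"uorf_change": False}
    elif name == "uorf_frameshift":
        o = L - 93
        U[o : o + 3] = list("ATG")
        U[o + 33 : o + 36] = list("TAA")
        U[o + 9], U[o + 10], U[o + 11] = "A", "C", "A"
        p.kind = "del_utr"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o + 10, "C", ""
        p.categories = {"uorf_change": False}
    elif name.startswith("kozak_m"):
        c = int(name.removeprefix("kozak_m"))  # 6, 7 or 11
        o = L - c
        U[o] = "C"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o, "C", "A"
        if c == 6:
            p.categories = {"kozak_alteration": True}
        elif c <= 10:
            p.categories = {"kozak_alteration": False}
        else:
            p.categories = {}
    elif name in ("te_pass", "te_fail"):
        o = L - 60
        U[o] = "C"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o, "C", "A"
        fc = 0.6 if name == "te_pass" else -0.4
        p.evidence = {"te_log2fc": fc}
        p.categories = {"te_change": name == "te_pass"}
    elif name in ("mfe_pass", "mfe_fail"):
        o = L - 60
        U[o] = "C"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o, "C", "A"
        fc = 2.0 if name == "mfe_pass" else 1.2
        p.evidence = {"mfe_fc": fc}
        p.categories = {"mfe_change": name == "mfe_pass"}
    elif name in ("tss_overlap", "ires_overlap", "tss_near_miss"):
        o = L - 50
        U[o] = "C"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o, "C", "A"
        if name == "tss_overlap":
            p.evidence = {"tss": True}
            p.categories = {"tss_or_ires": True}
        elif name == "ires_overlap":
            p.evidence = {"ires": True}
            p.categories = {"tss_or_ires": True}
        else:
            p.evidence = {"tss_miss": True}
            p.categories = {}
    elif name in ("af_pass_boundary", "af_fail_boundary", "af_absent"):
        o = L - 50
        U[o] = "C"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o, "C", "A"
        p.evidence = {"mfe_fc": 2.0}
        p.categories = {"mfe_change": True}
        if name == "af_pass_boundary":
            p.evidence["af"] = 0.019
        elif name == "af_fail_boundary":
            p.evidence["af"] = 0.02
            p.rarity_pass = False
    elif name in ("dp_low", "gq_low", "dp_gq_boundary_pass"):
        o = L - 50
        U[o] = "C"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o, "C", "A"
        p.evidence = {"mfe_fc": 2.0}
        if name == "dp_low":
            p.carrier = ("N1", "0/1", 10, 99)
            p.retained_at_read = False
            p.categories = {}
        elif name == "gq_low":
            p.carrier = ("N1", "0/1", 30, 15)
            p.retained_at_read = False
            p.categories = {}
        else:
            p.carrier = ("N2", "0/1", 11, 16)
            p.categories = {"mfe_change": True}
    elif name == "multi_category":
        o = L - 50
        U[o] = "C"
        p.utr_offset, p.mrna_ref, p.mrna_alt = o, "C", "A"
        p.evidence = {"mfe_fc": 2.0, "tss": True}
        p.categories = {"mfe_change": True, "tss_or_ires": True}
    else:
        raise PlanError(f"unknown plant {name!r}")
    return p


_UNSPLICED_PLANTS = [
    "uaug_gain_strong",
    "uaug_gain_weak",
    "uaug_gain_oorf",
    "uaug_loss",
    "ustop_loss",
    "uorf_frameshift",
    "kozak_m6",
    "kozak_m7",
    "kozak_m11",
    "te_pass",
    "te_fail",
    "mfe_pass",
    "mfe_fail",
    "tss_overlap",
    "ires_overlap",
    "tss_near_miss",
    "af_pass_boundary",
    "af_fail_boundary",
    "dp_low",
    "gq_low",
    "dp_gq_boundary_pass",
    "multi_category",
]

_SPLICE_PLANTS = [
    ("splice_donor_pass", 1, {"ds_ag": 0.02, "ds_dg": 0.25, "ds_al": 0.01, "ds_dl": 0.03}),
    ("splice_low_fail", 5, {"ds_ag": 0.02, "ds_dg": 0.15, "ds_al": 0.01, "ds_dl": 0.03}),
    ("splice_outside_flank", 30, {"ds_ag": 0.02, "ds_dg": 0.30, "ds_al": 0.01, "ds_dl": 0.03}),
]

# case plan: plant name -> (case_id, cohort, pattern, sex, zygosity, other_alleles,
#                           panel modes, shared phenotype tag, expect_candidate)
_CASE_PLAN = {
    "uaug_gain_strong": ("CASE01", "GE", "sporadic", "female", "hom", 0, ("AR",), "macular-dystrophy", True),
    "kozak_m6": ("CASE02", "GE", "AD", "female", "het", 0, ("AD",), "rod-cone-dystrophy", True),
    "te_pass": ("CASE03", "GE", "sporadic", "male", "hemi", 0, ("XL",), "fevr", True),
    "uaug_gain_oorf": ("CASE04", "CMGG", "sporadic", "female", "het", 1, ("AR",), "rod-cone-dystrophy", True),
    # phenotype-mismatch decoy: MOI passes (hom, AR), tags disjoint
    "mfe_pass": ("CASE05", "CMGG", "sporadic", "female", "hom", 0, ("AR",), None, False),
    # MOI-mismatch decoy: AR-only gene in an AD-pattern family, single het
    "tss_overlap": ("CASE06", "CMGG", "AD", "female", "het", 0, ("AR",), "rod-cone-dystrophy", False),
}

_DEFAULT_TAGS = ("retinal-dystrophy", "rod-cone-dystrophy")


@dataclass
class SyntheticWorld:
    """Everything the generator knows, before serialization."""

    config: SimulationConfig
    genes: list[_GeneBuild]
    plants: list[_Plant]
    chrom_seqs: dict[str, str]
    transcripts: list[TranscriptModel]
    panel: dict[str, GenePanelEntry]
    cases: list[CaseRecord]
    samples: list[str]
    sample_cohort: dict[str, str]
    expression: "object" = None  # pandas DataFrame, filled lazily


def _gene_roles(cfg: SimulationConfig, with_plants: bool) -> list[str]:
    n = cfg.n_genes
    n_spliced, n_enriched = cfg.n_spliced, cfg.n_enriched
    if n_spliced + n_enriched > n:
        raise ConfigurationError("spliced + enriched gene fractions exceed the gene count")
    roles = ["spliced"] * n_spliced
    free = n - n_spliced - n_enriched
    if with_plants:
        if n_spliced < len(_SPLICE_PLANTS) or free < _N_PLANT_GENES:
            raise PlanError(
                "variant plan needs >= 3 spliced and >= "
                f"{_N_PLANT_GENES} unspliced non-enriched genes"
            )
    roles += ["unspliced"] * free
    n_ctrl = min(_N_CONTROL_GENES, max(0, free - (_N_PLANT_GENES if with_plants else 0)))
    for i in range(n_ctrl):
        roles[n_spliced + free - 1 - i] = "control"
    roles += ["enriched"] * n_enriched
    return roles


def build_world(cfg: SimulationConfig, with_plants: bool = True) -> SyntheticWorld:
    """Deterministically build the full synthetic study."""
    rng = _rng(cfg, 1)
    roles = _gene_roles(cfg, with_plants)
    overlap_cycle = ["fully_distinct", "partly_overlapping", "fully_overlapping"]
    genes: list[_GeneBuild] = []
    plants: list[_Plant] = []
    unspliced_seen = 0
    spliced_seen = 0
    enriched_seen = 0

    for gi, role in enumerate(roles):
        gene_id = f"GSYN{gi:04d}"
        symbol = f"SYG{gi:03d}"
        tid_c = f"TSYN{gi:04d}C"
        strand = "+" if gi % 2 == 0 else "-"
        m3, p4 = _main_kozak(gi)
        cds = _build_cds(rng, p4)
        t3 = "".join(_filler(rng, 15))

        if role in ("enriched", "control"):
            L = int(rng.integers(160, 221))
            U = _filler(rng, L)
            U[L - 3] = m3
            exon_seq = "".join(U) + cds + t3
            if role == "control":
                cls = "fully_overlapping"
            else:
                cls = overlap_cycle[enriched_seen % 3]
                enriched_seen += 1
            tid_n = f"TSYN{gi:04d}N"
            if cls == "fully_overlapping":
                local_seq = exon_seq
                can = _TxSpec(tid_c, [(0, len(exon_seq))], L, L + len(cds) - 1, True, mane=gi % 4 == 0)
                nc = _TxSpec(tid_n, [(15, len(exon_seq))], L, L + len(cds) - 1, False)
            else:
                lead = "".join(_filler(rng, 60))
                intron = "GT" + "".join(_filler(rng, 116)) + "AG"
                c0 = len(lead) + len(intron)
                local_seq = lead + intron + exon_seq
                can = _TxSpec(tid_c, [(c0, c0 + len(exon_seq))], c0 + L, c0 + L + len(cds) - 1, True, mane=gi % 4 == 0)
                if cls == "partly_overlapping":
                    nc_start = c0 + L - 40
                else:
                    nc_start = c0 + L
                nc = _TxSpec(tid_n, [(0, 60), (nc_start, c0 + len(exon_seq))], c0 + L, c0 + L + len(cds) - 1, False)
            genes.append(
                _GeneBuild(
                    index=gi, gene_id=gene_id, symbol=symbol, strand=strand,
                    local_seq=local_seq, tx_specs=[can, nc], utr_len=L, role=role,
                    spliced_canonical=False, overlap_class=cls if role == "enriched" else None,
                    expected_enriched=role == "enriched",
                )
            )
            continue

        if role == "spliced":
            n_lead = int(rng.integers(1, 3))
            lead_lens = [int(rng.integers(45, 90)) for _ in range(n_lead)]
            tail = int(rng.integers(30, 60))
            L = sum(lead_lens) + tail
            U = _filler(rng, L)
            U[L - 3] = m3
            introns = ["GT" + "".join(_filler(rng, int(rng.integers(116, 297)))) + "AG" for _ in range(n_lead)]
            plant = None
            if with_plants and spliced_seen < len(_SPLICE_PLANTS):
                name, k, ds = _SPLICE_PLANTS[spliced_seen]
                plant = _Plant(name=name, gene_index=gi, kind="snv_intron", intron_k=k,
                               evidence={"spliceai": ds})
                if name == "splice_donor_pass":
                    plant.categories = {"splicing": True}
                elif name == "splice_low_fail":
                    plant.categories = {"splicing": False}
                else:
                    plant.retained_at_read = False
                plant.mrna_ref = introns[0][k - 1]
                plant.mrna_alt = _TRANSVERSION[plant.mrna_ref]
                plants.append(plant)
            spliced_seen += 1
            parts, exons_local, cursor, upos = [], [], 0, 0
            for i, ll in enumerate(lead_lens):
                parts.append("".join(U[upos : upos + ll]))
                exons_local.append((cursor, cursor + ll))
                cursor += ll
                upos += ll
                parts.append(introns[i])
                cursor += len(introns[i])
            final = "".join(U[upos:]) + cds + t3
            parts.append(final)
            exons_local.append((cursor, cursor + len(final)))
            cds_lo = cursor + tail
            local_seq = "".join(parts)
            specs = [_TxSpec(tid_c, exons_local, cds_lo, cds_lo + len(cds) - 1, True, mane=gi % 4 == 0)]
            if gi == 3:  # one non-coding transcript, dropped at load
                specs.append(_TxSpec(f"TSYN{gi:04d}L", [exons_local[0]], None, None, False, biotype="lncRNA"))
            genes.append(
                _GeneBuild(
                    index=gi, gene_id=gene_id, symbol=symbol, strand=strand,
                    local_seq=local_seq, tx_specs=specs, utr_len=L, role=role,
                    spliced_canonical=True, lead_exon_len=lead_lens[0],
                    intron1_seq=introns[0],
                )
            )
            continue

        # unspliced gene, possibly carrying one engineered plant
        L = int(rng.integers(160, 221))
        U = _filler(rng, L)
        U[L - 3] = m3
        plant = None
        if with_plants and unspliced_seen < len(_UNSPLICED_PLANTS):
            name = _UNSPLICED_PLANTS[unspliced_seen]
            if name == "uorf_frameshift":
                strand = "+"  # indel plants stay on the plus strand
            plant = _apply_unspliced_plant(name, U, L)
            plant.gene_index = gi
            plants.append(plant)
        unspliced_seen += 1
        exon_seq = "".join(U) + cds + t3
        genes.append(
            _GeneBuild(
                index=gi, gene_id=gene_id, symbol=symbol, strand=strand,
                local_seq=exon_seq,
                tx_specs=[_TxSpec(tid_c, [(0, len(exon_seq))], L, L + len(cds) - 1, True, mane=gi % 4 == 0)],
                utr_len=L, role=role, spliced_canonical=False,
            )
        )

    # --- chromosome placement ------------------------------------------
    plant_by_gene = {p.gene_index: p for p in plants}
    xl_gene = next((p.gene_index for p in plants if p.name == "te_pass"), None)
    chrom_parts: dict[str, list[str]] = {}
    cursors: dict[str, int] = {}
    chrom_i = 1
    for g in genes:
        if g.index == xl_gene:
            chrom = "chrX"
        else:
            chrom = f"chr{chrom_i}"
            if cursors.get(chrom, 0) + len(g.local_seq) + _GENE_GAP > _CHROM_CAPACITY:
                chrom_i += 1
                chrom = f"chr{chrom_i}"
        g.chrom = chrom
        g.offset = cursors.get(chrom, 0)
        piece = g.local_seq if g.strand == "+" else reverse_complement(g.local_seq)
        chrom_parts.setdefault(chrom, []).append(piece + "C" * _GENE_GAP)
        cursors[chrom] = g.offset + len(g.local_seq) + _GENE_GAP
    chrom_seqs = {c: "".join(parts) for c, parts in chrom_parts.items()}

    # --- transcript models ---------------------------------------------
    transcripts: list[TranscriptModel] = []
    canonical_of: dict[int, TranscriptModel] = {}
    for g in genes:
        B = len(g.local_seq)
        for spec in g.tx_specs:
            if g.strand == "+":
                exons = [GenomicInterval(g.chrom, g.offset + s, g.offset + e, "+") for s, e in spec.exons_local]
                cds_start = g.offset + spec.cds_lo if spec.cds_lo is not None else None
                cds_end = g.offset + spec.cds_hi if spec.cds_hi is not None else None
            else:
                exons = [GenomicInterval(g.chrom, g.offset + B - e, g.offset + B - s, "-") for s, e in spec.exons_local]
                cds_start = g.offset + B - 1 - spec.cds_lo if spec.cds_lo is not None else None
                cds_end = g.offset + B - 1 - spec.cds_hi if spec.cds_hi is not None else None
            exons.sort(key=lambda iv: iv.start, reverse=g.strand == "-")
            if spec.biotype != "protein_coding":
                cds_start = cds_end = None
            tx = TranscriptModel(
                transcript_id=spec.tid, gene_id=g.gene_id, gene_symbol=g.symbol,
                strand=g.strand, exons=exons,
                cds_start_genomic=cds_start, cds_end_genomic=cds_end,
                biotype=spec.biotype, is_canonical=spec.canonical and spec.biotype == "protein_coding",
                is_mane=spec.mane,
            )
            transcripts.append(tx)
            if spec.canonical:
                canonical_of[g.index] = tx

    # --- materialize plants (genomic coordinates, alleles) --------------
    for p in plants:
        g = genes[p.gene_index]
        tx = canonical_of[g.index]
        if p.kind == "snv_intron":
            c_anchor = g.lead_exon_len - 1 - g.utr_len
            pos0 = map_c_to_genomic(tx, CPosition("utr5_intronic", c_anchor, p.intron_k))
        else:
            pos0 = tx.genomic_position(p.utr_offset)
        p.chrom = g.chrom
        ref_genomic = chrom_seqs[g.chrom][pos0]
        expected = p.mrna_ref if g.strand == "+" else reverse_complement(p.mrna_ref)
        assert ref_genomic == expected, f"plant {p.name}: genome/plan mismatch"
        if p.kind == "del_utr":
            anchor = pos0 - 1
            p.pos = anchor + 1
            p.ref = chrom_seqs[g.chrom][anchor : pos0 + 1]
            p.alt = chrom_seqs[g.chrom][anchor]
        else:
            p.pos = pos0 + 1
            p.ref = ref_genomic
            p.alt = p.mrna_alt if g.strand == "+" else reverse_complement(p.mrna_alt)

    # --- panel, cases, cohorts ------------------------------------------
    panel: dict[str, GenePanelEntry] = {}
    ratings = ["green", "green", "amber"]
    for g in genes:
        plan = _CASE_PLAN.get(plant_by_gene[g.index].name) if g.index in plant_by_gene else None
        if plan is not None:
            _, _, _, _, _, _, modes, tag, _ = plan
            tags = (tag,) if tag else ("syndromic-other",)
        else:
            modes, tags = ("AR",), _DEFAULT_TAGS
        panel[g.symbol] = GenePanelEntry(
            gene_symbol=g.symbol,
            inheritance_modes=frozenset(modes),
            phenotype_tags=frozenset(tags),
            rating=ratings[g.index % 3],
        )

    cases: list[CaseRecord] = []
    for p in plants:
        plan = _CASE_PLAN.get(p.name)
        if plan is None:
            continue
        case_id, cohort, pattern, sex, zyg, other, _modes, tag, expect = plan
        g = genes[p.gene_index]
        gt = {"hom": "1/1", "het": "0/1", "hemi": "1/1"}[zyg]
        p.carrier = (case_id, gt, 30, 99)
        p.case_id = case_id if expect else None
        case_tags = frozenset({tag}) if tag else frozenset({"macular-dystrophy"})
        cases.append(
            CaseRecord(
                case_id=case_id, cohort=cohort, phenotype_tags=case_tags,
                family_pattern=pattern, sex=sex,
                variants=(CaseVariantCall(p.key, g.symbol, zyg),),
                other_reported_alleles={g.symbol: other} if other else {},
            )
        )
    cases.sort(key=lambda c: c.case_id)

    samples = sorted({c.case_id for c in cases}) + ["N1", "N2"]
    sample_cohort = {c.case_id: c.cohort for c in cases}
    sample_cohort.update({"N1": cfg.cohorts[0], "N2": cfg.cohorts[0]})

    return SyntheticWorld(
        config=cfg, genes=genes, plants=plants, chrom_seqs=chrom_seqs,
        transcripts=transcripts, panel=panel, cases=cases,
        samples=samples, sample_cohort=sample_cohort,
    )


# --- serialization ----------------------------------------------------------


def _write_fasta(world: SyntheticWorld, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(world.chrom_seqs):
            fh.write(f">{chrom}\n")
            seq = world.chrom_seqs[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _gtf_attrs(**kv) -> str:
    parts = []
    for k, v in kv.items():
        if k == "tags":
            parts.extend(f'tag "{t}";' for t in v)
        else:
            parts.append(f'{k} "{v}";')
    return " ".join(parts)


def _write_gtf(world: SyntheticWorld, path: Path) -> None:
    lines = []
    for g in world.genes:
        span_lo = min(e.start for t in world.transcripts if t.gene_id == g.gene_id for e in t.exons)
        span_hi = max(e.end for t in world.transcripts if t.gene_id == g.gene_id for e in t.exons)
        base = f"{g.chrom}\tfiveutr_sim\t"
        lines.append(
            base + f"gene\t{span_lo + 1}\t{span_hi}\t.\t{g.strand}\t.\t"
            + _gtf_attrs(gene_id=g.gene_id, gene_name=g.symbol, gene_biotype="protein_coding")
        )
        for tx in (t for t in world.transcripts if t.gene_id == g.gene_id):
            tags = []
            if tx.is_canonical:
                tags.append("Ensembl_canonical")
            if tx.is_mane:
                tags.append("MANE_Select")
            attrs = dict(
                gene_id=g.gene_id, transcript_id=tx.transcript_id, gene_name=g.symbol,
                transcript_biotype=tx.biotype,
            )
            if tags:
                attrs["tags"] = tags
            tspan = tx.span
            lines.append(
                base + f"transcript\t{tspan.start + 1}\t{tspan.end}\t.\t{g.strand}\t.\t" + _gtf_attrs(**attrs)
            )
            for e in sorted(tx.exons, key=lambda iv: iv.start):
                lines.append(
                    base + f"exon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t" + _gtf_attrs(**attrs)
                )
            if tx.is_coding:
                lo = min(tx.cds_start_genomic, tx.cds_end_genomic)
                hi = max(tx.cds_start_genomic, tx.cds_end_genomic)
                lines.append(
                    base + f"CDS\t{lo + 1}\t{hi + 1}\t.\t{g.strand}\t0\t" + _gtf_attrs(**attrs)
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def generate_reference(cfg: SimulationConfig, outdir: str | Path, with_plants: bool = True) -> SyntheticWorld:
    """Write genome.fa, annotation.gtf, panel.tsv and genes.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = build_world(cfg, with_plants=with_plants)
    _write_fasta(world, outdir / "genome.fa")
    _write_gtf(world, outdir / "annotation.gtf")
    with open(outdir / "panel.tsv", "w") as fh:
        fh.write("gene_symbol\tinheritance_modes\tphenotype_tags\trating\n")
        for sym in sorted(world.panel):
            e = world.panel[sym]
            fh.write(
                f"{sym}\t{','.join(sorted(e.inheritance_modes))}"
                f"\t{','.join(sorted(e.phenotype_tags))}\t{e.rating}\n"
            )
    with open(outdir / "genes.txt", "w") as fh:
        for g in world.genes:
            fh.write(g.symbol + "\n")
    return world


def generate_expression(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write expression.tsv: log-normal TPM draws, enriched isoforms boosted."""
    import pandas as pd

    cfg = world.config
    rng = _rng(cfg, 2)
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    rows = {}
    for g in world.genes:
        base_mean = float(np.exp(rng.normal(2.0, 0.5)))
        for spec in g.tx_specs:
            if spec.biotype != "protein_coding":
                continue
            if spec.canonical:
                mean = base_mean
            elif g.role == "enriched":
                mean = base_mean * cfg.enriched_multiplier
            else:
                mean = base_mean * 0.5
            draws = mean * np.exp(rng.normal(0.0, 0.3, size=cfg.n_samples))
            rows[spec.tid] = np.round(draws, 4)
    df = pd.DataFrame(rows, index=sample_ids).T
    df.index.name = "transcript_id"
    df.to_csv(Path(outdir) / "expression.tsv", sep="\t", float_format="%.4f")
    world.expression = df


def _write_vcf(world: SyntheticWorld, path: Path) -> None:
    header = ["##fileformat=VCFv4.2"]
    for chrom in sorted(world.chrom_seqs):
        header.append(f"##contig=<ID={chrom},length={len(world.chrom_seqs[chrom])}>")
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(world.samples)
    )
    body = []
    for p in sorted(world.plants, key=lambda p: (p.chrom, p.pos, p.ref, p.alt)):
        sample_f = []
        carrier, gt, dp, gq = p.carrier
        for s in world.samples:
            if s == carrier:
                sample_f.append(f"{gt}:{dp}:{gq}")
            else:
                sample_f.append("0/0:40:99")
        body.append(
            f"{p.chrom}\t{p.pos}\t{p.name}\t{p.ref}\t{p.alt}\t100\tPASS\t.\tGT:DP:GQ\t"
            + "\t".join(sample_f)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(header + body) + "\n")


def plant_variants(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write variants.vcf, evidence tables, TSS/IRES/capture BEDs and truth.json."""
    outdir = Path(outdir)
    _write_vcf(world, outdir / "variants.vcf")

    def keyrow(p: _Plant) -> str:
        return f"{p.chrom}\t{p.pos}\t{p.ref}\t{p.alt}"

    with open(outdir / "af.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf_popmax\n")
        for p in world.plants:
            if "af" in p.evidence:
                fh.write(f"{keyrow(p)}\t{p.evidence['af']:.6f}\n")
    with open(outdir / "spliceai.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tds_ag\tds_dg\tds_al\tds_dl\n")
        for p in world.plants:
            ds = p.evidence.get("spliceai")
            if ds:
                fh.write(
                    f"{keyrow(p)}\t{ds['ds_ag']:.2f}\t{ds['ds_dg']:.2f}"
                    f"\t{ds['ds_al']:.2f}\t{ds['ds_dl']:.2f}\n"
                )
    with open(outdir / "te.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tte_log2fc\n")
        for p in world.plants:
            if "te_log2fc" in p.evidence:
                fh.write(f"{keyrow(p)}\t{p.evidence['te_log2fc']:.3f}\n")
    with open(outdir / "mfe.tsv", "w") as fh:
        # proxy pairing scores over a +-30 nt window document self-consistency
        fh.write("chrom\tpos\tref\talt\tmfe_fc\tproxy_pairs_ref\tproxy_pairs_alt\n")
        for p in world.plants:
            if "mfe_fc" in p.evidence:
                seq = world.chrom_seqs[p.chrom]
                lo, hi = max(0, p.pos - 31), p.pos + 30
                ref_win = seq[lo:hi]
                alt_win = seq[lo : p.pos - 1] + p.alt + seq[p.pos - 1 + len(p.ref) : hi]
                fh.write(
                    f"{keyrow(p)}\t{p.evidence['mfe_fc']:.3f}"
                    f"\t{internal_mfe_proxy(ref_win)}\t{internal_mfe_proxy(alt_win)}\n"
                )
    tss, ires = [], []
    for p in world.plants:
        pos0 = p.pos - 1
        if p.evidence.get("tss"):
            tss.append((p.chrom, pos0 - 10, pos0 + 10))
        if p.evidence.get("tss_miss"):  # near-miss: interval ends 10 bp short
            tss.append((p.chrom, pos0 - 20, pos0 - 10))
        if p.evidence.get("ires"):
            ires.append((p.chrom, pos0 - 10, pos0 + 10))
    for name, rows in (("tss.bed", tss), ("ires.bed", ires)):
        with open(outdir / name, "w") as fh:
            for chrom, s, e in sorted(rows):
                fh.write(f"{chrom}\t{s}\t{e}\n")

    # capture designs: broad covers every 5'UTR exon; sparse covers only the
    # CDS-proximal 40 bp of each canonical 5'UTR
    broad, sparse = [], []
    for tx in world.transcripts:
        if not tx.is_coding or not tx.is_canonical:
            continue
        utr = five_prime_utr(tx)
        for iv in utr:
            broad.append((iv.chrom, iv.start, iv.end))
        last = utr[-1]  # CDS-proximal piece in transcript order
        if tx.strand == "+":
            sparse.append((last.chrom, max(last.start, last.end - 40), last.end))
        else:
            sparse.append((last.chrom, last.start, min(last.end, last.start + 40)))
    for name, rows in (("capture_broad.bed", broad), ("capture_sparse.bed", sparse)):
        with open(outdir / name, "w") as fh:
            for chrom, s, e in sorted(rows):
                fh.write(f"{chrom}\t{s}\t{e}\n")

    truth = {
        "genes": {
            g.symbol: {
                "canonical_id": next(s.tid for s in g.tx_specs if s.canonical),
                "noncanonical_id": next((s.tid for s in g.tx_specs if not s.canonical and s.biotype == "protein_coding"), None),
                "expected_enriched": g.expected_enriched,
                "overlap_class": g.overlap_class,
                "spliced_canonical_utr": g.spliced_canonical,
            }
            for g in world.genes
        },
        "variants": {
            p.key: {
                "plant": p.name,
                "gene": world.genes[p.gene_index].symbol,
                "categories": sorted(p.categories),
                "filter_pass": p.categories,
                "rarity_pass": p.rarity_pass,
                "retained_at_read": p.retained_at_read,
                "in_summary": p.in_summary,
                "case": p.case_id,
            }
            for p in world.plants
        },
        "expected_candidates": sorted(p.key for p in world.plants if p.case_id),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def generate_cases(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write cases.tsv and cohorts.tsv."""
    outdir = Path(outdir)
    with open(outdir / "cases.tsv", "w") as fh:
        fh.write(
            "case_id\tcohort\tphenotype_tags\tfamily_pattern\tsex\tsolved_status"
            "\talternative_diagnosis\tvariants\tother_alleles\n"
        )
        for c in world.cases:
            vs = ";".join(f"{v.variant_key}|{v.gene_symbol}|{v.zygosity}" for v in c.variants)
            oa = ";".join(f"{g}:{n}" for g, n in sorted(c.other_reported_alleles.items()))
            fh.write(
                f"{c.case_id}\t{c.cohort}\t{','.join(sorted(c.phenotype_tags))}"
                f"\t{c.family_pattern}\t{c.sex}\t{c.solved_status}"
                f"\t{int(c.alternative_diagnosis)}\t{vs}\t{oa}\n"
            )
    with open(outdir / "cohorts.tsv", "w") as fh:
        fh.write("sample\tcohort\n")
        for s in world.samples:
            fh.write(f"{s}\t{world.sample_cohort[s]}\n")


def generate_all(cfg: SimulationConfig, outdir: str | Path) -> SyntheticWorld:
    """Write the complete synthetic study into ``outdir``."""
    outdir = Path(outdir)
    world = generate_reference(cfg, outdir)
    generate_expression(world, outdir)
    plant_variants(world, outdir)
    generate_cases(world, outdir)
    return world


# --- published-cohort replica fixture ---------------------------------------


def _gained(orf_type: str, kozak: str, peptide: int | None) -> UaugDiff:
    rec = UorfRecord(
        start_offset=0, start_c=-123, frame_vs_cds="in_frame" if orf_type == ORF_UORF else "out_of_frame",
        stop_c=-46 if orf_type == ORF_UORF else None, orf_type=orf_type,
        kozak=kozak, peptide_length_aa=peptide,
    )
    return UaugDiff(gained=[rec], events=["uaug_gain"])


def table2_replica():
    """The published candidate set as an in-memory fixture.

    Encodes each prioritized variant with its printed gene, functional
    category evidence, MAF, zygosity, family inheritance pattern, and a
    panel entry granting the gene its printed mode of inheritance and
    phenotype; running the real annotation->classification->prioritization
    gates over it reproduces the published candidate list.

    Returns (annotations, cases, panel).
    """

    def ann(chrom, pos, ref, alt, **kv):
        v = Variant(chrom, pos, ref, alt)
        return VariantAnnotations(variant=v, **kv)

    sai = lambda x: {"DS_AG": 0.02, "DS_DG": x, "DS_AL": 0.01, "DS_DL": x}
    rows = [
        # (annotations, gene, case_id, cohort, tags, pattern, sex, zygosity,
        #  other_alleles, modes, alt_diagnosis)
        (ann("chr14", 67722520, "C", "T", max_population_af=0.00008544,
             c_position=CPosition("utr5", -123),
             sequence_events=_gained(ORF_UORF, "strong", 25)),
         "RDH12", "F1", "GE", "macular-dystrophy", "sporadic", "female", "het", 2, ("AR",), False),
        (ann("chr1", 5986310, "G", "A", max_population_af=0.00001972,
             c_position=CPosition("utr5", -21),
             sequence_events=_gained(ORF_OORF, "strong", None)),
         "NPHP4", "F2", "GE", "rod-cone-dystrophy", "sporadic", "female", "het", 1, ("AR",), False),
        (ann("chr1", 9943515, "G", "A", c_position=CPosition("utr5", -57),
             spliceai=sai(0.85), within_near_splice=True, distance_to_junction=3),
         "NMNAT1", "F3", "GE", "macular-dystrophy", "sporadic", "female", "het", 1, ("AR",), False),
        (ann("chr19", 54115798, "G", "A",
             c_position=CPosition("utr5_intronic", -9, 1),
             spliceai=sai(0.95), within_near_splice=True, distance_to_junction=1),
         "PRPF31", "F4", "GE", "lca-eosrd", "AD", "female", "het", 0, ("AD",), False),
        (ann("chr19", 54115798, "G", "T",
             c_position=CPosition("utr5_intronic", -9, 1),
             spliceai=sai(0.95), within_near_splice=True, distance_to_junction=1),
         "PRPF31", "F5", "GE", "rod-cone-dystrophy", "sporadic", "female", "het", 0, ("AD",), False),
        (ann("chrX", 43958715, "C", "T", c_position=CPosition("utr5", -70),
             spliceai=sai(0.50), within_near_splice=True, distance_to_junction=20),
         "NDP", "F6", "GE", "fevr", "sporadic", "male", "hemi", 0, ("XL",), False),
        (ann("chr1", 211492150, "C", "T", c_position=CPosition("utr5", -394),
             mfe_fc=1.8, overlaps_tss=True),
         "RD3", "F7", "GE", "rod-cone-dystrophy", "sporadic", "female", "hom", 0, ("AR",), False),
        (ann("chr2", 111898611, "G", "A", max_population_af=0.00002632,
             c_position=CPosition("utr5", -125), mfe_fc=1.8, overlaps_tss=True),
         "MERTK", "F8", "GE", "lca-eosrd", "sporadic", "female", "hom", 0, ("AR",), False),
        (ann("chr11", 31806455, "A", "G", c_position=CPosition("utr5", -44), mfe_fc=1.9),
         "PAX6", "F9", "GE", "cone-dysfunction", "AD", "female", "het", 0, ("AD",), False),
        (ann("chr10", 102714363, "C", "T", c_position=CPosition("utr5", -88), mfe_fc=1.7),
         "ARL3", "F10", "CMGG", "retinal-dystrophy", "AR", "female", "het", 0, ("AD", "AR"), False),
        (ann("chr9", 113275738, "C", "T", c_position=CPosition("utr5", -6)),
         "PRPF4", "F11", "CMGG", "rod-cone-dystrophy", "sporadic", "female", "het", 0, ("AD",), True),
    ]
    annotations, cases, panel = [], [], {}
    for a, gene, case_id, cohort, tag, pattern, sex, zyg, other, modes, alt_dx in rows:
        a.gene_symbol = gene
        a.cohorts = (cohort,)
        annotations.append(a)
        existing = panel.get(gene)
        tags = frozenset({tag}) | (existing.phenotype_tags if existing else frozenset())
        panel[gene] = GenePanelEntry(gene, frozenset(modes), tags, "green")
        cases.append(
            CaseRecord(
                case_id=case_id, cohort=cohort, phenotype_tags=frozenset({tag}),
                family_pattern=pattern, sex=sex,
                variants=(CaseVariantCall(a.key, gene, zyg),),
                other_reported_alleles={gene: other} if other else {},
                alternative_diagnosis=alt_dx,
            )
        )
    return annotations, cases, panel
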
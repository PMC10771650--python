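"""End-to-end workflow: select -> regions -> (coverage) -> annotate ->
classify -> prioritize.

Each output table carries a header with the tool version, a hash of the
configuration, and the classifier thresholds, so a run is reproducible
from its outputs alone; re-running an identical configuration reproduces
byte-identical file bodies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify_prioritize import (
    CategoryAssignment,
    ClassifierConfig,
    candidate_table,
    categorize,
    prioritize,
    read_cases,
    read_panel,
    summarize,
)
from .errors import ConfigurationError
from .genome_model import (
    GenomeAnnotation,
    load_annotation,
    map_genomic_to_c,
    read_bed,
    reverse_complement,
)
from .isoform_selection import (
    mean_abundance,
    read_expression,
    read_gene_list,
    select_isoforms,
    selection_table,
)
from .sequence_effects import UtrContext, UtrVariant, apply_variant, diff_uaug_events, left_normalize
from .utr_regions import (
    CaptureDesign,
    build_analysis_regions,
    capture_coverage,
    gene_utr_unions,
    write_regions_bed,
)
from .variant_annotation import (
    Variant,
    VariantAnnotations,
    attach_evidence,
    overlapping_regions,
    read_region_variants,
    region_tree,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    gtf: str
    fasta: str
    expression: str
    gene_list: str
    vcf: str
    panel: str
    cases: str
    outdir: str
    af_table: str | None = None
    spliceai_table: str | None = None
    te_table: str | None = None
    mfe_table: str | None = None
    tss_bed: str | None = None
    ires_bed: str | None = None
    capture_beds: tuple[str, ...] = ()
    capture_padding: int = 0
    cohorts_table: str | None = None  # sample -> cohort map
    flank_bp: int = 25
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def validate(self) -> None:
        for name in ("gtf", "fasta", "expression", "gene_list", "vcf", "panel", "cases"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")

    def hash(self) -> str:
        payload = json.dumps(
            {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in dataclasses.asdict(self).items()
                if k != "outdir"
            },
            sort_keys=True,
            default=sorted,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def annotate_sequence_effects(
    ann: GenomeAnnotation,
    annotations: list[VariantAnnotations],
    regions,
    flank_bp: int = 25,
) -> None:
    """Fill c-position, near-splice geometry and uAUG diff events in place.

    Each variant is interpreted against the first selected transcript whose
    analysis regions it overlaps (region hits are deduplicated by
    position).  SNV and simple indel consequences are computed on the
    spliced 5'UTR; indels on minus-strand transcripts keep their positional
    annotation but skip the sequence diff.
    """
    trees = region_tree(regions)
    for va in annotations:
        v = va.variant
        hits = overlapping_regions(trees, v.span)
        if not hits:
            continue
        region = hits[0]
        tx = ann[region.transcript_id]
        va.gene_symbol = region.gene_symbol
        va.transcript_id = tx.transcript_id
        pos0 = v.pos - 1
        try:
            cpos = map_genomic_to_c(tx, pos0, flank=flank_bp + 10)
        except Exception:
            continue
        va.c_position = cpos
        utr_introns = [i for i in tx.introns()]
        if cpos.kind == "utr5_intronic":
            va.distance_to_junction = abs(cpos.intron_offset)
            va.within_near_splice = va.distance_to_junction <= flank_bp
        elif cpos.kind == "utr5" and utr_introns:
            ti = tx.transcript_index(pos0)
            edges = []
            for i, e in enumerate(tx.exons):
                last = tx.transcript_index(e.start if tx.strand == "-" else e.end - 1)
                first = tx.transcript_index(e.end - 1 if tx.strand == "-" else e.start)
                if i > 0:
                    edges.append(first)
                if i < len(tx.exons) - 1:
                    edges.append(last)
            if edges:
                va.distance_to_junction = min(abs(ti - e) + 1 for e in edges)
                va.within_near_splice = va.distance_to_junction <= flank_bp
        if cpos.kind != "utr5":
            continue
        # sequence-level diff on the spliced 5'UTR
        utr_seq = ann.spliced_utr_sequence(tx)
        cds_seq = ann.cds_sequence(tx)
        ctx = UtrContext(utr_seq, cds_seq, tx.transcript_id)
        L = len(utr_seq)
        offset = L + cpos.c_offset
        ref, alt = v.ref, v.alt
        shared = 0
        while shared < min(len(ref), len(alt)) and ref[shared] == alt[shared] and len(ref) != len(alt):
            shared += 1
        if shared:
            ref, alt = ref[shared:], alt[shared:]
        if tx.strand == "-":
            if len(v.ref) != 1 or len(v.alt) != 1:
                continue  # minus-strand indels: positional annotation only
            ref, alt = reverse_complement(ref), reverse_complement(alt)
            moffset = offset
        else:
            moffset = offset + shared
        if moffset < 0 or moffset + len(ref) > L:
            continue  # edit runs out of the 5'UTR
        try:
            uv = UtrVariant(moffset, ref, alt)
            uv = left_normalize(utr_seq, uv) if uv.length_delta else uv
            alt_ctx = apply_variant(ctx, uv)
            va.sequence_events = diff_uaug_events(ctx, alt_ctx, uv)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("sequence diff failed for %s on %s: %s", v.key, tx.transcript_id, exc)


@dataclass
class PipelineResult:
    selections: list
    regions: list
    coverage: list
    annotations: list[VariantAnnotations]
    assignments: dict[str, CategoryAssignment]
    summary: pd.DataFrame
    candidates: list


def _write_table(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the output bundle into ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cc = config.classifier
    header = [
        f"fiveutr {__version__}",
        f"config_hash {config.hash()}",
        (
            f"thresholds maf<{cc.maf_max} spliceai>{cc.spliceai_min} "
            f"near_splice<={cc.near_splice_bp} |te|>={cc.te_abs_log2fc_min} "
            f"|mfe|>={cc.mfe_abs_fc_min} kozak_positions="
            f"{sorted(cc.kozak_prioritized_positions)}"
        ),
    ]

    annotation = load_annotation(config.gtf, config.fasta)
    genes = read_gene_list(config.gene_list)
    means = mean_abundance(read_expression(config.expression))
    selections = select_isoforms(annotation, means, genes)
    _write_table(selection_table(selections), outdir / "selection.tsv", header)

    selected_txs = [annotation[tid] for s in selections for tid in s.retained_ids]
    regions = build_analysis_regions(selected_txs, flank_bp=config.flank_bp)
    write_regions_bed(regions, outdir / "regions.bed")

    coverage = []
    if config.capture_beds:
        unions = gene_utr_unions(
            annotation, {s.gene_symbol: s.retained_ids for s in selections}
        )
        frames = []
        for bed in config.capture_beds:
            design = CaptureDesign.from_bed(bed, padding_bp=config.capture_padding)
            rep = capture_coverage(unions, design)
            coverage.append(rep)
            df = rep.per_gene.copy()
            df.insert(0, "design", rep.design)
            frames.append(df)
        cov_header = header + [f"utr_union_rule {coverage[0].union_rule}"]
        _write_table(pd.concat(frames, ignore_index=True), outdir / "coverage.tsv", cov_header)

    variants = read_region_variants(config.vcf, regions)
    annotations = attach_evidence(
        variants,
        af_table=config.af_table,
        spliceai_table=config.spliceai_table,
        te_table=config.te_table,
        mfe_table=config.mfe_table,
        tss_intervals=read_bed(config.tss_bed) if config.tss_bed else None,
        ires_intervals=read_bed(config.ires_bed) if config.ires_bed else None,
    )
    if config.spliceai_table is None:
        log.warning("no SpliceAI table supplied; splicing category will be unpopulated")
    annotate_sequence_effects(annotation, annotations, regions, flank_bp=config.flank_bp)

    # cohort attribution from carrier samples
    cohort_of_sample = {}
    if config.cohorts_table:
        cdf = pd.read_csv(config.cohorts_table, sep="\t")
        cohort_of_sample = dict(zip(cdf["sample"], cdf["cohort"]))
    for va in annotations:
        cos = sorted({cohort_of_sample.get(c.sample, "GE") for c in va.variant.carriers})
        va.cohorts = tuple(cos)

    assignments = {va.key: categorize(va, cc) for va in annotations}
    ann_rows = []
    for va in annotations:
        a = assignments[va.key]
        ann_rows.append(
            {
                "variant_key": va.key,
                "gene_symbol": va.gene_symbol,
                "c_position": str(va.c_position) if va.c_position else "",
                "max_population_af": va.max_population_af,
                "max_spliceai": va.max_spliceai,
                "te_log2fc": va.te_log2fc,
                "mfe_fc": va.mfe_fc,
                "overlaps_tss": va.overlaps_tss,
                "overlaps_ires": va.overlaps_ires,
                "categories": ";".join(sorted(a.categories)),
                "passing": ";".join(sorted(a.passing)),
                "rarity_pass": a.rarity_pass,
            }
        )
    _write_table(pd.DataFrame(ann_rows), outdir / "annotated.tsv", header)

    cohort_names = tuple(
        pd.unique(pd.read_csv(config.cohorts_table, sep="\t")["cohort"]).tolist()
    ) if config.cohorts_table else ("GE",)
    summary = summarize(list(assignments.values()), cohort_names=cohort_names)
    _write_table(summary, outdir / "summary.tsv", header)

    panel = read_panel(config.panel)
    cases = read_cases(config.cases)
    candidates = prioritize(cases, assignments, panel, cc)
    _write_table(candidate_table(candidates), outdir / "candidates.tsv", header)

    return PipelineResult(
        selections=selections,
        regions=regions,
        coverage=coverage,
        annotations=annotations,
        assignments=assignments,
        summary=summary,
        candidates=candidates,
    )
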
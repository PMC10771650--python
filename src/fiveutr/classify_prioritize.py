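"""Functional-category classification and MOI/phenotype prioritization.

An annotated 5'UTR variant is assigned to up to seven (non-mutually
exclusive) categories, each with its own filter:

1. ``uaug_gained``       -- a variant-created uAUG; passes when the new
   AUG sits in a strong or moderate Kozak context.
2. ``uorf_change``       -- perturbation of an existing uORF; passes on
   natural uAUG loss (stop loss and frameshifts are held but fail).
3. ``kozak_alteration``  -- exonic position within -10..-1 of the main
   AUG; passes at the high-information positions {-3,-4,-5,-6,-9}.
4. ``splicing``          -- within +-25 bp of an intron-exon boundary;
   passes when any SpliceAI delta score exceeds 0.2 (strict).
5. ``te_change``         -- predicted translational-efficiency change;
   passes at |log2FC| >= 0.5 (~1.5-fold).
6. ``mfe_change``        -- secondary-structure minimum-free-energy
   change; passes at |FC| >= 1.5.
7. ``tss_or_ires``       -- overlaps a transcription start site or an
   internal ribosome entry site.

A rarity gate (MAF < 2% in all populations; absence from every reference
database passes) precedes the category filters.  Candidates must
additionally match the family's mode of inheritance and the proband's
phenotype against the gene panel.  Variants at intronic near-splice
positions are eligible only for the splicing category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConsistencyError
from .variant_annotation import VariantAnnotations

CATEGORIES = (
    "uaug_gained",
    "uorf_change",
    "kozak_alteration",
    "splicing",
    "te_change",
    "mfe_change",
    "tss_or_ires",
)

CATEGORY_LABELS = {
    "uaug_gained": "uAUG gained",
    "uorf_change": "Change in existing uORF",
    "kozak_alteration": "Alteration of classical or retinal primary Kozak context",
    "splicing": "Splicing",
    "te_change": "Change in translational efficiency",
    "mfe_change": "Change in secondary structure minimum free energy",
    "tss_or_ires": "Overlapping a retinal transcription start site or an IRES",
}


@dataclass(frozen=True)
class ClassifierConfig:
    maf_max: float = 0.02
    spliceai_min: float = 0.2
    near_splice_bp: int = 25
    te_abs_log2fc_min: float = 0.5
    mfe_abs_fc_min: float = 1.5
    kozak_prioritized_positions: frozenset[int] = frozenset({-3, -4, -5, -6, -9})
    kozak_window: tuple[int, int] = (-10, -1)
    uaug_kozak_allowed: frozenset[str] = frozenset({"strong", "moderate"})
    # Reporting-only consensus strings; the Kozak filter itself is positional.
    classical_kozak_consensus: str = "GCCGCCACCATGG"
    retinal_kozak_consensus: str = ""

    def __post_init__(self) -> None:
        if not (self.maf_max > 0 and self.spliceai_min > 0 and self.near_splice_bp > 0):
            raise ValueError("thresholds must be positive")
        if not set(self.kozak_prioritized_positions) <= set(
            range(self.kozak_window[0], self.kozak_window[1] + 1)
        ):
            raise ValueError("prioritized positions must lie inside the Kozak window")


@dataclass
class CategoryAssignment:
    variant_key: str
    gene_symbol: str | None
    categories: set[str] = field(default_factory=set)
    filter_pass: dict[str, bool] = field(default_factory=dict)
    cohorts: tuple[str, ...] = ()
    rarity_pass: bool = True

    @property
    def multi_category(self) -> bool:
        return len(self.categories) > 1

    @property
    def passing(self) -> set[str]:
        return {c for c in self.categories if self.filter_pass.get(c)}


def rarity_filter(ann: VariantAnnotations, config: ClassifierConfig = ClassifierConfig()) -> bool:
    """MAF < maf_max in all populations; absent AF passes (strict <)."""
    return ann.max_population_af is None or ann.max_population_af < config.maf_max


def categorize(
    ann: VariantAnnotations, config: ClassifierConfig = ClassifierConfig()
) -> CategoryAssignment:
    """Evidence-driven category assignment with per-category filter flags."""
    asg = CategoryAssignment(
        variant_key=ann.key,
        gene_symbol=ann.gene_symbol,
        cohorts=ann.cohorts,
        rarity_pass=rarity_filter(ann, config),
    )
    intronic = ann.c_position is not None and ann.c_position.kind == "utr5_intronic"

    def hold(cat: str, passes: bool) -> None:
        asg.categories.add(cat)
        asg.filter_pass[cat] = passes

    if not intronic:
        ev = ann.sequence_events
        if ev is not None and ev.gained:
            hold(
                "uaug_gained",
                any(g.kozak in config.uaug_kozak_allowed for g in ev.gained),
            )
        if ev is not None and (
            ev.lost or any(e in ("ustop_loss", "uframe_shift") for e in ev.events)
        ):
            hold("uorf_change", bool(ev.lost))
        if ann.c_position is not None and ann.c_position.kind == "utr5":
            c = ann.c_position.c_offset
            lo, hi = config.kozak_window
            if lo <= c <= hi:
                hold("kozak_alteration", c in config.kozak_prioritized_positions)
        if ann.te_log2fc is not None:
            hold("te_change", abs(ann.te_log2fc) >= config.te_abs_log2fc_min)
        if ann.mfe_fc is not None:
            hold("mfe_change", abs(ann.mfe_fc) >= config.mfe_abs_fc_min)
        if ann.overlaps_tss or ann.overlaps_ires:
            hold("tss_or_ires", True)
    if (
        ann.spliceai is not None
        and ann.within_near_splice
        and ann.distance_to_junction is not None
        and ann.distance_to_junction <= config.near_splice_bp
    ):
        hold("splicing", (ann.max_spliceai or 0.0) > config.spliceai_min)
    return asg


# --- Table-1 style summary --------------------------------------------------


def summarize(
    assignments: list[CategoryAssignment], cohort_names: tuple[str, ...] = ("GE", "CMGG")
) -> pd.DataFrame:
    """Category summary over variants surviving rarity + >=1 passing filter.

    Single-category rows count variants whose passing set is exactly that
    category; variants passing more than one category fall into the
    '> 1 category' row.  The percent column is 100 * row total / grand
    total, rounded to 2 decimals, and the rows partition the total.
    """
    counts: dict[str, dict[str, int]] = {
        c: {n: 0 for n in cohort_names} for c in CATEGORIES
    }
    counts["> 1 category"] = {n: 0 for n in cohort_names}
    for a in assignments:
        if not a.rarity_pass or not a.passing:
            continue
        row = next(iter(a.passing)) if len(a.passing) == 1 else "> 1 category"
        cohorts = a.cohorts or (cohort_names[0],)
        seen = set()
        for co in cohorts:
            if co in counts[row] and co not in seen:
                counts[row][co] += 1
                seen.add(co)
    table = {
        (CATEGORY_LABELS.get(row, row)): per for row, per in counts.items()
    }
    return summary_from_counts(table, cohort_names)


def summary_from_counts(
    counts: dict[str, dict[str, int]], cohort_names: tuple[str, ...] = ("GE", "CMGG")
) -> pd.DataFrame:
    """Render per-cohort category counts as the summary table.

    ``counts`` maps row label -> {cohort -> count}.  Adds Total and
    percent columns (percent of the grand total, 2 decimals) plus a final
    Total row.
    """
    rows = []
    grand = sum(sum(per.values()) for per in counts.values())
    for label, per in counts.items():
        total = sum(per.values())
        rows.append(
            {
                "category": label,
                **{n: per.get(n, 0) for n in cohort_names},
                "total": total,
                "percent": round(100.0 * total / grand, 2) if grand else 0.0,
            }
        )
    rows.append(
        {
            "category": "Total",
            **{n: sum(per.get(n, 0) for per in counts.values()) for n in cohort_names},
            "total": grand,
            "percent": round(100.0, 2) if grand else 0.0,
        }
    )
    return pd.DataFrame(rows)


def percent_of(numerator: int, denominator: int) -> int:
    """Whole-percent report formatter (e.g. 233/378 -> 62)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round(100.0 * numerator / denominator)


# --- MOI / phenotype prioritization ----------------------------------------


@dataclass(frozen=True)
class GenePanelEntry:
    gene_symbol: str
    inheritance_modes: frozenset[str]  # subset of {AD, AR, XL}
    phenotype_tags: frozenset[str]
    rating: str = "green"  # green | amber | red

    def __post_init__(self) -> None:
        if not self.inheritance_modes:
            raise ValueError(f"{self.gene_symbol}: at least one inheritance mode required")
        if self.rating not in ("green", "amber", "red"):
            raise ValueError(f"{self.gene_symbol}: bad rating {self.rating!r}")


@dataclass(frozen=True)
class CaseVariantCall:
    variant_key: str
    gene_symbol: str
    zygosity: str  # het | hom | hemi


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    cohort: str
    phenotype_tags: frozenset[str]
    family_pattern: str  # AD | AR | XL | sporadic
    sex: str  # male | female
    variants: tuple[CaseVariantCall, ...]
    other_reported_alleles: dict[str, int] = field(default_factory=dict)
    solved_status: str = "unsolved"
    alternative_diagnosis: bool = False


def moi_compatible(
    case: CaseRecord,
    gene: GenePanelEntry | None,
    zygosity: str,
    other_alleles: int = 0,
) -> tuple[bool, str]:
    """Mode-of-inheritance gate; sporadic cases are compatible with all modes.

    AD: heterozygous in an AD-pattern or sporadic case.  AR: homozygous,
    or heterozygous with >=1 additional rare allele in the same gene, in
    an AR-pattern or sporadic case.  XL: hemizygous male or heterozygous
    female in an XL-pattern or sporadic case.  For genes carrying both AD
    and AR modes, a heterozygote in an AR-pattern family is accepted under
    the dominant model (reduced penetrance cannot be excluded).  A family
    pattern excludes genes restricted to the opposite mode.
    """
    if gene is None:
        return False, "not on panel"
    pat = case.family_pattern
    modes = gene.inheritance_modes
    reasons = []
    if "AD" in modes:
        if pat in ("AD", "sporadic") and zygosity in ("het", "hom"):
            return True, f"AD gene, {zygosity} in {pat} case"
        if pat == "AR" and zygosity == "het" and "AR" in modes:
            return True, "dual AD/AR gene, het under dominant model (reduced penetrance)"
        reasons.append("AD mode incompatible")
    if "AR" in modes:
        if pat in ("AR", "sporadic"):
            if zygosity == "hom":
                return True, f"AR gene, homozygous in {pat} case"
            if zygosity == "het" and other_alleles >= 1:
                return True, f"AR gene, het with {other_alleles} additional rare allele(s)"
            reasons.append("AR mode: single het allele")
        else:
            reasons.append("AR mode incompatible with family pattern")
    if "XL" in modes:
        if pat in ("XL", "sporadic"):
            if zygosity == "hemi" and case.sex == "male":
                return True, f"XL gene, hemizygous male in {pat} case"
            if zygosity in ("het", "hom") and case.sex == "female":
                return True, f"XL gene, {zygosity} female in {pat} case"
            reasons.append("XL mode: zygosity/sex incompatible")
        else:
            reasons.append("XL mode incompatible with family pattern")
    return False, "; ".join(reasons) or "no compatible mode"


@dataclass
class CandidateVariant:
    variant_key: str
    gene_symbol: str
    case_id: str
    categories: tuple[str, ...]
    rationale: tuple[str, ...]
    panel_rating: str
    segregation_note: str = ""
    screen_warning: bool = False


def prioritize(
    cases: list[CaseRecord],
    assignments: dict[str, CategoryAssignment],
    panel: dict[str, GenePanelEntry],
    config: ClassifierConfig = ClassifierConfig(),
) -> list[CandidateVariant]:
    """Candidate 5'UTR variants: rarity AND >=1 passing category AND MOI
    AND phenotype compatibility.

    Candidates found in cases flagged with an alternative diagnosis are
    still emitted, carrying a screen warning, mirroring the follow-up
    screen for alternative molecular diagnoses.
    """
    out: list[CandidateVariant] = []
    for case in cases:
        for call in case.variants:
            asg = assignments.get(call.variant_key)
            if asg is None:
                raise ConsistencyError(
                    f"case {case.case_id} references unknown variant {call.variant_key}"
                )
            if not asg.rarity_pass:
                continue
            passing = asg.passing
            if not passing:
                continue
            entry = panel.get(call.gene_symbol)
            ok, moi_reason = moi_compatible(
                case,
                entry,
                call.zygosity,
                case.other_reported_alleles.get(call.gene_symbol, 0),
            )
            if not ok:
                continue
            if not (case.phenotype_tags & entry.phenotype_tags):
                continue
            out.append(
                CandidateVariant(
                    variant_key=call.variant_key,
                    gene_symbol=call.gene_symbol,
                    case_id=case.case_id,
                    categories=tuple(sorted(passing)),
                    rationale=(
                        f"rarity pass (MAF<{config.maf_max})",
                        f"categories: {', '.join(sorted(passing))}",
                        moi_reason,
                        f"phenotype overlap: {', '.join(sorted(case.phenotype_tags & entry.phenotype_tags))}",
                        f"panel rating: {entry.rating}",
                    ),
                    panel_rating=entry.rating,
                    screen_warning=case.alternative_diagnosis,
                )
            )
    out.sort(key=lambda c: (c.case_id, c.gene_symbol, c.variant_key))
    return out


def read_panel(path) -> dict[str, GenePanelEntry]:
    """Panel TSV: gene_symbol, inheritance_modes, phenotype_tags, rating."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[row["gene_symbol"]] = GenePanelEntry(
            gene_symbol=row["gene_symbol"],
            inheritance_modes=frozenset(str(row["inheritance_modes"]).split(",")),
            phenotype_tags=frozenset(str(row["phenotype_tags"]).split(",")),
            rating=row["rating"],
        )
    return out


def read_cases(path) -> list[CaseRecord]:
    """Case TSV with `variants` as key|gene|zygosity triples ';'-joined."""
    df = pd.read_csv(path, sep="\t", dtype={"alternative_diagnosis": int})
    cases = []
    for _, row in df.iterrows():
        calls = []
        for item in str(row["variants"]).split(";"):
            if not item:
                continue
            key, gene, zyg = item.rsplit("|", 2)
            calls.append(CaseVariantCall(key, gene, zyg))
        other = {}
        if pd.notna(row.get("other_alleles")) and str(row.get("other_alleles")):
            for item in str(row["other_alleles"]).split(";"):
                gene, n = item.split(":")
                other[gene] = int(n)
        cases.append(
            CaseRecord(
                case_id=row["case_id"],
                cohort=row["cohort"],
                phenotype_tags=frozenset(str(row["phenotype_tags"]).split(",")),
                family_pattern=row["family_pattern"],
                sex=row["sex"],
                variants=tuple(calls),
                other_reported_alleles=other,
                solved_status=row.get("solved_status", "unsolved"),
                alternative_diagnosis=bool(row["alternative_diagnosis"]),
            )
        )
    return cases


def candidate_table(candidates: list[CandidateVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "gene_symbol": c.gene_symbol,
                "variant_key": c.variant_key,
                "categories": ";".join(c.categories),
                "panel_rating": c.panel_rating,
                "screen_warning": c.screen_warning,
                "rationale": " | ".join(c.rationale),
            }
            for c in candidates
        ]
    )
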
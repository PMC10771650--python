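"""Category assignment, filters, summary arithmetic, and prioritization."""

import pytest

from fiveutr.classify_prioritize import (
    CaseRecord,
    CaseVariantCall,
    CATEGORIES,
    ClassifierConfig,
    GenePanelEntry,
    categorize,
    moi_compatible,
    percent_of,
    prioritize,
    rarity_filter,
    summarize,
    summary_from_counts,
)
from fiveutr.errors import ConsistencyError
from fiveutr.genome_model import CPosition
from fiveutr.sequence_effects import ORF_UORF, UaugDiff, UorfRecord
from fiveutr.synthetic_data import table2_replica
from fiveutr.variant_annotation import Variant, VariantAnnotations


def ann(**kw):
    v = kw.pop("variant", Variant("chr1", 100, "C", "T"))
    return VariantAnnotations(variant=v, **kw)


def gained(kozak="strong"):
    rec = UorfRecord(0, -100, "in_frame", -25, ORF_UORF, kozak, 25)
    return UaugDiff(gained=[rec], events=["uaug_gain"])


class TestCategorize:
    def test_gained_uaug_strong_kozak_passes(self):
        a = categorize(ann(sequence_events=gained("strong"), c_position=CPosition("utr5", -123)))
        assert a.categories == {"uaug_gained"}
        assert a.filter_pass["uaug_gained"]

    def test_gained_uaug_weak_kozak_fails_filter(self):
        a = categorize(ann(sequence_events=gained("weak")))
        assert a.categories == {"uaug_gained"}
        assert not a.filter_pass["uaug_gained"]

    @pytest.mark.parametrize("ds, expected", [(0.25, True), (0.20, False)])
    def test_spliceai_boundary_is_strict(self, ds, expected):
        a = categorize(
            ann(
                c_position=CPosition("utr5_intronic", -9, 1),
                spliceai={"DS_AG": 0.0, "DS_DG": ds, "DS_AL": 0.0, "DS_DL": 0.0},
                within_near_splice=True,
                distance_to_junction=1,
            )
        )
        assert a.categories == {"splicing"}
        assert a.filter_pass["splicing"] == expected

    def test_multi_category(self):
        a = categorize(ann(mfe_fc=2.0, overlaps_tss=True, c_position=CPosition("utr5", -50)))
        assert a.categories == {"mfe_change", "tss_or_ires"}
        assert a.multi_category

    def test_intronic_positions_only_eligible_for_splicing(self):
        a = categorize(
            ann(
                c_position=CPosition("utr5_intronic", -9, 5),
                mfe_fc=3.0,
                te_log2fc=2.0,
                overlaps_tss=True,
                spliceai={"DS_AG": 0.9, "DS_DG": 0.0, "DS_AL": 0.0, "DS_DL": 0.0},
                within_near_splice=True,
                distance_to_junction=5,
            )
        )
        assert a.categories == {"splicing"}

    def test_kozak_window_positions(self):
        a6 = categorize(ann(c_position=CPosition("utr5", -6)))
        a7 = categorize(ann(c_position=CPosition("utr5", -7)))
        a11 = categorize(ann(c_position=CPosition("utr5", -11)))
        assert a6.filter_pass["kozak_alteration"] is True
        assert a7.filter_pass["kozak_alteration"] is False
        assert "kozak_alteration" not in a11.categories

    def test_absent_evidence_withholds_category(self):
        a = categorize(ann(c_position=CPosition("utr5", -50)))
        assert a.categories == set()


class TestRarity:
    @pytest.mark.parametrize(
        "af, expected", [(0.019, True), (0.02, False), (None, True), (0.5, False)]
    )
    def test_boundaries(self, af, expected):
        assert rarity_filter(ann(max_population_af=af)) == expected


class TestSummary:
    def test_reported_count_table_percent_column(self):
        """Feeding the published per-cohort category counts reproduces the
        published percent column."""
        counts = {
            "uAUG gained": {"GE": 30, "CMGG": 5},
            "Change in existing uORF": {"GE": 17, "CMGG": 1},
            "Alteration of classical or retinal primary Kozak context": {"GE": 16, "CMGG": 7},
            "Splicing": {"GE": 29, "CMGG": 10},
            "Change in translational efficiency": {"GE": 1, "CMGG": 0},
            "Change in secondary structure minimum free energy": {"GE": 194, "CMGG": 43},
            "Overlapping a retinal transcription start site or an IRES": {"GE": 692, "CMGG": 69},
            "> 1 category": {"GE": 276, "CMGG": 60},
        }
        df = summary_from_counts(counts)
        assert df[df.category == "Total"]["total"].item() == 1450
        got = df[df.category != "Total"]["percent"].tolist()
        assert got == [2.41, 1.24, 1.59, 2.69, 0.07, 16.34, 52.48, 23.17]
        assert sum(got) == pytest.approx(100.0, abs=0.05)

    def test_single_variant_single_category(self):
        a = categorize(ann(mfe_fc=2.0, c_position=CPosition("utr5", -50)))
        a.cohorts = ("GE",)
        df = summarize([a])
        row = df[df.category.str.contains("minimum free energy")].iloc[0]
        assert row["percent"] == 100.0 and row["GE"] == 1

    def test_partition_identity(self, pipeline_result):
        """Single-category rows + multi row partition the grand total."""
        df = pipeline_result.summary
        body = df[df.category != "Total"]
        total = df[df.category == "Total"]
        assert body["total"].sum() == total["total"].item()
        for cohort in ("GE", "CMGG"):
            assert body[cohort].sum() == total[cohort].item()
        assert body["percent"].sum() == pytest.approx(100.0, abs=0.05)

    @pytest.mark.parametrize(
        "num, den, expected", [(233, 378, 62), (126, 378, 33), (904, 1547, 58)]
    )
    def test_whole_percent_formatter(self, num, den, expected):
        assert percent_of(num, den) == expected


def case(pattern="sporadic", sex="female", tags=("rcd",), **kw):
    defaults = dict(
        case_id="C", cohort="GE", phenotype_tags=frozenset(tags),
        family_pattern=pattern, sex=sex, variants=(),
    )
    defaults.update(kw)
    return CaseRecord(**defaults)


def panel_entry(modes=("AR",), tags=("rcd",)):
    return GenePanelEntry("G", frozenset(modes), frozenset(tags))


class TestMoi:
    def test_sporadic_ar_hom_passes(self):
        ok, why = moi_compatible(case(), panel_entry(("AR",)), "hom")
        assert ok and "homozygous" in why

    def test_ad_het_in_ad_family_passes(self):
        ok, _ = moi_compatible(case(pattern="AD"), panel_entry(("AD",)), "het")
        assert ok

    def test_sporadic_male_hemi_xl_passes(self):
        ok, _ = moi_compatible(case(sex="male"), panel_entry(("XL",)), "hemi")
        assert ok

    def test_ar_het_needs_second_allele(self):
        ok, why = moi_compatible(case(), panel_entry(("AR",)), "het", other_alleles=0)
        assert not ok and "single het" in why
        ok, _ = moi_compatible(case(), panel_entry(("AR",)), "het", other_alleles=1)
        assert ok

    def test_family_pattern_excludes_opposite_mode(self):
        ok, _ = moi_compatible(case(pattern="AD"), panel_entry(("AR",)), "hom")
        assert not ok
        ok, _ = moi_compatible(case(pattern="AR"), panel_entry(("AD",)), "het")
        assert not ok

    def test_dual_ad_ar_gene_het_in_ar_family_passes(self):
        ok, why = moi_compatible(case(pattern="AR"), panel_entry(("AD", "AR")), "het")
        assert ok and "dominant model" in why

    def test_gene_off_panel_fails(self):
        ok, why = moi_compatible(case(), None, "hom")
        assert not ok and why == "not on panel"


class TestPrioritize:
    def test_replica_candidate_set(self):
        """The published-cohort replica yields 11 candidates in 10 genes,
        4 of them in the splicing category."""
        annotations, cases, panel = table2_replica()
        assignments = {a.key: categorize(a) for a in annotations}
        candidates = prioritize(cases, assignments, panel)
        assert len(candidates) == 11
        assert len({c.gene_symbol for c in candidates}) == 10
        assert sum("splicing" in c.categories for c in candidates) == 4

    def test_phenotype_mismatch_excluded(self):
        annotations, cases, panel = table2_replica()
        assignments = {a.key: categorize(a) for a in annotations}
        bad_cases = [
            CaseRecord(
                c.case_id, c.cohort, frozenset({"unrelated-phenotype"}),
                c.family_pattern, c.sex, c.variants, c.other_reported_alleles,
            )
            for c in cases
        ]
        assert prioritize(bad_cases, assignments, panel) == []

    def test_gates_are_monotone(self):
        """Widening any gate never removes a candidate."""
        annotations, cases, panel = table2_replica()
        assignments = {a.key: categorize(a) for a in annotations}
        base = {c.variant_key for c in prioritize(cases, assignments, panel)}
        all_tags = frozenset().union(*(e.phenotype_tags for e in panel.values()), {"x"})
        wide_panel = {
            g: GenePanelEntry(g, frozenset({"AD", "AR", "XL"}), all_tags, e.rating)
            for g, e in panel.items()
        }
        wide = {c.variant_key for c in prioritize(cases, assignments, wide_panel)}
        assert base <= wide

    def test_order_invariance(self):
        annotations, cases, panel = table2_replica()
        assignments = {a.key: categorize(a) for a in annotations}
        a = prioritize(cases, assignments, panel)
        b = prioritize(list(reversed(cases)), assignments, panel)
        assert [c.variant_key for c in a] == [c.variant_key for c in b]

    def test_unknown_variant_reference_is_error(self):
        c = case(variants=(CaseVariantCall("chr9:1:A:T", "G", "het"),))
        with pytest.raises(ConsistencyError):
            prioritize([c], {}, {"G": panel_entry()})

    def test_screen_warning_for_alternative_diagnosis(self):
        annotations, cases, panel = table2_replica()
        assignments = {a.key: categorize(a) for a in annotations}
        candidates = prioritize(cases, assignments, panel)
        flagged = [c for c in candidates if c.screen_warning]
        assert [c.case_id for c in flagged] == ["F11"]
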
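"""uORF scanning, Kozak assessment, and variant diffing."""

import numpy as np
import pytest

from conftest import brute_force_uorfs
from fiveutr.sequence_effects import (
    ORF_EXTENSION,
    ORF_OORF,
    ORF_UORF,
    UtrContext,
    UtrVariant,
    apply_variant,
    diff_uaug_events,
    kozak_alteration,
    kozak_frequency_matrix,
    kozak_strength,
    left_normalize,
    scan_uorfs,
)

CDS = "ATG" + "GCC" * 12 + "TAA"


class TestScanUorfs:
    def test_inframe_extension(self):
        # uAUG at offset 1; remaining UTR codons GTG ACC hold no stop and the
        # frame matches the CDS -> N-terminal extension
        ctx = UtrContext("CATGGTGACC", CDS)
        (rec,) = scan_uorfs(ctx)
        assert rec.start_offset == 1
        assert rec.orf_type == ORF_EXTENSION

    def test_uorf_with_25_codon_peptide(self):
        # stop codon 75 nt downstream of the uAUG, still in the UTR:
        # 25-amino-acid peptide including the initiator Met
        utr = "CC" + "ATG" + "GCA" * 24 + "TAA" + "CCCC"
        ctx = UtrContext(utr, CDS)
        (rec,) = scan_uorfs(ctx)
        assert rec.orf_type == ORF_UORF
        assert rec.peptide_length_aa == 25
        assert rec.stop_c == (2 + 75 + 2) - len(utr)

    def test_out_of_frame_overlapping_cds(self):
        utr = "CCCC" + "ATG" + "CACCA"  # (len - 4) % 3 != 0, no UTR stop
        ctx = UtrContext(utr, CDS)
        (rec,) = scan_uorfs(ctx)
        assert rec.frame_vs_cds == "out_of_frame"
        assert rec.orf_type == ORF_OORF

    def test_ambiguous_codon_excluded_from_typing(self):
        ctx = UtrContext("CCATGCNACC", CDS)
        (rec,) = scan_uorfs(ctx)
        assert rec.ambiguous and rec.orf_type is None

    def test_matches_brute_force_oracle_on_random_sequences(self):
        """Scanner == independent enumerator on 1,000 random 5'UTRs."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(0, 301))
            gc = rng.uniform(0.3, 0.7)
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            utr = "".join(rng.choice(list("ACGT"), size=n, p=p))
            ctx = UtrContext(utr, CDS)
            got = [(r.start_offset, r.orf_type) for r in scan_uorfs(ctx)]
            assert got == brute_force_uorfs(ctx)

    def test_peptide_length_is_stop_offset_over_three(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            utr = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 200))))
            for r in scan_uorfs(UtrContext(utr, CDS)):
                if r.orf_type == ORF_UORF:
                    stop_first = r.stop_c + len(utr) - 2
                    assert r.peptide_length_aa == (stop_first - r.start_offset) // 3


class TestKozak:
    @pytest.mark.parametrize(
        "utr, cds, expected",
        [
            ("GCCACC", "ATGG" + CDS[4:], "strong"),    # -3 A, +4 G
            ("GCCCCC", "ATGG" + CDS[4:], "moderate"),  # -3 C, +4 G
            ("GCCCCC", "ATGT" + CDS[4:], "weak"),      # -3 C, +4 T
            ("GCCACC", "ATGT" + CDS[4:], "moderate"),  # -3 A, +4 T
        ],
    )
    def test_two_feature_rule(self, utr, cds, expected):
        ctx = UtrContext(utr, cds)
        assert kozak_strength(ctx, len(utr)).strength == expected

    def test_truncated_context_counts_as_nonmatching(self):
        ctx = UtrContext("AT", "ATGG" + CDS[4:])  # no -3 base available
        k = kozak_strength(ctx, 2)
        assert k.minus3_base == "?" and k.strength == "moderate"

    @pytest.mark.parametrize(
        "cpos, in_window, prioritized",
        [(-6, True, True), (-7, True, False), (-11, False, False), (-1, True, False), (-9, True, True)],
    )
    def test_positional_window_flags(self, cpos, in_window, prioritized):
        k = kozak_alteration(cpos)
        assert k.in_classical_window == in_window
        assert k.prioritized_position == prioritized

    def test_frequency_matrix_identical_sequences(self):
        ctx = UtrContext("ACGTACGTAC", CDS)
        m = kozak_frequency_matrix([ctx, ctx])
        assert (m.max(axis=0) == 1.0).all()
        assert np.allclose(m.sum(axis=0), 1.0)

    def test_frequency_matrix_half_half(self):
        a = UtrContext("A" * 10, CDS)
        c = UtrContext("C" * 10, CDS)
        m = kozak_frequency_matrix([a, c])
        assert m.loc["A", -5] == 0.5 and m.loc["C", -5] == 0.5

    def test_frequency_matrix_matches_direct_tally(self):
        rng = np.random.default_rng(11)
        ctxs = [
            UtrContext("".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 30)))), CDS)
            for _ in range(50)
        ]
        m = kozak_frequency_matrix(ctxs)
        # independent tally at position -2 and +4
        for pos in (-2, 4):
            counts = {b: 0 for b in "ACGTN"}
            for ctx in ctxs:
                if pos < 0 and len(ctx.utr_seq) >= -pos:
                    counts[ctx.utr_seq[pos]] += 1
                elif pos > 0:
                    counts[ctx.cds_seq[pos - 1]] += 1
            total = sum(counts.values())
            for b in "ACGT":
                assert m.loc[b, pos] == pytest.approx(counts[b] / total)


class TestDiff:
    def test_uaug_gain_with_downstream_stop(self):
        # single-base substitution creates an AUG in strong Kozak context,
        # in frame with a stop codon whose first base lies 75 nt downstream
        L = 150
        U = ["A" if i % 7 == 0 else "C" for i in range(L)]
        p = L - 123
        U[p], U[p + 1], U[p + 2] = "A", "C", "G"
        U[p - 3], U[p + 3] = "A", "G"
        U[p + 75 : p + 78] = list("TAA")
        ref = UtrContext("".join(U), CDS)
        var = UtrVariant(p + 1, "C", "T")
        d = diff_uaug_events(ref, apply_variant(ref, var), var)
        (g,) = d.gained
        assert g.orf_type == ORF_UORF
        assert g.kozak == "strong"
        assert g.peptide_length_aa == 25
        assert g.start_c == -123

    def test_no_change_yields_no_events(self):
        ref = UtrContext("CCACCACCACC", CDS)
        var = UtrVariant(2, "A", "C")  # no ATG/stop content change
        d = diff_uaug_events(ref, apply_variant(ref, var), var)
        assert d.is_empty

    def test_uaug_loss(self):
        U = list("CCC" + "ATG" + "CAC" * 5 + "TAA" + "CCC")
        ref = UtrContext("".join(U), CDS)
        var = UtrVariant(4, "T", "C")
        d = diff_uaug_events(ref, apply_variant(ref, var), var)
        assert [r.start_offset for r in d.lost] == [3]
        assert "uaug_loss" in d.events and not d.gained

    def test_ustop_loss(self):
        utr = "CCC" + "ATG" + "CAC" * 5 + "TAA" + "CCC"
        ref = UtrContext(utr, CDS)
        var = UtrVariant(utr.index("TAA", 6), "T", "C")
        d = diff_uaug_events(ref, apply_variant(ref, var), var)
        assert "ustop_loss" in d.events and not d.lost and not d.gained

    def test_frameshift_in_existing_uorf(self):
        utr = "CCC" + "ATG" + "CACCAC" + "TAA" + "CCC"
        ref = UtrContext(utr, CDS)
        var = left_normalize(utr, UtrVariant(8, "C", ""))
        d = diff_uaug_events(ref, apply_variant(ref, var), var)
        assert "uframe_shift" in d.events

    def test_reverse_variant_restores_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            utr = "".join(rng.choice(list("ACGT"), size=60))
            ref = UtrContext(utr, CDS)
            off = int(rng.integers(0, 60))
            alt_base = {"A": "G", "C": "T", "G": "A", "T": "C"}[utr[off]]
            var = UtrVariant(off, utr[off], alt_base)
            alt = apply_variant(ref, var)
            back = apply_variant(alt, UtrVariant(off, alt_base, utr[off]))
            assert back.utr_seq == ref.utr_seq
            d = diff_uaug_events(ref, alt, var)
            gained = {r.start_offset for r in d.gained}
            lost = {r.start_offset for r in d.lost}
            assert not (gained & lost)

    def test_variant_outside_utr_rejected(self):
        ref = UtrContext("CCCC", CDS)
        from fiveutr.errors import ContractViolation

        with pytest.raises(ContractViolation):
            apply_variant(ref, UtrVariant(10, "C", "A"))
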
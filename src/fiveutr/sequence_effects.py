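"""Sequence-level 5'UTR consequence annotation.

Everything here operates on a :class:`UtrContext`: the spliced 5'UTR
sequence (mRNA sense, DNA alphabet) plus enough downstream CDS to type
uORFs that overlap the coding sequence.  The scanner finds every uAUG,
follows its frame into the CDS to locate the first stop codon, and types
the resulting ORF:

* ``uorf_stop_in_utr``      -- stop codon entirely within the 5'UTR;
* ``oorf_out_of_frame_overlapping_cds`` -- no 5'UTR stop, frame differs
  from the main ORF;
* ``inframe_cds_extension`` -- no 5'UTR stop, same frame as the main ORF
  (translation would extend the N-terminus).

Kozak strength uses the two-feature rule: a purine at -3 and a G at +4
(positions numbered with the A of AUG as +1) give *strong*; exactly one of
the two gives *moderate*; neither gives *weak*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractViolation, InputError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
ORF_UORF = "uorf_stop_in_utr"
ORF_OORF = "oorf_out_of_frame_overlapping_cds"
ORF_EXTENSION = "inframe_cds_extension"


@dataclass(frozen=True)
class UtrContext:
    """Spliced 5'UTR + downstream CDS for one transcript."""

    utr_seq: str
    cds_seq: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if not self.cds_seq.upper().startswith("ATG"):
            raise ContractViolation(f"{self.transcript_id}: cds_seq must start with ATG")
        bad = set(self.utr_seq.upper() + self.cds_seq.upper()) - set("ACGTN")
        if bad:
            raise ContractViolation(f"{self.transcript_id}: bad alphabet {sorted(bad)}")

    @property
    def full(self) -> str:
        return (self.utr_seq + self.cds_seq).upper()


@dataclass(frozen=True)
class KozakAssessment:
    aug_pos: int  # offset of the A within utr_seq (or len(utr) for main AUG)
    strength: str  # strong | moderate | weak
    minus3_base: str  # '?' when outside the available sequence
    plus4_base: str
    in_classical_window: bool = False
    prioritized_position: bool = False


@dataclass(frozen=True)
class UorfRecord:
    """One uAUG and the ORF it initiates."""

    start_offset: int  # 0-based offset of the A within utr_seq
    start_c: int  # c. position of the uAUG (negative)
    frame_vs_cds: str  # in_frame | out_of_frame
    stop_c: int | None  # c. position of the LAST stop-codon base, if found
    orf_type: str | None  # None when ambiguous
    kozak: str
    peptide_length_aa: int | None  # initiator Met included
    ambiguous: bool = False  # an N interrupted the codon walk


def kozak_strength(ctx: UtrContext, aug_offset: int) -> KozakAssessment:
    """Strength of the Kozak context around an ATG at ``aug_offset``.

    ``aug_offset`` indexes into ``utr_seq + cds_seq``; bases at -3/+4 that
    fall outside the available sequence count as non-matching ('?').
    """
    s = ctx.full
    if s[aug_offset : aug_offset + 3] != "ATG":
        raise ContractViolation(f"no ATG at offset {aug_offset}")
    m3 = s[aug_offset - 3] if aug_offset >= 3 else "?"
    p4 = s[aug_offset + 3] if aug_offset + 3 < len(s) else "?"
    hits = (m3 in "AG") + (p4 == "G")
    strength = {2: "strong", 1: "moderate", 0: "weak"}[hits]
    return KozakAssessment(aug_pos=aug_offset, strength=strength, minus3_base=m3, plus4_base=p4)


def scan_uorfs(ctx: UtrContext) -> list[UorfRecord]:
    """All uAUG-initiated ORFs in the 5'UTR, fully typed.

    Every ATG lying entirely within ``utr_seq`` yields one record; the stop
    search continues into ``cds_seq``.  A stop codon straddling the
    UTR/CDS junction does not count as a 5'UTR stop, so such ORFs are typed
    by frame alone.
    """
    s = ctx.full
    L = len(ctx.utr_seq)
    records: list[UorfRecord] = []
    for i in range(L - 2):
        if s[i : i + 3] != "ATG":
            continue
        frame = "in_frame" if (L - i) % 3 == 0 else "out_of_frame"
        koz = kozak_strength(ctx, i).strength
        stop_j = None
        ambiguous = False
        j = i
        while j + 3 <= len(s):
            codon = s[j : j + 3]
            if "N" in codon:
                ambiguous = True
                break
            if codon in STOP_CODONS:
                stop_j = j
                break
            j += 3
        if ambiguous:
            records.append(
                UorfRecord(i, i - L, frame, None, None, koz, None, ambiguous=True)
            )
            continue
        stop_c = None
        peptide = None
        if stop_j is not None:
            last = stop_j + 2
            stop_c = last - L if last < L else last - L + 1
            peptide = (stop_j - i) // 3
        if stop_j is not None and stop_j + 2 < L:
            orf_type = ORF_UORF
        elif frame == "out_of_frame":
            orf_type = ORF_OORF
        else:
            orf_type = ORF_EXTENSION
        records.append(UorfRecord(i, i - L, frame, stop_c, orf_type, koz, peptide))
    return records


@dataclass(frozen=True)
class UtrVariant:
    """A variant expressed in spliced-5'UTR coordinates (mRNA sense)."""

    offset: int  # 0-based offset of the first ref base within utr_seq
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ContractViolation("ref == alt")

    @property
    def length_delta(self) -> int:
        return len(self.alt) - len(self.ref)


def left_normalize(utr_seq: str, variant: UtrVariant) -> UtrVariant:
    """Shift an indel left while flanking context permits (VCF-style)."""
    off, ref, alt = variant.offset, variant.ref.upper(), variant.alt.upper()
    seq = utr_seq.upper()
    if seq[off : off + len(ref)] != ref:
        raise ContractViolation("variant ref does not match utr_seq")
    while (
        off > 0
        and len(ref) != len(alt)
        and ref
        and alt
        and ref[-1] == alt[-1]
    ):
        off -= 1
        prev = seq[off]
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
    return UtrVariant(off, ref, alt)


def apply_variant(ctx: UtrContext, variant: UtrVariant) -> UtrContext:
    """Return the context with the variant applied to the 5'UTR sequence."""
    seq = ctx.utr_seq.upper()
    off = variant.offset
    if not (0 <= off and off + len(variant.ref) <= len(seq)):
        raise ContractViolation("variant outside utr_seq span")
    if seq[off : off + len(variant.ref)] != variant.ref.upper():
        raise ContractViolation(
            f"ref mismatch at {off}: expected {variant.ref}, "
            f"found {seq[off : off + len(variant.ref)]}"
        )
    alt_seq = seq[:off] + variant.alt.upper() + seq[off + len(variant.ref) :]
    return UtrContext(alt_seq, ctx.cds_seq, ctx.transcript_id)


EVENT_UAUG_GAIN = "uaug_gain"
EVENT_UAUG_LOSS = "uaug_loss"
EVENT_USTOP_LOSS = "ustop_loss"
EVENT_UFRAME_SHIFT = "uframe_shift"


@dataclass
class UaugDiff:
    """Events produced by diffing ref vs alt uORF scans."""

    gained: list[UorfRecord] = field(default_factory=list)
    lost: list[UorfRecord] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (self.gained or self.lost or self.events)


def diff_uaug_events(ctx_ref: UtrContext, ctx_alt: UtrContext, variant: UtrVariant) -> UaugDiff:
    """Compare ref and alt uORF scans around an applied variant.

    ``ctx_alt`` must equal ``ctx_ref`` with ``variant`` applied (indels
    should be left-normalized first).  Offsets downstream of an indel are
    shifted by its length delta before matching ref and alt records.
    """
    ref_records = scan_uorfs(ctx_ref)
    alt_records = scan_uorfs(ctx_alt)
    delta = variant.length_delta
    edit_lo = variant.offset
    edit_hi = variant.offset + len(variant.ref)

    def map_offset(o: int) -> int | None:
        if o < edit_lo:
            return o
        if o >= edit_hi:
            return o + delta
        return o if delta == 0 and len(variant.ref) == 1 else None

    alt_by_offset = {r.start_offset: r for r in alt_records}
    mapped = {}
    for r in ref_records:
        mo = map_offset(r.start_offset)
        mapped[r.start_offset] = alt_by_offset.get(mo) if mo is not None else None
    matched_alt_offsets = {a.start_offset for a in mapped.values() if a is not None}

    diff = UaugDiff()
    for a in alt_records:
        if a.start_offset not in matched_alt_offsets:
            diff.gained.append(a)
            diff.events.append(EVENT_UAUG_GAIN)
    for r in ref_records:
        if mapped[r.start_offset] is None:
            diff.lost.append(r)
            diff.events.append(EVENT_UAUG_LOSS)
    for r in ref_records:
        a = mapped[r.start_offset]
        if a is not None and r.orf_type == ORF_UORF and a.orf_type != ORF_UORF:
            diff.events.append(EVENT_USTOP_LOSS)
    if delta % 3 != 0:
        for r in ref_records:
            end = (
                r.stop_c + len(ctx_ref.utr_seq) + 1
                if r.stop_c is not None and r.stop_c < 0
                else len(ctx_ref.utr_seq)
            )
            if r.start_offset < edit_hi and edit_lo < end:
                diff.events.append(EVENT_UFRAME_SHIFT)
                break
    return diff


def kozak_alteration(
    variant_c_pos: int,
    window: tuple[int, int] = (-10, -1),
    prioritized: frozenset[int] = frozenset({-3, -4, -5, -6, -9}),
) -> KozakAssessment:
    """Positional main-AUG Kozak flags for an exonic 5'UTR c. position."""
    in_window = window[0] <= variant_c_pos <= window[1]
    return KozakAssessment(
        aug_pos=variant_c_pos,
        strength="n/a",
        minus3_base="?",
        plus4_base="?",
        in_classical_window=in_window,
        prioritized_position=in_window and variant_c_pos in prioritized,
    )


def kozak_frequency_matrix(contexts: list[UtrContext]) -> pd.DataFrame:
    """Per-position nucleotide frequencies over the -10..+4 Kozak window.

    Columns are HGVS-style positions (-10..-1, then +1..+4 over the AUG and
    the following base); transcripts with short 5'UTRs contribute only to
    the columns they cover.  Each column sums to 1.
    """
    if not contexts:
        raise InputError("empty transcript set")
    positions = list(range(-10, 0)) + list(range(1, 5))
    counts = {p: {b: 0 for b in "ACGTN"} for p in positions}
    for ctx in contexts:
        utr = ctx.utr_seq.upper()
        cds = ctx.cds_seq.upper()
        for p in positions:
            if p < 0:
                if len(utr) >= -p:
                    counts[p][utr[p]] += 1
            else:
                if len(cds) >= p:
                    counts[p][cds[p - 1]] += 1
    freq = pd.DataFrame(counts, columns=positions, index=list("ACGTN"), dtype=float)
    totals = freq.sum(axis=0)
    if (totals == 0).any():
        raise InputError("a Kozak window column received no contributions")
    return freq / totals
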
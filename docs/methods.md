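# Methods

## Coordinate model

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
VCF (1-based) convert at the I/O boundary. A transcript stores exons in
5'→3' order along its strand; the CDS start is the genomic position of the
first base of the main AUG (on the minus strand, the highest-coordinate
base of the codon). HGVS-style c. numbering has no position 0: c.-1 is the
base immediately 5' of the A of AUG. Intronic bases inside 5'UTR introns
are numbered from the nearer exon edge (c.-N+k from the donor, c.-N-k from
the acceptor); at the exact midpoint of an odd-length intron the donor side
wins. The mapping is exactly invertible, and the test suite checks the
genomic → c. → genomic round trip over every base of every synthetic
transcript, plus invariance under mirroring the genome (reverse-complement
with flipped strands). Introns wholly inside the CDS and positions upstream
of the transcription start are outside the supported c. range and raise.

Only protein-coding transcripts are modeled; others are dropped at load
with a logged count. Either an `Ensembl_canonical` or a `MANE_Select` GTF
tag marks a transcript canonical (the annotation does not promise which of
the two will be present, so the loader accepts either and records which it
saw).

## Isoform selection

Per-transcript abundance is the plain arithmetic mean of TPM over all
samples — no filtering, transformation, or outlier handling. Per gene the
canonical transcript is always kept; the top-mean protein-coding transcript
is additionally kept when it is non-canonical, giving at most two isoforms
per gene. Ties at identical means resolve to the canonical transcript, and
among non-canonical ties to the lexicographically smallest id, so the
selection is deterministic and invariant to sample order.

5'UTR overlap between the canonical and enriched isoform is the length of
the genomic intersection of the two 5'UTR interval sets. "Fully
overlapping" is interpreted as containment of the shorter 5'UTR in the
longer; zero shared bases is "fully distinct"; everything else is "partly
overlapping". The boundary between "partly" and "fully" when neither UTR
contains the other is genuinely underdetermined; containment is this
package's choice and is applied uniformly.

## Analysis regions and capture audit

The variant search space is: every 5'UTR exon, plus a donor and an acceptor
flank of 25 intronic bp (configurable) at every splice junction whose two
flanking exonic bases are both 5'UTR. No flank is emitted upstream of the
transcription start — that is the whole extent of "excluding the promoter";
no separate promoter model exists. Flanks are clipped to their intron, so
no emitted base can be CDS (checked as a test invariant). Overlapping
regions from the two isoforms of one gene are both emitted with their
transcript identity; variant lookup deduplicates by position.

Capture coverage uses the per-gene genomic union of the selected (≤2)
transcripts' 5'UTR exons as denominator (the union rule is stated in the
report header, since per-gene audits could equally use the canonical UTR
only). Near-splice flanks are excluded from the denominator: the audit is
of 5'UTRs, the flanks exist only for variant search. Bait padding is
applied symmetrically per interval before intersection; coverage is
monotone in both padding and bait count by construction.

## Sequence-level 5'UTR effects

The uORF scanner examines every ATG lying wholly within the spliced 5'UTR
and walks codons — continuing into the CDS — to the first stop (TAA, TAG,
TGA; standard table). Typing: stop entirely within the UTR → uORF; no UTR
stop, frame different from the CDS → out-of-frame overlapping oORF; no UTR
stop, same frame → in-frame N-terminal extension. A stop codon straddling
the UTR/CDS junction is not a UTR stop, so such ORFs type by frame. Peptide
length includes the initiator Met and equals the nucleotide distance from
uAUG to stop divided by three. Overlapping uORFs are all reported; there is
no greedy 5'-most suppression. An N inside a walked codon flags the record
ambiguous and excludes it from typing. Near-cognate starts (CUG/GUG) are
out of scope.

Kozak strength is the standard two-feature rule on −3 and +4 (A of AUG =
+1): purine at −3 and G at +4 → strong, exactly one → moderate, neither →
weak; a position outside the available sequence counts as non-matching. The
positional Kozak-alteration filter for the main AUG (window −10..−1,
prioritized positions −3, −4, −5, −6, −9) is purely positional; a
tissue-specific Kozak consensus string is a reporting-only configuration
value with no default claim of fidelity, because the filter the workflow
applies does not depend on it.

Variant diffing rescans the reference and alternate 5'UTR, matching uAUGs
by offset (offsets 3' of an indel are shifted by its length change).
Gains and losses are the unmatched records; destroying an existing uORF's
stop without an upstream replacement is a stop-loss event; an indel of
length ≢ 0 (mod 3) inside an existing uORF is a frameshift event. Indels
are left-normalized before diffing. The scanner is verified against an
independent brute-force enumerator on 1,000 random sequences (lengths
0–300, GC 0.3–0.7), and diffing satisfies: no-op ⇒ no events, gain/loss
sets disjoint, and exact reversal restores the reference.

The captured CDS context is min(full CDS, 999 nt) — ample to type
overlapping ORFs on synthetic scales; ORFs with no stop inside the captured
window type by frame alone. On minus-strand transcripts, substitutions are
complemented into mRNA sense; multi-base indels there keep their positional
annotation but skip the sequence diff (the synthetic plan places indel
plants on plus-strand genes; a production run would pre-normalize such
calls).

## Variant filters and evidence

The sequencing-quality gate is per carrier, not per site: a record is
retained iff at least one carrier sample has DP > 10 AND GQ > 15 (strict
inequalities; DP = 10 or GQ = 15 fail). Whether the original workflow gated
per sample or per site is not derivable from its description; the
per-carrier rule is this package's documented choice and is stated in the
report header. Multi-allelic records are split; a variant must overlap an
analysis region.

External evidence (population AF, SpliceAI ΔAG/ΔDG/ΔAL/ΔDL, TE log2FC, MFE
fold change) comes from pre-computed tables keyed by chrom/pos/ref/alt;
TSS and IRES sets are BED intervals. A variant absent from a table keeps
the field absent — never a fabricated zero — and absence from every AF
source passes the rarity gate, since absence from reference populations is
itself evidence of rarity. The SpliceAI summary is the max of the four
deltas; raw deltas are retained.

`internal_mfe_proxy` is a Nussinov maximum base-pairing DP (Watson–Crick +
GU, minimum hairpin loop 3) used only by the synthetic generator to write
self-consistency columns into its MFE fixture tables; no scientific claim
rests on it and production MFE values are always table-supplied.

## Classification and prioritization

Seven non-exclusive categories; a variant's category is held when the
relevant evidence exists, and its filter passes on: (i) gained uAUG in
strong or moderate Kozak; (ii) natural uAUG loss (stop-loss and frameshift
perturbations are held but fail); (iii) c-position in {−3,−4,−5,−6,−9};
(iv) within ±25 bp of a junction and max SpliceAI Δ > 0.2; (v) |TE log2FC|
≥ 0.5; (vi) |MFE FC| ≥ 1.5; (vii) TSS or IRES overlap. Threshold boundary
semantics follow the source workflow exactly: MAF and SpliceAI strict
("lower/higher than"), TE and MFE inclusive (≥). Variants at intronic
near-splice positions are eligible only for the splicing category; the
other six require an exonic 5'UTR position. The category summary counts
only filter-passing categories (a variant passing several goes to the
"> 1 category" row), so the rows partition the total and the percent
column sums to 100.

The inheritance gate: AD — het in an AD-pattern or sporadic case; AR — hom,
or het with ≥ 1 additional rare allele in the same gene, in an AR-pattern
or sporadic case; XL — hemizygous male or het female in an XL-pattern or
sporadic case. Sporadic cases are compatible with all three modes. A family
pattern excludes genes restricted to the opposite mode, with one
deliberate provision: for genes that carry both AD and AR modes, a single
heterozygous variant in an AR-pattern family is accepted under the dominant
model, because reduced penetrance cannot be excluded for dual-inheritance
genes and real candidate sets include exactly this configuration.
Phenotype compatibility is a non-empty intersection of controlled tags — no
ontology reasoning. Panel rating (green/amber/red) is carried into the
rationale but is not a gate. Candidates found in cases with a recorded
alternative molecular diagnosis are emitted with a screen warning rather
than suppressed.

## Synthetic data: what it emulates, what it does not

The generator's defaults mirror the real study's shape: ~1/3 of genes with
spliced (multi-exon) 5'UTRs, 20 % of genes with a non-canonical isoform
that tops expression (boosted 4× over its canonical, log-normal TPM noise,
102 samples), genes on both strands, main-AUG Kozak contexts cycling
strong/moderate/weak, chromosomes ≤ 100 kb. 60 genes are generated by
default — enough to host every plant plus spliced, enriched, control and
plain genes — so a full run takes seconds.

Synthetic UTRs are low-complexity (A/C filler) so that planted start and
stop codons are provably the only ones present and every engineered
variant has exactly one intended consequence. For each category the plan
plants at least one passing and one failing variant (SpliceAI 0.25/0.15 at
+1/+5 bp plus one at +30 bp outside the flank; TE +0.6/−0.4; MFE 2.0/1.2;
Kozak positions −6/−7/−11; uAUG gains in strong and weak context and an
out-of-frame gain; uAUG loss, stop loss, and a uORF frameshift deletion;
TSS/IRES overlaps and a near-miss), plus rarity plants at MAF
0.019/0.02/absent and quality plants at DP 11/10 and GQ 16/15. Six cases
cover the MOI archetypes (sporadic AR hom, AD het, sporadic XL hemizygous
male, AR het with a second allele) and two decoys (phenotype mismatch, MOI
mismatch). Each output file draws from its own seed-derived random stream,
so outputs are byte-deterministic and adding a file never perturbs the
others.

What passing on this synthetic cohort does **not** show: performance on
realistic sequence composition (real UTRs are GC-rich and contain incidental
uAUGs), on noisy or conflicting evidence tables, on structural variants, or
on real population AF spectra. The generator validates the pipeline's
logic, boundaries, and bookkeeping — not its clinical yield.

The replica of the published candidate table is an in-memory fixture that
encodes each prioritized variant's printed gene, category evidence, MAF,
zygosity, and family pattern, with a panel granting each gene its printed
inheritance mode; SpliceAI deltas for the splicing rows are not printed in
the source table and are encoded as representative above-threshold values,
which the count-based checks do not depend on.

## Numerical and degenerate-input choices

Percentages in the category summary round to 2 decimals; the ratio
formatter for prose reports rounds to whole percent. Coverage of an empty
capture design is an all-zero report with a warning, not an error. An empty
expression matrix is an input error; a panel gene with no expression rows
keeps its canonical isoform with mean 0. A missing evidence table
gracefully withholds its category rather than aborting, since real cohorts
lack some annotations. Re-running the pipeline with an identical
configuration reproduces byte-identical outputs (headers carry a config
hash, never timestamps).

## Known limitations

- No liftover, no 3'UTR or protein-level HGVS, no structural-variant
  handling beyond the ClinVar CNV filter.
- The splicing category depends entirely on supplied SpliceAI tables; the
  package never predicts splicing itself.
- Minus-strand multi-base indels receive positional but not sequence-diff
  annotation (see above).
- Phenotype matching is tag-set intersection; no HPO semantics.
- The capture audit measures design intervals, not empirical read depth.
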
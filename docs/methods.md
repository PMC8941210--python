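# Methods

`skipfinder` detects, scores and quantifies exon-skipping events in
gene-targeted long-read cDNA sequencing of a single known transcript, and
annotates their coding consequences. This note records the model behind
each stage, the parameters that matter, the numerical choices, and the
limits of what the synthetic-data tests demonstrate.

## Coordinate frame and reference model

All analysis happens in mRNA (transcript) space: reads are aligned to the
spliced reference transcript, so introns never appear and "exon
boundaries" are splice-junction positions on the mRNA. Internally every
interval is 0-based half-open (BED convention); report tables convert to
1-based inclusive at the I/O boundary only. The reference model couples
the transcript sequence with an ordered, non-overlapping exon table and a
declared CDS; all invariants (bounds, ordering, CDS divisibility) are
enforced at load time rather than downstream.

The bundled demo transcript mirrors the geometry of a long multi-exon
tRNA-synthetase mRNA: 33 coding exons tiling 3.9 kb with a 213 nt exon at
ordinal 20. Because 213 is divisible by 3, skipping exon 20 is in-frame
and removes 71 codons; this is the central worked example throughout the
package. Exon boundary ties (two boundaries equidistant from a gap
endpoint) resolve to the lower exon index, purely for determinism.

## Alignment

Gene-targeted cDNA reads are noisy subsequences of one known transcript,
so alignment is semi-global ("glocal"): the read is consumed end to end
while gaps at either end of the reference are free. The full Gotoh
three-state affine-gap recurrence is computed exactly (no banding or
heuristics; the reference is only ~4 kb) in a numba-compiled kernel with
one traceback-pointer byte per cell.

Default scoring: match +2, mismatch −4, gap open −4, gap extend −1, with
the open penalty charged once per gap. Affine costs are essential to the
method: a skipped exon appears as one long deletion, which must be
cheaper than the same bases lost to many scattered gaps. Ties in the
recurrence resolve aligned-base over deletion over insertion, making the
CIGAR deterministic. Reads scoring below 0.5 points per base (e.g.
reverse-complement contaminants) are flagged unaligned. Insertions
abutting either reference end are reported as soft clips.

Because the DP tie-break is sequence-agnostic, a deletion flanked by
repeated bases can land a few nt off the true junction among
score-equivalent placements. A splice-aware normalization step therefore
shifts each internal deletion run, within its score-preserving range, to
the placement minimizing its total offset from the nearest annotated exon
boundaries (ties to the leftmost placement). This is the transcript-space
analogue of the junction-aware gap placement genome spliced aligners
perform, and it is what makes the noiseless round-trip exact: an
error-free skip read realigns to precisely the skipped exon's interval.

External SAM/BAM alignments can substitute for the internal aligner;
unmapped/secondary/supplementary records are dropped with logged counts.

## Alignment-quality filter

An alignment is retained iff

    ln(aligned_bases / cigar_instructions) >= 4,

i.e. at least e⁴ ≈ 54.6 read bases aligned per CIGAR run on average.
`aligned_bases` counts read bases placed opposite reference bases
(matches + mismatches, excluding insertions and clips);
`cigar_instructions` counts run-length CIGAR entries including clips.
Neither term has a universal definition, so both conventions are
config-switchable; the defaults above are the most literal reading. The
threshold is inclusive and the log is natural. The filter removes
alignments shredded by many small error indels while passing clean
alignments even when interrupted by one genuine exon-sized deletion
(a full-length read with a single skip has 3 instructions, ratio ≈ 1200).

## Gap scoring, event aggregation, retention

Deletion runs are extracted from retained alignments; within a read,
deletions separated by an aligned "island" of at most 3 bases are bridged
into one gap (absorbing alignment error inside a real splice deletion),
and only gaps of at least 20 nt become skip candidates. The 20 nt floor
separates splice-scale deletions from error-scale indels (capped at 5 nt
in the simulator): real exons are far larger, error indels far smaller.

Each candidate gap maps to the nearest exon start (for its 5' end) and
nearest exon end (for its 3' end) and receives the gap quality score

    (1 + |start − near_exon_start| + |end − near_exon_end|)^(−1/2),

which is 1.0 exactly when both endpoints sit on boundaries and decays
with total offset. Gaps sharing an implied exon span pool their scores;
events with total score < 1 are discarded. One boundary-exact read
suffices to nominate an event; off-boundary gaps must accumulate support
(e.g. four gaps at total offset 3 each: 4 × 0.5 = 2).

## Per-read classification and PSI

Quantification is exon-anchored: for each retained event span, the
candidate deletion interval D is the annotated span, not each read's own
gap, so all reads are judged against the same interval. A read is called
skipping iff at least 80% of positions in D lack an aligned base and at
least half of the positions in the two flanking margins, pooled, carry
one; each margin is round(0.2·|D|) nt (minimum 1), clipped to the
transcript. Reads whose alignments do not cover D plus both margins are
excluded from the denominator — a truncated cDNA cannot testify either
way. Percent skipping is 100·(called / spanning) with a Wilson 95%
interval (Wald behaves poorly at the small proportions typical here).

Distinct skip patterns across reads form the splice-variant catalog
(SV1, SV2, … in descending read count; full-length reported separately),
and a descriptive 2×2 table tallies skip calls against any other splicing
feature on the same read (partial event or ≥20 nt insertion).

## Partial (alternative splice-site) events

A partial event deletes part of an exon: exactly one endpoint of the
(island-bridged) gap coincides with an annotated boundary, at tolerance
0 nt — alignment jitter is absorbed by the merge step rather than by a
boundary tolerance. Candidate gaps merge when both respective endpoint
distances are ≤ 3 nt (start-to-start AND end-to-end); clusters are
connected components of that link graph, so merging is independent of
input order and permits chains. The reported interval is the modal
(start, end) among members (ties to the smallest coordinates), and only
clusters supported by ≥ 4 distinct reads are reported. Merging precedes
the support filter so near-identical noisy gaps pool their support.

## Coding consequences and in-silico RT-PCR

Total deleted CDS length divisible by 3 ⇒ in-frame, removing length/3
codons; otherwise the frame shifts at the first affected codon. Counting
is sequence-level: a deletion splitting two codons that re-fuse in frame
still counts length/3 codons. Deletions crossing the CDS start/stop are
reported as truncating, not scored. The amplicon predictor returns the
primer span minus all deleted segments inside it; a deletion covering a
primer site yields "no product", and partial overlap of the span is
subtracted with a warning.

## Regulator-screen summaries

rMATS skipped-exon records (standard column set) are parsed with
per-file experiment tags (cell line, knockdown target), filtered at
p < 0.01, and joined to annotated exons by interval equality with ±1 nt
tolerance (absorbing 0/1-based discrepancies). The reported change in
percent exon skipping is −100 × IncLevelDifference, since skipping is
the complement of inclusion; the sign convention is written into the
output header. Cell lines are never averaged. Motif scanning expands
IUPAC degenerate letters to character classes and reports every
(overlapping) occurrence, 1-based; RNA alphabets (U) are accepted.

## Synthetic libraries and what the tests show

The simulator emulates a 3'-anchored gene-targeted cDNA library: reads
are drawn from a weighted isoform mixture (full-length, whole-exon skips,
alternative splice sites, optional retained-intron insertions), optionally
5'-truncated (a truncated fraction of 0.6 with uniform start positions
reproduces a ~2.7 kb mean read on the 3.9 kb transcript), and corrupted
with per-base mismatches and geometric-length indels (length 1 dominant,
capped at 5 nt). Error rates are quoted as the expected per-base fraction
of erroneous bases — the convention used when quoting long-read error
percentages — so indel events initiate at rate/mean_indel_length per
base. One RNG stream is consumed in read-index order: equal seeds give
byte-identical outputs, and extending a library never perturbs earlier
reads. Every read carries a ground-truth record (isoform, span, injected
error ops) enabling parameter-recovery tests.

The emulated leukocyte scenario — 1,000 reads, 22% exon-20 skip
abundance, 1% mismatch + 1% indel (0.5% insertion + 0.5% deletion),
seed 42 — recovers the true skip fraction within binomial uncertainty
(SD ≈ 1.3 points at n = 1,000).

What passing these tests does *not* show: the simulator draws i.i.d.
errors on a uniform-random transcript, so it exercises none of the
homopolymer-biased error structure, chimeric reads, degraded-RNA length
bias, or reverse-transcription artifacts of real long-read libraries;
recovery on real data depends on those nuisances. The simulator also has
no intron sequence — retained introns are synthetic insertions — so
splice-site motif validation is out of reach by construction.

## Problem sizes and determinism

The default test suite runs simulation-heavy checks on a scaled 1.3 kb /
8-exon transcript (the statistical properties tested are size-invariant)
and reserves the full 3.9 kb, 1,000-read scenario for the end-to-end
recovery check; the acceptance script re-runs that scenario at full
scale. All randomness flows from explicit integer seeds; reruns are
byte-identical. Degenerate inputs (zero reads, zero exons, empty
matrices) return empty-but-typed results or raise typed errors as
documented per operation, never NaN surprises downstream.
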
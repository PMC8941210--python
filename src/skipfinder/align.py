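"""Pairwise semi-global alignment of cDNA reads to the transcript.

Gene-targeted long reads are (noisy) subsequences of a single known
transcript, so the natural alignment mode is glocal: the read is consumed
end to end while gaps at either end of the *reference* are free. Affine gap
costs make one long deletion — the signature of a skipped exon — cheaper
than the same bases lost to many scattered gaps, which is exactly the
signal downstream stages score.

The dynamic program is exact (full Gotoh three-state recurrence) and runs
in a numba-compiled kernel; with a ~4 kb reference there is no need for
banding, though a band can be enabled for larger references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .errors import InputError
from .model import TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "Scoring",
    "AlignmentRecord",
    "align_semiglobal",
    "read_sam",
    "write_sam",
]

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# read-consuming and reference-consuming CIGAR operations
_READ_OPS = {"M", "I", "S"}
_REF_OPS = {"M", "D"}


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring parameters; a gap of length k costs
    ``gap_open + k * gap_extend`` (both negative)."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -1


@dataclass
class AlignmentRecord:
    """One read's alignment to the transcript as CIGAR runs.

    ``aligned_bases`` counts read bases placed opposite reference bases
    (M runs: matches and mismatches), excluding insertions and clips;
    ``cigar_instructions`` counts run-length entries including clips. Both
    feed the downstream alignment-quality filter.
    """

    read_id: str
    ref_start: int
    cigar: list[tuple[str, int]]
    score: int = 0
    aligned: bool = True

    def __post_init__(self) -> None:
        for op, n in self.cigar:
            if n <= 0:
                raise InputError(f"{self.read_id}: non-positive CIGAR run {op}{n}")

    @property
    def aligned_bases(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")

    @property
    def cigar_instructions(self) -> int:
        return len(self.cigar)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _READ_OPS)

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


# Traceback pointer bit layout (one byte per DP cell):
#   bits 0-1: source of H — 0 diagonal, 1 E (deletion), 2 F (insertion)
#   bit 2:    E extended an existing deletion (else opened from H)
#   bit 3:    F extended an existing insertion (else opened from H)
@njit(cache=True)
def _gotoh_semiglobal(read, ref, match, mismatch, gap_open, gap_extend):
    n = read.shape[0]
    m = ref.shape[0]
    NEG = -(1 << 30)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    prev_h = np.zeros(m + 1, dtype=np.int32)   # row i-1 of H; free leading ref gap
    prev_f = np.full(m + 1, NEG, dtype=np.int32)
    cur_h = np.empty(m + 1, dtype=np.int32)
    cur_f = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        rb = read[i - 1]
        # column 0: read prefix must be consumed -> insertion run
        cur_f[0] = gap_open + gap_extend * i
        cur_h[0] = cur_f[0]
        ptr[i, 0] = 2 | (8 if i > 1 else 0)
        e = NEG  # E within this row
        for j in range(1, m + 1):
            s = match if (rb == ref[j - 1] and rb < 4) else mismatch
            diag = prev_h[j - 1] + s
            # E: gap in read (deletion from reference)
            open_e = cur_h[j - 1] + gap_open + gap_extend
            ext_e = e + gap_extend
            p = ptr[i, j]
            if ext_e > open_e:
                e = ext_e
                p |= 4
            else:
                e = open_e
            # F: gap in reference (insertion of read bases)
            open_f = prev_h[j] + gap_open + gap_extend
            ext_f = prev_f[j] + gap_extend
            if ext_f > open_f:
                f = ext_f
                p |= 8
            else:
                f = open_f
            cur_f[j] = f
            # prefer aligned-base over deletion over insertion on ties
            if diag >= e and diag >= f:
                h = diag
                p |= 0
            elif e >= f:
                h = e
                p |= 1
            else:
                h = f
                p |= 2
            cur_h[j] = h
            ptr[i, j] = p
        prev_h, cur_h = cur_h, prev_h
        prev_f, cur_f = cur_f, prev_f
    # free trailing reference gap: best score anywhere in the last row
    best_j = 0
    best = NEG
    for j in range(m + 1):
        if prev_h[j] > best:
            best = prev_h[j]
            best_j = j
    return best, best_j, ptr


@njit(cache=True)
def _traceback(ptr, n, best_j):
    # returns (ops, lens, ref_start); ops: 0=M, 1=D, 2=I
    ops = np.empty(n + ptr.shape[1], dtype=np.int8)
    lens = np.empty(n + ptr.shape[1], dtype=np.int64)
    k = 0
    i = n
    j = best_j
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0:
        p = ptr[i, j]
        if state == 0:
            state = p & 3
            if state == 0:
                if k > 0 and ops[k - 1] == 0:
                    lens[k - 1] += 1
                else:
                    ops[k] = 0
                    lens[k] = 1
                    k += 1
                i -= 1
                j -= 1
        elif state == 1:  # deletion consumes reference
            if k > 0 and ops[k - 1] == 1:
                lens[k - 1] += 1
            else:
                ops[k] = 1
                lens[k] = 1
                k += 1
            if p & 4 == 0:
                state = 0
            j -= 1
        else:  # insertion consumes read
            if k > 0 and ops[k - 1] == 2:
                lens[k - 1] += 1
            else:
                ops[k] = 2
                lens[k] = 1
                k += 1
            if p & 8 == 0:
                state = 0
            i -= 1
    return ops[:k], lens[:k], j


def align_semiglobal(
    read_id: str,
    read: str,
    model: TranscriptModel,
    scoring: Scoring = Scoring(),
    min_score_per_base: float = 0.5,
    length_margin: int = 100,
) -> AlignmentRecord:
    """Optimally align one read to the transcript (affine gaps, free
    reference end gaps, read fully consumed).

    Ties in the recurrence resolve aligned-base over deletion over
    insertion, so the CIGAR is deterministic. Reads scoring below
    ``min_score_per_base * len(read)`` (e.g. reverse-complement or foreign
    sequence) are flagged ``aligned=False``. Insertions abutting either end
    of the reference are reported as soft clips.
    """
    if not read:
        raise InputError(f"{read_id}: empty read")
    if len(read) > len(model) + length_margin:
        logger.warning(
            "%s: read length %d exceeds reference length %d by more than %d",
            read_id, len(read), len(model), length_margin,
        )
    score, best_j, ptr = _gotoh_semiglobal(
        _encode(read), _encode(model.sequence),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    ops, lens, ref_start = _traceback(ptr, len(read), best_j)
    names = "MDI"
    cigar = [(names[op], int(ln)) for op, ln in zip(ops[::-1], lens[::-1])]
    # boundary insertions cannot be placed on the reference: soft-clip them
    if cigar and cigar[0][0] == "I" and ref_start == 0:
        cigar[0] = ("S", cigar[0][1])
    if cigar and cigar[-1][0] == "I" and (
        ref_start + sum(n for op, n in cigar if op in _REF_OPS) == len(model)
    ):
        cigar[-1] = ("S", cigar[-1][1])
    aligned = score >= min_score_per_base * len(read)
    return AlignmentRecord(
        read_id=read_id, ref_start=int(ref_start), cigar=cigar,
        score=int(score), aligned=aligned,
    )


def read_sam(path: str | Path, model: TranscriptModel) -> list[AlignmentRecord]:
    """Load externally produced SAM/BAM alignments against the transcript.

    Unmapped, secondary and supplementary records are dropped (counts
    logged). The file's reference name must match the model's.
    """
    import pysam

    records: list[AlignmentRecord] = []
    dropped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        names = set(fh.references or ())
        if names and model.name not in names:
            raise InputError(
                f"{path}: reference names {sorted(names)} do not include "
                f"the model's ({model.name!r})"
            )
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                dropped += 1
                continue
            if aln.reference_name != model.name:
                raise InputError(
                    f"{path}: record {aln.query_name} mapped to "
                    f"{aln.reference_name!r}, expected {model.name!r}"
                )
            op_names = "MIDNSHP=XB"
            cigar = []
            for code, length in aln.cigartuples or ():
                op = op_names[code]
                if op in "=X":
                    op = "M"
                if op == "N":  # reference skip behaves like a deletion here
                    op = "D"
                cigar.append((op, length))
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_start=aln.reference_start,
                    cigar=cigar,
                    score=0,
                )
            )
    if dropped:
        logger.info("%s: dropped %d unmapped/secondary/supplementary records", path, dropped)
    return records


def write_sam(
    records: list[AlignmentRecord], model: TranscriptModel, path: str | Path,
    reads: dict[str, str] | None = None,
) -> None:
    """Export internal alignments as a minimal SAM file (no MD tags)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": model.name, "LN": len(model)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_name = model.name
            a.reference_start = rec.ref_start
            a.mapping_quality = 60 if rec.aligned else 0
            a.flag = 0 if rec.aligned else 4
            a.cigarstring = rec.cigar_string()
            if reads is not None and rec.read_id in reads:
                a.query_sequence = reads[rec.read_id]
            out.write(a)
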
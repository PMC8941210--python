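"""Transcript reference model: sequence, exon structure and coordinate frame.

The coordinate frame for the whole package is the mature mRNA, not the
genome: reads are aligned to the transcript sequence, so "exon boundaries"
are splice-junction positions on the mRNA. Internally every interval is
0-based half-open (BED convention); conversion to 1-based inclusive
coordinates happens only when tables are written for human consumption.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AnnotationError, BoundsError, FormatError, InputError, SpecError

__all__ = [
    "ExonAnnotation",
    "TranscriptModel",
    "IsoformSpec",
    "load_transcript",
    "write_exon_table",
    "build_isoform_sequence",
    "nearest_boundaries",
]


@dataclass(frozen=True)
class ExonAnnotation:
    """One exon of the transcript.

    ``exon_index`` is the 1-based ordinal used in biological naming
    ("exon 20"); ``start``/``end`` are 0-based half-open transcript
    coordinates.
    """

    exon_index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"exon {self.exon_index}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise AnnotationError(f"exon {self.exon_index}: negative start {self.start}")


@dataclass(frozen=True)
class TranscriptModel:
    """Reference transcript with ordered exon intervals and a declared CDS."""

    name: str
    sequence: str
    exons: tuple[ExonAnnotation, ...]
    cds_start: int = 0
    cds_end: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if self.cds_end is None:
            object.__setattr__(self, "cds_end", len(self.sequence))
        if not self.sequence:
            raise InputError("transcript sequence is empty")
        prev_end = -1
        for exon in self.exons:
            if exon.start < prev_end:
                raise AnnotationError(
                    f"exon {exon.exon_index} overlaps the previous exon or is out of order"
                )
            if exon.end > len(self.sequence):
                raise BoundsError(
                    f"exon {exon.exon_index} extends past the sequence end "
                    f"({exon.end} > {len(self.sequence)})"
                )
            prev_end = exon.end
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise BoundsError(
                f"CDS [{self.cds_start}, {self.cds_end}) outside sequence of length "
                f"{len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    def exon(self, exon_index: int) -> ExonAnnotation:
        """Look up an exon by its 1-based ordinal."""
        for e in self.exons:
            if e.exon_index == exon_index:
                return e
        raise AnnotationError(f"no exon with index {exon_index}")

    def exon_span_interval(self, exon_indices: Iterable[int]) -> tuple[int, int]:
        """Transcript interval covered by a contiguous run of exon indices."""
        idx = sorted(set(exon_indices))
        if not idx:
            raise AnnotationError("empty exon span")
        return self.exon(idx[0]).start, self.exon(idx[-1]).end


@dataclass(frozen=True)
class IsoformSpec:
    """Describes one splice isoform relative to the reference transcript.

    ``skipped_exons`` removes whole annotated exons; ``partial_events``
    removes arbitrary intervals (alternative 3'/5' splice sites) given as
    ``((start, end), description)``; ``retained_introns`` (simulation only)
    inserts synthetic intron sequence at a junction, given as
    ``(position, length)``.
    """

    skipped_exons: frozenset[int] = frozenset()
    partial_events: tuple[tuple[tuple[int, int], str], ...] = ()
    retained_introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "skipped_exons", frozenset(self.skipped_exons))
        object.__setattr__(self, "partial_events", tuple(
            ((int(s), int(e)), str(d)) for (s, e), d in self.partial_events
        ))
        object.__setattr__(self, "retained_introns", tuple(
            (int(p), int(n)) for p, n in self.retained_introns
        ))

    def deleted_intervals(self, model: TranscriptModel) -> list[tuple[int, int]]:
        """All deleted intervals, sorted, validated as non-overlapping."""
        intervals = [
            (model.exon(i).start, model.exon(i).end) for i in sorted(self.skipped_exons)
        ]
        intervals += [iv for iv, _ in self.partial_events]
        intervals.sort()
        for (s, e), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e:
                raise SpecError(f"overlapping deletion events: ({s},{e}) and ({s2},{e2})")
        for s, e in intervals:
            if not (0 <= s < e <= len(model)):
                raise SpecError(f"deleted interval ({s},{e}) outside the transcript")
        return intervals

    @property
    def label(self) -> str:
        parts = []
        if self.skipped_exons:
            parts.append("skip" + "+".join(str(i) for i in sorted(self.skipped_exons)))
        for (s, e), desc in self.partial_events:
            parts.append(desc or f"partial{s}-{e}")
        for p, n in self.retained_introns:
            parts.append(f"retain{p}+{n}")
        return "_".join(parts) if parts else "full"


def _parse_exon_table(path: Path) -> list[ExonAnnotation]:
    """Parse a BED (4-column, 0-based half-open) or headered TSV exon table.

    The TSV form declares its convention through the mandatory header
    ``exon_index<TAB>start<TAB>end`` with 0-based half-open coordinates.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: exon table is empty")
    header = lines[0].split("\t")
    exons: list[ExonAnnotation] = []
    if header[:3] == ["exon_index", "start", "end"]:
        for ln in lines[1:]:
            fields = ln.split("\t")
            exons.append(ExonAnnotation(int(fields[0]), int(fields[1]), int(fields[2])))
    else:
        # BED: chrom, start, end, name — name carries the ordinal when present
        for i, ln in enumerate(lines, start=1):
            fields = ln.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: BED line has fewer than 3 columns: {ln!r}")
            idx = i
            if len(fields) >= 4:
                digits = "".join(c for c in fields[3] if c.isdigit())
                if digits:
                    idx = int(digits)
            exons.append(ExonAnnotation(idx, int(fields[1]), int(fields[2])))
    exons.sort(key=lambda e: e.start)
    return exons


def load_transcript(fasta_path: str | Path, exon_table_path: str | Path) -> TranscriptModel:
    """Load a single-record FASTA plus its exon table into a validated model.

    The FASTA must contain exactly one record; the exon table is either
    4-column BED or a TSV with header ``exon_index  start  end`` (0-based
    half-open). All model invariants are enforced on load.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) == 0:
        raise InputError(f"{fasta_path}: FASTA contains no records")
    if len(records) > 1:
        raise InputError(
            f"{fasta_path}: expected exactly one record, found {len(records)}"
        )
    rec = records[0]
    exons = _parse_exon_table(Path(exon_table_path))
    return TranscriptModel(name=rec.id, sequence=str(rec.seq).upper(), exons=tuple(exons))


def write_exon_table(model: TranscriptModel, path: str | Path) -> None:
    """Write the exon annotation as the headered TSV form (0-based half-open)."""
    buf = io.StringIO()
    buf.write("exon_index\tstart\tend\n")
    for e in model.exons:
        buf.write(f"{e.exon_index}\t{e.start}\t{e.end}\n")
    Path(path).write_text(buf.getvalue())


def build_isoform_sequence(model: TranscriptModel, spec: IsoformSpec,
                           intron_sequences: Sequence[str] | None = None) -> str:
    """Construct the mRNA sequence of an isoform.

    Deleted intervals (skipped exons, partial events) are excised; retained
    introns insert sequence at their junction position. Retained-intron
    sequence may be supplied explicitly (one per event, in order); otherwise
    a deterministic synthetic filler derived from the transcript name and
    event coordinates is used, which is sufficient for simulation.
    """
    deletions = spec.deleted_intervals(model)
    seq = model.sequence
    pieces: list[str] = []
    cursor = 0
    for s, e in deletions:
        pieces.append(seq[cursor:s])
        cursor = e
    pieces.append(seq[cursor:])
    out = "".join(pieces)

    if spec.retained_introns:
        # Map insertion points from reference coordinates into the spliced
        # sequence; insert right-to-left so earlier coordinates stay valid.
        events = sorted(spec.retained_introns)
        for k, (pos, length) in reversed(list(enumerate(events))):
            if not (0 <= pos <= len(model)):
                raise SpecError(f"retained-intron position {pos} outside transcript")
            shift = sum(e - s for s, e in deletions if e <= pos)
            for s, e in deletions:
                if s < pos < e:
                    raise SpecError("retained intron inside a deleted interval")
            ins_at = pos - shift
            if intron_sequences is not None:
                intron = intron_sequences[k]
            else:
                intron = _synthetic_intron(model.name, pos, length)
            out = out[:ins_at] + intron + out[ins_at:]
    return out


def _synthetic_intron(name: str, pos: int, length: int) -> str:
    import zlib

    import numpy as np

    seed = zlib.crc32(f"{name}:{pos}:{length}".encode()) % (2**31)
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def nearest_boundaries(
    gap_start: int, gap_end: int, model: TranscriptModel
) -> tuple[int, int, tuple[int, ...]]:
    """Map a deletion gap to the nearest annotated exon boundaries.

    Returns ``(near_exon_start, near_exon_end, implied_span)`` where the
    first two are the exon *start* coordinate closest to ``gap_start`` and
    the exon *end* coordinate closest to ``gap_end``, and the implied span
    is the run of exon indices from the matched start's exon through the
    matched end's exon (empty when the matches cross, i.e. the gap does not
    correspond to any whole-exon run). Distance ties resolve to the
    lower exon index, making the mapping deterministic.
    """
    if not model.exons:
        raise AnnotationError("model has no exons")
    if not (0 <= gap_start < gap_end <= len(model)):
        raise BoundsError(f"gap ({gap_start},{gap_end}) outside transcript")
    best_start = min(model.exons, key=lambda e: (abs(gap_start - e.start), e.exon_index))
    best_end = min(model.exons, key=lambda e: (abs(gap_end - e.end), e.exon_index))
    if best_start.exon_index <= best_end.exon_index:
        span = tuple(
            e.exon_index
            for e in model.exons
            if best_start.exon_index <= e.exon_index <= best_end.exon_index
        )
    else:
        span = ()
    return best_start.start, best_end.end, span
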
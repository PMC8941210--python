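"""Exon-skipping detection: gap extraction, boundary scoring, event
aggregation, per-read classification and the splice-variant catalog.

Each reference deletion in a filtered alignment is mapped to the nearest
annotated exon boundaries and weighted by the gap quality score

    (1 + |start - near_exon_start| + |end - near_exon_end|) ** -0.5

which is 1 for a deletion landing exactly on exon boundaries and decays
with the total boundary offset. Gaps sharing an implied exon span pool
their scores into one candidate event; events whose total score stays
below 1 are discarded, so a single sloppy gap can never nominate an event
but either one boundary-exact deletion or several near-boundary ones can.

Per-read quantification is exon-anchored: a read skips a candidate exon
span when at least 80% of the span's positions lack an aligned base while
at least half of the positions in the two flanking margins (each 20% of
the span length) carry one. Reads whose alignments do not cover the span
plus both margins cannot testify either way and are excluded from the
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .errors import AnnotationError
from .model import TranscriptModel, nearest_boundaries
from .qc import PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GapEvent",
    "ScoredGap",
    "SkipEvent",
    "ReadCall",
    "normalize_gap_placement",
    "extract_gaps",
    "score_gap",
    "aggregate_skip_events",
    "classify_read",
    "classify_reads",
    "catalog_isoforms",
    "cooccurrence_table",
]


@dataclass(frozen=True)
class GapEvent:
    """One reference-deletion interval observed in one read."""

    read_id: str
    start: int  # transcript coordinate of first deleted base
    end: int    # one past the last deleted base

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.read_id}: empty gap ({self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScoredGap:
    gap: GapEvent
    score: float
    span: tuple[int, ...]
    start_offset: int
    end_offset: int


@dataclass
class SkipEvent:
    """Aggregated exon-skipping candidate over one implied exon span."""

    span: tuple[int, ...]
    gaps: list[ScoredGap]

    @property
    def total_score(self) -> float:
        return float(sum(g.score for g in self.gaps))

    @property
    def supporting_reads(self) -> int:
        return len({g.gap.read_id for g in self.gaps})


@dataclass(frozen=True)
class ReadCall:
    """Per-read skip call for one candidate exon span."""

    read_id: str
    span: tuple[int, ...]
    spanning: bool
    interior_unaligned_fraction: float
    margin_aligned_fraction: float
    call: bool


def normalize_gap_placement(
    record: AlignmentRecord, model: TranscriptModel
) -> AlignmentRecord:
    """Shift deletions within their score-equivalent range toward exon
    boundaries.

    When the reference bases flanking a deletion repeat, several gap
    placements realize the same optimal alignment score and the DP's
    tie-break picks one arbitrarily. Splice-aware placement resolves the
    ambiguity biologically: each internal deletion run is shifted, among
    all score-preserving placements, to the one minimizing its total
    offset from the nearest annotated exon boundaries (ties to the
    leftmost placement). Scores and CIGAR validity are unchanged.
    """
    seq = model.sequence
    cigar = list(record.cigar)
    pos = record.ref_start
    starts = []  # reference start of every run
    for op, length in cigar:
        starts.append(pos)
        if op in ("M", "D"):
            pos += length
    for k, (op, length) in enumerate(cigar):
        if op != "D" or k == 0 or k == len(cigar) - 1:
            continue
        if cigar[k - 1][0] != "M" or cigar[k + 1][0] != "M":
            continue
        s = starts[k]
        e = s + length
        max_left = cigar[k - 1][1]
        max_right = cigar[k + 1][1]
        shl = 0
        while shl < max_left and seq[s - shl - 1] == seq[e - shl - 1]:
            shl += 1
        shr = 0
        while shr < max_right and seq[s + shr] == seq[e + shr]:
            shr += 1

        def cost(s_new: int) -> int:
            ns, ne, _ = nearest_boundaries(s_new, s_new + length, model)
            return abs(s_new - ns) + abs(s_new + length - ne)

        best = min(range(s - shl, s + shr + 1), key=lambda c: (cost(c), c))
        d = best - s
        if d != 0:
            cigar[k - 1] = ("M", cigar[k - 1][1] + d)
            cigar[k + 1] = ("M", cigar[k + 1][1] - d)
            starts[k] = best
    cigar = [(op, n) for op, n in cigar if n > 0]
    return AlignmentRecord(
        read_id=record.read_id, ref_start=record.ref_start, cigar=cigar,
        score=record.score, aligned=record.aligned,
    )


def extract_gaps(record: AlignmentRecord, min_gap: int = 20) -> list[GapEvent]:
    """One GapEvent per deletion CIGAR run of length >= min_gap, in read order.

    ``min_gap=1`` yields every deletion run; the pipeline extracts all runs,
    bridges small aligned islands, and only then applies the candidate
    floor, so two halves of a true splice deletion separated by a spurious
    island are not lost.
    """
    gaps: list[GapEvent] = []
    pos = record.ref_start
    for op, length in record.cigar:
        if op == "D":
            if length >= min_gap:
                gaps.append(GapEvent(read_id=record.read_id, start=pos, end=pos + length))
            pos += length
        elif op == "M":
            pos += length
    return gaps


def score_gap(gap: GapEvent, model: TranscriptModel) -> ScoredGap:
    """Gap quality score and implied exon span for one deletion."""
    if not model.exons:
        raise AnnotationError("model has no exons")
    near_start, near_end, span = nearest_boundaries(gap.start, gap.end, model)
    d_start = abs(gap.start - near_start)
    d_end = abs(gap.end - near_end)
    score = (1 + d_start + d_end) ** -0.5
    return ScoredGap(gap=gap, score=score, span=span,
                     start_offset=d_start, end_offset=d_end)


def aggregate_skip_events(
    scored: list[ScoredGap], retention_threshold: float = 1.0
) -> list[SkipEvent]:
    """Group scored gaps by implied exon span, sum scores, apply retention.

    Gaps whose implied span is empty (boundary matches crossing) are
    ignored. Events with total score below the threshold are discarded;
    survivors are sorted by total score, descending.
    """
    by_span: dict[tuple[int, ...], list[ScoredGap]] = {}
    for sg in scored:
        if not sg.span:
            continue
        by_span.setdefault(sg.span, []).append(sg)
    events = [SkipEvent(span=span, gaps=gaps) for span, gaps in by_span.items()]
    kept = [ev for ev in events if ev.total_score >= retention_threshold]
    dropped = len(events) - len(kept)
    if dropped:
        logger.info("event aggregation: discarded %d low-score events", dropped)
    kept.sort(key=lambda ev: (-ev.total_score, ev.span))
    return kept


def classify_read(
    presence_row: np.ndarray,
    span_interval: tuple[int, int],
    read_id: str = "",
    span: tuple[int, ...] = (),
    read_bounds: tuple[int, int] | None = None,
    interior_threshold: float = 0.80,
    margin_threshold: float = 0.50,
    margin_width_frac: float = 0.20,
) -> ReadCall | None:
    """Classify one read against one candidate deletion interval.

    The call is positive iff the unaligned fraction over the interval is at
    least ``interior_threshold`` and the aligned fraction over the two
    flanking margins, pooled, is at least ``margin_threshold``; each margin
    is ``round(margin_width_frac * interval_length)`` nt (minimum 1),
    clipped to the transcript. Reads whose alignment does not cover the
    interval plus both margins are non-spanning (call False, excluded from
    denominators); margins falling entirely outside the transcript exclude
    the read too (returns None, logged).
    """
    s, e = span_interval
    length = e - s
    w = max(1, round(margin_width_frac * length))
    left_lo, left_hi = s - w, s
    right_lo, right_hi = e, e + w
    n_pos = presence_row.shape[0]
    left_lo_c, right_hi_c = max(0, left_lo), min(n_pos, right_hi)
    if left_hi <= 0 or right_lo >= n_pos:
        logger.warning("%s: margins outside transcript for span %s", read_id, span)
        return None
    if read_bounds is not None:
        rs, re = read_bounds
        if rs > left_lo_c or re < right_hi_c:
            return ReadCall(read_id=read_id, span=span, spanning=False,
                            interior_unaligned_fraction=np.nan,
                            margin_aligned_fraction=np.nan, call=False)
    interior = presence_row[s:e]
    margins = np.concatenate([presence_row[left_lo_c:left_hi],
                              presence_row[right_lo:right_hi_c]])
    interior_unaligned = 1.0 - float(interior.mean())
    margin_aligned = float(margins.mean()) if margins.size else 0.0
    call = interior_unaligned >= interior_threshold and margin_aligned >= margin_threshold
    return ReadCall(read_id=read_id, span=span, spanning=True,
                    interior_unaligned_fraction=interior_unaligned,
                    margin_aligned_fraction=margin_aligned, call=call)


def classify_reads(
    pm: PresenceMatrix,
    records: list[AlignmentRecord],
    model: TranscriptModel,
    events: list[SkipEvent],
    **thresholds,
) -> pd.DataFrame:
    """Classify every read against every retained event span.

    Returns one row per (read, span) with the fractions, the spanning flag
    and the boolean call.
    """
    bounds = {r.read_id: (r.ref_start, r.ref_end) for r in records}
    rows = []
    for ev in events:
        interval = model.exon_span_interval(ev.span)
        span_str = "+".join(map(str, ev.span))
        for i, read_id in enumerate(pm.read_ids):
            rc = classify_read(
                pm.matrix[i], interval, read_id=read_id, span=ev.span,
                read_bounds=bounds.get(read_id), **thresholds,
            )
            if rc is None:
                continue
            rows.append({
                "read_id": read_id,
                "span": span_str,
                "spanning": rc.spanning,
                "interior_unaligned_fraction": rc.interior_unaligned_fraction,
                "margin_aligned_fraction": rc.margin_aligned_fraction,
                "call": rc.call,
            })
    return pd.DataFrame(
        rows, columns=["read_id", "span", "spanning",
                       "interior_unaligned_fraction", "margin_aligned_fraction",
                       "call"],
    )


def catalog_isoforms(calls: pd.DataFrame) -> pd.DataFrame:
    """Catalog distinct skip patterns as numbered splice variants.

    Each read's pattern is the set of event spans it was called skipping.
    Patterns with at least one skipped span are labelled SV1, SV2, ... in
    descending read-count order; the full-length pattern is reported as its
    own row. Percentages are of all classified (spanning-anywhere) reads.
    """
    if calls.empty:
        return pd.DataFrame(columns=["label", "pattern", "read_count", "percent"])
    spanning = calls[calls["spanning"]]
    patterns: dict[str, str] = {}
    for read_id, group in spanning.groupby("read_id"):
        skipped = sorted(group.loc[group["call"], "span"])
        patterns[read_id] = "|".join(skipped) if skipped else "full"
    counts = pd.Series(patterns).value_counts()
    total = int(counts.sum())
    rows = []
    rank = 0
    for pattern, count in counts.items():
        if pattern == "full":
            continue
        rank += 1
        rows.append({"label": f"SV{rank}", "pattern": pattern,
                     "read_count": int(count), "percent": 100.0 * count / total})
    full_count = int(counts.get("full", 0))
    rows.append({"label": "full-length", "pattern": "full",
                 "read_count": full_count, "percent": 100.0 * full_count / total})
    return pd.DataFrame(rows, columns=["label", "pattern", "read_count", "percent"])


def cooccurrence_table(
    calls: pd.DataFrame, other_features: dict[str, bool]
) -> pd.DataFrame:
    """2x2 contingency of per-read skip calls against any-other-feature flags.

    Purely descriptive — no test statistic is attached. ``other_features``
    maps read_id to whether the read carries any non-skip splicing feature
    (partial event, long insertion / retained intron).
    """
    skip_by_read: dict[str, bool] = {}
    if not calls.empty:
        spanning = calls[calls["spanning"]]
        for read_id, group in spanning.groupby("read_id"):
            skip_by_read[read_id] = bool(group["call"].any())
    cells = {(False, False): 0, (False, True): 0, (True, False): 0, (True, True): 0}
    for read_id, has_skip in skip_by_read.items():
        other = bool(other_features.get(read_id, False))
        cells[(has_skip, other)] += 1
    return pd.DataFrame(
        {
            "other_feature": [cells[(False, True)], cells[(True, True)]],
            "no_other_feature": [cells[(False, False)], cells[(True, False)]],
        },
        index=pd.Index(["no_skip", "skip"], name="skip_call"),
    )


def events_table(events: list[SkipEvent]) -> pd.DataFrame:
    """Events as a report table (1-based inclusive span coordinates)."""
    rows = []
    for ev in events:
        rows.append({
            "span": "+".join(map(str, ev.span)),
            "total_score": ev.total_score,
            "supporting_reads": ev.supporting_reads,
            "n_gaps": len(ev.gaps),
        })
    return pd.DataFrame(rows, columns=["span", "total_score", "supporting_reads", "n_gaps"])
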
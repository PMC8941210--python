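"""Alternative 3'/5' splice-site (partial exon-skipping) detection.

A partial event removes only part of an exon, so its deletion has exactly
one endpoint on an annotated exon boundary. Because a single noisy read
can place a deletion endpoint anywhere, partial events are only reported
when supported by at least four distinct reads, after two noise-absorbing
steps: within a read, deletions separated by an aligned "island" of at
most three bases are bridged into one gap; across reads, deletions whose
respective endpoints lie within three bases of each other are merged into
one candidate (connected components), whose interval is the modal
(start, end) among members.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .model import TranscriptModel
from .skipdet import GapEvent

logger = logging.getLogger(__name__)

__all__ = [
    "PartialCandidate",
    "bridge_islands",
    "merge_candidates",
    "find_partial_candidates",
    "partials_table",
]


@dataclass
class PartialCandidate:
    """A merged cluster of off-boundary deletions across reads."""

    members: list[GapEvent]
    interval: tuple[int, int]
    start_at_boundary: bool
    end_at_boundary: bool

    @property
    def support(self) -> int:
        return len({g.read_id for g in self.members})


def bridge_islands(gaps: list[GapEvent], max_island: int = 3) -> list[GapEvent]:
    """Merge consecutive same-read gaps separated by tiny aligned islands.

    Gaps must belong to one read and be sorted by start. Applied
    left-to-right until stable; the merged gap spans from the first start
    to the last end, absorbing islands of at most ``max_island`` aligned
    bases that are best explained as sequencing or alignment error.
    """
    if len(gaps) <= 1:
        return list(gaps)
    read_ids = {g.read_id for g in gaps}
    if len(read_ids) != 1:
        raise ValueError("bridge_islands operates within a single read")
    merged = [gaps[0]]
    for gap in gaps[1:]:
        prev = merged[-1]
        island = gap.start - prev.end
        if island < 0:
            raise ValueError(f"{gap.read_id}: overlapping gaps")
        if island <= max_island:
            merged[-1] = GapEvent(read_id=prev.read_id, start=prev.start, end=gap.end)
        else:
            merged.append(gap)
    return merged


def _boundary_flags(
    gap: GapEvent, model: TranscriptModel, boundary_tol: int
) -> tuple[bool, bool]:
    starts = {e.start for e in model.exons}
    ends = {e.end for e in model.exons}
    at_start = any(abs(gap.start - s) <= boundary_tol for s in starts)
    at_end = any(abs(gap.end - e) <= boundary_tol for e in ends)
    return at_start, at_end


def merge_candidates(
    gaps: list[GapEvent], max_endpoint_dist: int = 3
) -> list[list[GapEvent]]:
    """Cluster gaps whose respective endpoints differ by <= max_endpoint_dist.

    Two gaps link when |start - start'| <= d AND |end - end'| <= d; clusters
    are the connected components of the link graph (transitive closure), so
    the result is independent of input order.
    """
    n = len(gaps)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(range(n), key=lambda i: (gaps[i].start, gaps[i].end, gaps[i].read_id))
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            if gaps[j].start - gaps[i].start > max_endpoint_dist:
                break
            if abs(gaps[i].end - gaps[j].end) <= max_endpoint_dist:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[int, list[GapEvent]] = {}
    for i in order:
        clusters.setdefault(find(i), []).append(gaps[i])
    # canonical order: by the first member under (start, end, read_id)
    out = list(clusters.values())
    out.sort(key=lambda ms: (ms[0].start, ms[0].end, ms[0].read_id))
    return out


def _modal_interval(members: list[GapEvent]) -> tuple[int, int]:
    counts = Counter((g.start, g.end) for g in members)
    best = max(counts.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))
    return best[0]


def find_partial_candidates(
    gaps: list[GapEvent],
    model: TranscriptModel,
    boundary_tol: int = 0,
    min_support: int = 4,
    max_endpoint_dist: int = 3,
) -> list[PartialCandidate]:
    """Detect alternative splice-site events from island-bridged gaps.

    A gap is a candidate member iff exactly one endpoint coincides (within
    ``boundary_tol``) with an annotated exon boundary; members are merged
    by endpoint proximity and clusters supported by fewer than
    ``min_support`` distinct reads are discarded. Gaps with both endpoints
    off-boundary are excluded and logged as "other feature" material.
    """
    members: list[GapEvent] = []
    both_off = 0
    for gap in gaps:
        at_start, at_end = _boundary_flags(gap, model, boundary_tol)
        if at_start != at_end:  # exactly one endpoint on a boundary
            members.append(gap)
        elif not at_start and not at_end:
            both_off += 1
    if both_off:
        logger.info(
            "partial detection: %d gaps with both endpoints off-boundary "
            "excluded (logged as other features)", both_off,
        )
    clusters = merge_candidates(members, max_endpoint_dist=max_endpoint_dist)
    out: list[PartialCandidate] = []
    for cluster in clusters:
        support = len({g.read_id for g in cluster})
        if support < min_support:
            continue
        interval = _modal_interval(cluster)
        probe = GapEvent(read_id="_modal", start=interval[0], end=interval[1])
        at_start, at_end = _boundary_flags(probe, model, boundary_tol)
        out.append(PartialCandidate(
            members=cluster, interval=interval,
            start_at_boundary=at_start, end_at_boundary=at_end,
        ))
    out.sort(key=lambda c: (-c.support, c.interval))
    return out


def partials_table(
    candidates: list[PartialCandidate], model: TranscriptModel
) -> pd.DataFrame:
    """Partial events as a report table (1-based inclusive coordinates)."""
    from .model import nearest_boundaries

    rows = []
    for c in candidates:
        near_start, near_end, span = nearest_boundaries(*c.interval, model)
        if c.start_at_boundary:
            offset = c.interval[1] - near_end
            nearest_exon = span[-1] if span else None
        else:
            offset = c.interval[0] - near_start
            nearest_exon = span[0] if span else None
        rows.append({
            "start": c.interval[0] + 1,
            "end": c.interval[1],
            "n_members": len(c.members),
            "support": c.support,
            "start_at_boundary": c.start_at_boundary,
            "end_at_boundary": c.end_at_boundary,
            "nearest_exon": nearest_exon,
            "offset_from_boundary": offset,
        })
    return pd.DataFrame(
        rows, columns=["start", "end", "n_members", "support",
                       "start_at_boundary", "end_at_boundary",
                       "nearest_exon", "offset_from_boundary"],
    )
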
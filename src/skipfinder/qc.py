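"""Alignment-quality filtering and the per-position base-presence matrix.

The filter keeps an alignment only when

    ln(aligned_bases / cigar_instructions) >= threshold   (default 4)

i.e. the read must carry on average at least e^4 ~ 54.6 aligned bases per
CIGAR run. Alignments shredded into many small runs by error indels fail;
clean alignments — even those interrupted by one genuine exon-sized
deletion — pass easily. ``aligned_bases`` counts read bases opposite
reference bases (matches + mismatches); ``cigar_instructions`` counts
run-length CIGAR entries including clips by default (both conventions are
exposed because the terms admit either reading).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .model import TranscriptModel

logger = logging.getLogger(__name__)

__all__ = ["quality_filter", "filter_table", "PresenceMatrix", "presence_matrix"]


def _ln_ratio(record: AlignmentRecord, count_clips: bool) -> float | None:
    instructions = record.cigar_instructions
    if not count_clips:
        instructions = sum(1 for op, _ in record.cigar if op not in "SH")
    if instructions == 0:
        return None
    ab = record.aligned_bases
    if ab == 0:
        return -math.inf
    return math.log(ab / instructions)


def quality_filter(
    records: list[AlignmentRecord],
    threshold: float = 4.0,
    count_clips: bool = True,
) -> list[AlignmentRecord]:
    """Retain alignments with ln(aligned_bases/cigar_instructions) >= threshold.

    Unaligned records and records with no CIGAR instructions are rejected.
    The threshold is inclusive. Retained/removed counts are logged.
    """
    kept: list[AlignmentRecord] = []
    removed = 0
    for rec in records:
        if not rec.aligned:
            removed += 1
            continue
        ratio = _ln_ratio(rec, count_clips)
        if ratio is None:
            logger.warning("%s: record with zero CIGAR instructions rejected", rec.read_id)
            removed += 1
            continue
        if ratio >= threshold:
            kept.append(rec)
        else:
            removed += 1
    logger.info("quality filter: retained %d, removed %d", len(kept), removed)
    return kept


def filter_table(
    records: list[AlignmentRecord],
    threshold: float = 4.0,
    count_clips: bool = True,
) -> pd.DataFrame:
    """Per-record filter diagnostics: counts, ln ratio and retained flag."""
    rows = []
    for rec in records:
        ratio = _ln_ratio(rec, count_clips)
        rows.append({
            "read_id": rec.read_id,
            "aligned_bases": rec.aligned_bases,
            "cigar_instructions": rec.cigar_instructions if count_clips
            else sum(1 for op, _ in rec.cigar if op not in "SH"),
            "ln_ratio": np.nan if ratio is None else ratio,
            "retained": rec.aligned and ratio is not None and ratio >= threshold,
        })
    return pd.DataFrame(
        rows, columns=["read_id", "aligned_bases", "cigar_instructions",
                       "ln_ratio", "retained"],
    )


@dataclass
class PresenceMatrix:
    """Binary reads x positions indicator of aligned-base presence.

    Position ``j`` of row ``i`` is 1 when read ``i`` places a base opposite
    reference position ``j`` (an M run); deletions, clips and uncovered
    flanks are 0. Column means give the per-position coverage fraction,
    the quantity visualised as a base-presence graph.
    """

    read_ids: list[str]
    matrix: np.ndarray  # bool, shape (n_reads, transcript_length)

    @property
    def coverage_fraction(self) -> np.ndarray:
        if self.matrix.shape[0] == 0:
            return np.full(self.matrix.shape[1], np.nan)
        return self.matrix.mean(axis=0)

    def row(self, read_id: str) -> np.ndarray:
        return self.matrix[self.read_ids.index(read_id)]

    def coverage_table(self) -> pd.DataFrame:
        cov = self.coverage_fraction
        return pd.DataFrame({
            "position": np.arange(1, self.matrix.shape[1] + 1),  # 1-based report
            "coverage_fraction": cov,
        })


def presence_matrix(
    records: list[AlignmentRecord], model: TranscriptModel
) -> PresenceMatrix:
    """Build the base-presence matrix from CIGAR runs."""
    n = len(records)
    mat = np.zeros((n, len(model)), dtype=bool)
    for i, rec in enumerate(records):
        pos = rec.ref_start
        for op, length in rec.cigar:
            if op == "M":
                mat[i, pos:pos + length] = True
                pos += length
            elif op == "D":
                pos += length
            # I, S, H consume no reference
    return PresenceMatrix(read_ids=[r.read_id for r in records], matrix=mat)


def plot_presence(pm: PresenceMatrix, path: str, max_reads: int = 500) -> None:
    """Render the base-presence graph (reads stacked over transcript position)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = pm.matrix[:max_reads]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.imshow(sub, aspect="auto", interpolation="nearest", cmap="Greys")
    ax.set_xlabel("transcript position (nt)")
    ax.set_ylabel("read")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
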
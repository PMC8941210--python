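"""Regulator-screen summaries: rMATS skipped-exon tables and motif scans.

Knockdown screens of RNA-binding proteins report differential splicing as
rMATS skipped-exon (SE) records carrying an inclusion-level difference
(knockdown minus control, on [-1, 1]). Skipping is the complement of
inclusion, so the change in percent exon skipping reported here is
``-100 x IncLevelDifference``; the sign convention is recorded in the
output header. Motif scanning locates IUPAC consensus binding sites
(e.g. splicing-factor motifs) on transcript windows.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import FormatError, MotifError
from .model import TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "SkippedExonRecord",
    "MotifHit",
    "parse_rmats_se",
    "filter_significant",
    "summarize_delta_skipping",
    "scan_motifs",
]

_REQUIRED_COLUMNS = [
    "GeneID", "geneSymbol", "exonStart_0base", "exonEnd",
    "PValue", "FDR", "IncLevelDifference",
]


@dataclass(frozen=True)
class SkippedExonRecord:
    """One rMATS skipped-exon entry with its experiment tags."""

    gene_id: str
    gene_symbol: str
    exon_start: int   # 0-based, as in the source format
    exon_end: int
    p_value: float
    fdr: float
    inc_level_difference: float
    cell_line: str = ""
    target: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.fdr <= 1.0):
            raise FormatError(f"p-value/FDR outside [0,1] for {self.gene_symbol}")
        if not (-1.0 <= self.inc_level_difference <= 1.0):
            raise FormatError(
                f"IncLevelDifference {self.inc_level_difference} outside [-1,1]"
            )


def parse_rmats_se(
    path: str | Path, cell_line: str = "", target: str = ""
) -> list[SkippedExonRecord]:
    """Parse an rMATS SE output TSV, tagging records with their experiment.

    Requires the standard column set; malformed rows are rejected with
    row-numbered log entries rather than aborting the parse.
    """
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas raises several flavours here
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required rMATS SE columns {missing}")
    records: list[SkippedExonRecord] = []
    for row_number, row in frame.iterrows():
        try:
            records.append(SkippedExonRecord(
                gene_id=str(row["GeneID"]),
                gene_symbol=str(row["geneSymbol"]),
                exon_start=int(row["exonStart_0base"]),
                exon_end=int(row["exonEnd"]),
                p_value=float(row["PValue"]),
                fdr=float(row["FDR"]),
                inc_level_difference=float(row["IncLevelDifference"]),
                cell_line=cell_line,
                target=target,
            ))
        except (ValueError, TypeError, FormatError) as exc:
            logger.warning("%s row %d: rejected (%s)", path, row_number + 2, exc)
    return records


def filter_significant(
    records: list[SkippedExonRecord], p_threshold: float = 0.01,
    gene: str | None = None,
) -> list[SkippedExonRecord]:
    """Keep records with p < threshold, optionally restricted to one gene.

    Idempotent: filtering twice equals filtering once.
    """
    out = [r for r in records if r.p_value < p_threshold]
    if gene is not None:
        out = [r for r in out if gene in (r.gene_symbol, r.gene_id)]
    return out


def summarize_delta_skipping(
    records: list[SkippedExonRecord],
    model: TranscriptModel,
    coordinate_tol: int = 1,
) -> pd.DataFrame:
    """Per (target, cell line, exon): change in percent exon skipping.

    Exon intervals are joined to the model's annotated exons by interval
    equality with +/-``coordinate_tol`` nt slack (absorbing 0/1-based
    discrepancies between annotation sources); unmatched rows are flagged
    ``unmapped`` and excluded from per-exon rows. Cell lines are never
    averaged. The reported change is ``-100 x IncLevelDifference``
    (skipping = 1 - inclusion).
    """
    rows = []
    for r in records:
        exon_index = None
        for e in model.exons:
            if (abs(r.exon_start - e.start) <= coordinate_tol
                    and abs(r.exon_end - e.end) <= coordinate_tol):
                exon_index = e.exon_index
                break
        rows.append({
            "target": r.target,
            "cell_line": r.cell_line,
            "gene": r.gene_symbol,
            "exon_index": exon_index,
            "exon_start": r.exon_start,
            "exon_end": r.exon_end,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "delta_percent_skipping": -100.0 * r.inc_level_difference,
            "unmapped": exon_index is None,
        })
    frame = pd.DataFrame(
        rows, columns=["target", "cell_line", "gene", "exon_index",
                       "exon_start", "exon_end", "p_value", "fdr",
                       "delta_percent_skipping", "unmapped"],
    )
    if frame["unmapped"].any():
        logger.info("delta-skipping summary: %d rows unmapped to annotated exons",
                    int(frame["unmapped"].sum()))
    return frame


@dataclass(frozen=True)
class MotifHit:
    """One IUPAC motif occurrence; ``position`` is 1-based."""

    motif: str
    position: int
    matched: str


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif.upper():
        if ch == "U":
            ch = "T"
        values = ambiguous_dna_values.get(ch)
        if values is None:
            raise MotifError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        parts.append(ch if len(values) == 1 else f"[{values}]")
    return "".join(parts)


def scan_motifs(
    sequence: str, motifs: list[str], window_offset: int = 0
) -> list[MotifHit]:
    """All (overlapping) occurrences of IUPAC motifs in a sequence window.

    RNA motifs (with U) are accepted and matched against the DNA-alphabet
    transcript. ``window_offset`` shifts reported positions when the window
    is a slice of a longer transcript; positions are 1-based.
    """
    if not motifs:
        raise MotifError("motif list is empty")
    seq = sequence.upper().replace("U", "T")
    hits: list[MotifHit] = []
    for motif in motifs:
        pattern = re.compile(f"(?=({_iupac_regex(motif)}))")
        for m in pattern.finditer(seq):
            hits.append(MotifHit(
                motif=motif,
                position=window_offset + m.start() + 1,
                matched=m.group(1),
            ))
    hits.sort(key=lambda h: (h.position, h.motif))
    return hits


def motif_table(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"motif": h.motif, "position": h.position, "matched": h.matched}
         for h in hits],
        columns=["motif", "position", "matched"],
    )
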
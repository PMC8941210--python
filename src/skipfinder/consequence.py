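"""Coding consequences of splice events, in-silico RT-PCR and PSI.

A deletion whose total removed CDS length is divisible by three preserves
the reading frame and removes length/3 codons (a 213 nt exon removes 71
amino acids); otherwise it shifts the frame from the first affected codon.
Counting is sequence-level: a deletion that splits two codons which
re-fuse in frame still counts length/3 removed codons regardless of phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .model import IsoformSpec, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "ConsequenceReport",
    "frame_consequence",
    "predict_amplicon",
    "PsiEstimate",
    "estimate_psi",
]


@dataclass(frozen=True)
class ConsequenceReport:
    """Coding consequence of one isoform's deletions."""

    label: str
    deleted_cds_length: int
    in_frame: bool
    aa_removed: int | None          # codons removed, when in frame
    frameshift_codon: int | None    # 1-based codon ordinal, when frameshifting
    truncating: bool                # deletion crosses the CDS start or stop
    affected_cds_interval: tuple[int, int] | None

    @property
    def kind(self) -> str:
        if self.truncating:
            return "truncating"
        if self.deleted_cds_length == 0:
            return "non-coding"
        return "in-frame" if self.in_frame else "frameshift"


def frame_consequence(spec: IsoformSpec, model: TranscriptModel) -> ConsequenceReport:
    """Annotate the reading-frame consequence of an isoform's deletions.

    The total deleted CDS length is summed across all events; a deletion
    crossing the CDS start or end is reported as truncating and not scored
    as removed amino acids.
    """
    deletions = spec.deleted_intervals(model)
    cs, ce = model.cds_start, model.cds_end
    deleted_cds = 0
    truncating = False
    first = last = None
    for s, e in deletions:
        if s < cs < e or s < ce < e:
            truncating = True
        overlap_s, overlap_e = max(s, cs), min(e, ce)
        if overlap_e > overlap_s:
            deleted_cds += overlap_e - overlap_s
            first = overlap_s if first is None else min(first, overlap_s)
            last = overlap_e if last is None else max(last, overlap_e)
    in_frame = deleted_cds % 3 == 0
    aa_removed = deleted_cds // 3 if (in_frame and not truncating) else None
    frameshift_codon = None
    if not in_frame and not truncating and first is not None:
        frameshift_codon = (first - cs) // 3 + 1
    return ConsequenceReport(
        label=spec.label,
        deleted_cds_length=deleted_cds,
        in_frame=in_frame,
        aa_removed=aa_removed,
        frameshift_codon=frameshift_codon,
        truncating=truncating,
        affected_cds_interval=(first, last) if first is not None else None,
    )


def predict_amplicon(
    primer_span: tuple[int, int], spec: IsoformSpec, model: TranscriptModel
) -> int | None:
    """Predicted RT-PCR product length for one isoform.

    The product is the primer span minus every deleted segment inside it;
    a deletion covering either primer site means no product (None). A
    deletion only partially overlapping the span subtracts its overlapping
    portion, with a warning — primers flanking a splice junction still
    amplify the shortened product.
    """
    span_s, span_e = primer_span
    if not (0 <= span_s < span_e <= len(model)):
        raise ValueError(f"primer span ({span_s},{span_e}) outside transcript")
    length = span_e - span_s
    for s, e in spec.deleted_intervals(model):
        if s <= span_s < e or s <= span_e - 1 < e:
            logger.info("%s: deletion (%d,%d) covers a primer site — no product",
                        spec.label, s, e)
            return None
        overlap = min(e, span_e) - max(s, span_s)
        if overlap > 0:
            if s < span_s or e > span_e:
                logger.warning("%s: deletion (%d,%d) partially overlaps the primer span",
                               spec.label, s, e)
            length -= overlap
    return length


@dataclass(frozen=True)
class PsiEstimate:
    """Percent exon skipping with a Wilson 95% interval."""

    exon_span: str
    n_skipping: int
    n_spanning: int
    percent_skipping: float
    ci_low: float
    ci_high: float


def estimate_psi(calls: pd.DataFrame, span: str) -> PsiEstimate | None:
    """Percent skipping for one event span from per-read calls.

    The denominator is reads whose alignments span the candidate exon plus
    both margins (the classifier's ``spanning`` flag); the Wilson score
    interval quantifies binomial uncertainty. Returns None (logged) when
    no read spans the exon.
    """
    sub = calls[(calls["span"] == span) & calls["spanning"]]
    n = len(sub)
    if n == 0:
        logger.warning("PSI for span %s: no spanning reads", span)
        return None
    k = int(sub["call"].sum())
    low, high = proportion_confint(k, n, alpha=0.05, method="wilson")
    return PsiEstimate(
        exon_span=span, n_skipping=k, n_spanning=n,
        percent_skipping=100.0 * k / n,
        ci_low=100.0 * float(low), ci_high=100.0 * float(high),
    )


def psi_table(calls: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for span in sorted(calls["span"].unique()) if not calls.empty else []:
        est = estimate_psi(calls, span)
        if est is None:
            continue
        rows.append({
            "span": est.exon_span, "n_skipping": est.n_skipping,
            "n_spanning": est.n_spanning,
            "percent_skipping": est.percent_skipping,
            "wilson_ci_low": est.ci_low, "wilson_ci_high": est.ci_high,
        })
    return pd.DataFrame(
        rows, columns=["span", "n_skipping", "n_spanning", "percent_skipping",
                       "wilson_ci_low", "wilson_ci_high"],
    )


def consequence_table(
    specs: list[IsoformSpec], model: TranscriptModel
) -> pd.DataFrame:
    rows = []
    for spec in specs:
        rep = frame_consequence(spec, model)
        rows.append({
            "isoform": rep.label,
            "kind": rep.kind,
            "deleted_cds_length": rep.deleted_cds_length,
            "in_frame": rep.in_frame,
            "aa_removed": np.nan if rep.aa_removed is None else rep.aa_removed,
            "frameshift_codon": np.nan if rep.frameshift_codon is None
            else rep.frameshift_codon,
        })
    return pd.DataFrame(
        rows, columns=["isoform", "kind", "deleted_cds_length", "in_frame",
                       "aa_removed", "frameshift_codon"],
    )
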
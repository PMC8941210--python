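"""Column schemas for every table the pipeline writes.

Shipped alongside the code so that outputs can be validated
programmatically; the human-readable description lives in
``docs/output_schemas.md``.
"""

from __future__ import annotations

import pandas as pd

from .errors import FormatError

TABLE_SCHEMAS: dict[str, list[str]] = {
    "filter": ["read_id", "aligned_bases", "cigar_instructions", "ln_ratio",
               "retained"],
    "coverage": ["position", "coverage_fraction"],
    "events": ["span", "total_score", "supporting_reads", "n_gaps"],
    "read_calls": ["read_id", "span", "spanning", "interior_unaligned_fraction",
                   "margin_aligned_fraction", "call"],
    "catalog": ["label", "pattern", "read_count", "percent"],
    "cooccurrence": ["other_feature", "no_other_feature"],
    "partials": ["start", "end", "n_members", "support", "start_at_boundary",
                 "end_at_boundary", "nearest_exon", "offset_from_boundary"],
    "consequences": ["isoform", "kind", "deleted_cds_length", "in_frame",
                     "aa_removed", "frameshift_codon"],
    "psi": ["span", "n_skipping", "n_spanning", "percent_skipping",
            "wilson_ci_low", "wilson_ci_high"],
    "truth": ["read_id", "isoform", "skipped_exons", "has_partial",
              "has_retention", "span_start", "span_end", "n_mismatch",
              "n_insertion", "n_deletion", "error_ops"],
    "rmats_summary": ["target", "cell_line", "gene", "exon_index", "exon_start",
                      "exon_end", "p_value", "fdr", "delta_percent_skipping",
                      "unmapped"],
    "motifs": ["motif", "position", "matched"],
}


def validate_table(name: str, frame: pd.DataFrame) -> None:
    """Raise FormatError unless the frame has exactly the schema's columns."""
    expected = TABLE_SCHEMAS.get(name)
    if expected is None:
        raise FormatError(f"unknown table {name!r}")
    if list(frame.columns) != expected:
        raise FormatError(
            f"table {name!r}: columns {list(frame.columns)} != schema {expected}"
        )
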
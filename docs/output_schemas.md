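# Output table schemas

Machine-readable copies of these schemas live in
`skipfinder.schemas.TABLE_SCHEMAS`; every pipeline run validates each
table against them before writing. Coordinates in report tables are
1-based inclusive unless a column name says otherwise.

## filter.tsv
| column | meaning |
|---|---|
| read_id | read identifier |
| aligned_bases | read bases aligned opposite reference bases (M runs) |
| cigar_instructions | CIGAR run-length entries (clips included by default) |
| ln_ratio | ln(aligned_bases / cigar_instructions) |
| retained | True iff ln_ratio >= filter threshold (default 4) |

## coverage.tsv
| column | meaning |
|---|---|
| position | transcript position (1-based) |
| coverage_fraction | fraction of retained reads with an aligned base here |

## events.tsv
| column | meaning |
|---|---|
| span | implied exon span of the skip event, e.g. `20` or `5+6` |
| total_score | sum of gap quality scores across supporting gaps |
| supporting_reads | distinct reads contributing gaps |
| n_gaps | gaps pooled into the event |

## read_calls.tsv
| column | meaning |
|---|---|
| read_id | read identifier |
| span | candidate exon span the read was judged against |
| spanning | read's alignment covers the span plus both margins |
| interior_unaligned_fraction | fraction of span positions without an aligned base |
| margin_aligned_fraction | pooled aligned fraction over the two margins |
| call | True iff interior >= 0.80 and margins >= 0.50 |

## catalog.tsv
| column | meaning |
|---|---|
| label | `SV1`, `SV2`, ... by descending count; `full-length` separate |
| pattern | skipped spans joined by `|`, or `full` |
| read_count | reads with exactly this pattern |
| percent | percentage of classified reads |

## cooccurrence.tsv
2x2 counts: rows `no_skip`/`skip` (any skip call per read), columns
`other_feature`/`no_other_feature` (partial event or >= 20 nt insertion
on the same read). Descriptive only.

## partials.tsv
| column | meaning |
|---|---|
| start, end | merged deletion interval (1-based inclusive) |
| n_members | gaps in the merged cluster |
| support | distinct supporting reads (always >= 4) |
| start_at_boundary, end_at_boundary | exactly one is True |
| nearest_exon | exon index of the boundary-matched endpoint |
| offset_from_boundary | signed nt offset of the off-boundary endpoint |

## consequences.tsv
| column | meaning |
|---|---|
| isoform | event label |
| kind | `in-frame`, `frameshift`, `truncating` or `non-coding` |
| deleted_cds_length | nt of CDS removed |
| in_frame | deleted_cds_length divisible by 3 |
| aa_removed | codons removed (in-frame only) |
| frameshift_codon | 1-based codon where the shift begins (frameshift only) |

## psi.tsv
| column | meaning |
|---|---|
| span | event span |
| n_skipping | reads called skipping |
| n_spanning | denominator (spanning reads) |
| percent_skipping | 100 * n_skipping / n_spanning |
| wilson_ci_low, wilson_ci_high | Wilson 95% interval (percent) |

## truth.tsv (simulation only)
read_id, isoform label, skipped_exons, has_partial, has_retention,
span_start/span_end (read's interval on its isoform, 0-based half-open),
n_mismatch/n_insertion/n_deletion, and the compact error-op list
(`X1@pos;I2@pos;D1@pos`, positions on the clean template).

## rMATS summary (rmats-summary subcommand)
target, cell_line, gene, exon_index (joined with +/-1 nt tolerance),
exon_start/exon_end (0-based, as in the source), p_value, fdr,
delta_percent_skipping (= -100 x IncLevelDifference), unmapped.

## motifs.tsv (motif-scan subcommand)
motif (IUPAC string), position (1-based), matched subsequence.
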
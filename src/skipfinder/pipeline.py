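"""End-to-end orchestration: simulate/load -> align -> filter -> detect ->
classify -> catalog -> annotate -> summarize, with a run manifest.

Every stage's thresholds live in :class:`RunConfig`; the manifest written
with each run records the exact parameters, package version and input
checksums, and every output table is validated against its shipped schema
before writing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import AlignmentRecord, Scoring, align_semiglobal, read_sam
from .consequence import consequence_table, psi_table
from .errors import ConfigError, InputError
from .model import IsoformSpec, TranscriptModel, load_transcript
from .partials import bridge_islands, find_partial_candidates, partials_table
from .qc import filter_table, presence_matrix, quality_filter
from .schemas import validate_table
from .simulate import SimulationConfig, simulate_to_files
from .skipdet import (
    aggregate_skip_events,
    classify_reads,
    catalog_isoforms,
    cooccurrence_table,
    events_table,
    extract_gaps,
    normalize_gap_placement,
    score_gap,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All thresholds and paths for one pipeline run.

    Defaults are the method's published operating points: quality filter at
    ln-ratio 4, event retention at total score 1, per-read classification
    at 80% interior / 50% margin / 20% margin width, partial events at
    support 4 with 3 nt endpoint merging and 3 nt island bridging, and a
    20 nt floor on candidate splice deletions.
    """

    out_dir: Path
    reference_fasta: Path | None = None
    exon_table: Path | None = None
    reads_fasta: Path | None = None
    sam_path: Path | None = None
    simulate: SimulationConfig | None = None

    filter_threshold: float = 4.0
    count_clips: bool = True
    retention_threshold: float = 1.0
    interior_threshold: float = 0.80
    margin_threshold: float = 0.50
    margin_width_frac: float = 0.20
    min_gap: int = 20
    min_support: int = 4
    max_endpoint_dist: int = 3
    max_island: int = 3
    boundary_tol: int = 0
    scoring: Scoring = field(default_factory=Scoring)
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in (
            ("interior_threshold", 0, 1), ("margin_threshold", 0, 1),
            ("margin_width_frac", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo},{hi}]")
        if self.min_gap < 1 or self.min_support < 1:
            raise ConfigError("min_gap and min_support must be >= 1")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    model: TranscriptModel
    records: list[AlignmentRecord]
    retained: list[AlignmentRecord]
    events: pd.DataFrame
    calls: pd.DataFrame
    catalog: pd.DataFrame
    partials: pd.DataFrame
    psi: pd.DataFrame
    consequences: pd.DataFrame
    cooccurrence: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_fasta_reads(path: Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def run_pipeline(config: RunConfig, model: TranscriptModel | None = None) -> PipelineResult:
    """Execute the full detection pipeline and write all output tables.

    Inputs may be (a) a reference FASTA + exon table with reads FASTA or a
    SAM/BAM, or (b) an in-memory model plus a simulation config. The run is
    deterministic given identical inputs and seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("skipfinder")
    root.addHandler(handler)
    try:
        return _run(config, model, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, model: TranscriptModel | None, out: Path) -> PipelineResult:
    inputs: dict[str, str] = {}
    if model is None:
        if config.reference_fasta is None or config.exon_table is None:
            raise InputError("a reference FASTA and exon table (or a model) are required")
        for p in (config.reference_fasta, config.exon_table):
            if not Path(p).exists():
                raise InputError(f"input not found: {p}")
        model = load_transcript(config.reference_fasta, config.exon_table)
        inputs["reference_fasta"] = _sha256(config.reference_fasta)
        inputs["exon_table"] = _sha256(config.exon_table)

    # --- stage: obtain alignments -------------------------------------
    records: list[AlignmentRecord]
    reads: list[tuple[str, str]] = []
    if config.sam_path is not None:
        if not Path(config.sam_path).exists():
            raise InputError(f"input not found: {config.sam_path}")
        inputs["sam"] = _sha256(config.sam_path)
        records = read_sam(config.sam_path, model)
    else:
        if config.simulate is not None:
            fasta = out / "simulated_reads.fasta"
            _, truth = simulate_to_files(model, config.simulate, fasta,
                                         out / "truth.tsv")
            validate_table("truth", truth)
            reads = _read_fasta_reads(fasta)
            inputs["simulated_reads"] = _sha256(fasta)
        elif config.reads_fasta is not None:
            if not Path(config.reads_fasta).exists():
                raise InputError(f"input not found: {config.reads_fasta}")
            inputs["reads_fasta"] = _sha256(config.reads_fasta)
            reads = _read_fasta_reads(config.reads_fasta)
        else:
            raise InputError("no reads: provide reads_fasta, sam_path or simulate")
        logger.info("aligning %d reads", len(reads))
        records = [
            align_semiglobal(read_id, seq, model, scoring=config.scoring)
            for read_id, seq in reads
        ]
    unaligned = sum(1 for r in records if not r.aligned)
    if unaligned:
        logger.info("dropped %d reads below the alignment score threshold", unaligned)

    # --- stage: quality filter + presence -----------------------------
    ftab = filter_table(records, config.filter_threshold, config.count_clips)
    validate_table("filter", ftab)
    ftab.to_csv(out / "filter.tsv", sep="\t", index=False)
    retained = quality_filter(records, config.filter_threshold, config.count_clips)
    retained = [normalize_gap_placement(r, model) for r in retained]
    pm = presence_matrix(retained, model)
    cov = pm.coverage_table()
    validate_table("coverage", cov)
    cov.to_csv(out / "coverage.tsv", sep="\t", index=False)

    # --- stage: gaps, scoring, events ---------------------------------
    gaps_by_read = {
        rec.read_id: bridge_islands(extract_gaps(rec, min_gap=1), config.max_island)
        for rec in retained
    }
    candidate_gaps = [
        g for gaps in gaps_by_read.values() for g in gaps if g.length >= config.min_gap
    ]
    scored = [score_gap(g, model) for g in candidate_gaps]
    events = aggregate_skip_events(scored, config.retention_threshold)
    ev_tab = events_table(events)
    validate_table("events", ev_tab)
    ev_tab.to_csv(out / "events.tsv", sep="\t", index=False)

    # --- stage: partial events ----------------------------------------
    partial_candidates = find_partial_candidates(
        candidate_gaps, model, boundary_tol=config.boundary_tol,
        min_support=config.min_support, max_endpoint_dist=config.max_endpoint_dist,
    )
    part_tab = partials_table(partial_candidates, model)
    validate_table("partials", part_tab)
    part_tab.to_csv(out / "partials.tsv", sep="\t", index=False)

    # --- stage: per-read classification, catalog, co-occurrence -------
    calls = classify_reads(
        pm, retained, model, events,
        interior_threshold=config.interior_threshold,
        margin_threshold=config.margin_threshold,
        margin_width_frac=config.margin_width_frac,
    )
    validate_table("read_calls", calls)
    calls.to_csv(out / "read_calls.tsv", sep="\t", index=False)

    partial_read_ids = {
        g.read_id for c in partial_candidates for g in c.members
    }
    other_features = {}
    for rec in retained:
        long_insertion = any(op == "I" and n >= config.min_gap for op, n in rec.cigar)
        other_features[rec.read_id] = (
            rec.read_id in partial_read_ids or long_insertion
        )
    catalog = catalog_isoforms(calls)
    validate_table("catalog", catalog)
    catalog.to_csv(out / "catalog.tsv", sep="\t", index=False)
    cooc = cooccurrence_table(calls, other_features)
    validate_table("cooccurrence", cooc.reset_index(drop=True))
    cooc.to_csv(out / "cooccurrence.tsv", sep="\t")

    # --- stage: consequences + PSI ------------------------------------
    specs = [
        IsoformSpec(skipped_exons=frozenset(ev.span)) for ev in events
    ] + [
        IsoformSpec(partial_events=((c.interval, f"partial_{c.interval[0]+1}_{c.interval[1]}"),))
        for c in partial_candidates
    ]
    cons = consequence_table(specs, model)
    validate_table("consequences", cons)
    cons.to_csv(out / "consequences.tsv", sep="\t", index=False)
    psi = psi_table(calls)
    validate_table("psi", psi)
    psi.to_csv(out / "psi.tsv", sep="\t", index=False)

    manifest = {
        "package": "skipfinder",
        "version": __version__,
        "python": platform.python_version(),
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in {"out_dir", "reference_fasta", "exon_table", "reads_fasta",
                         "sam_path"}
        },
        "inputs": inputs,
        "transcript": {"name": model.name, "length": len(model),
                       "n_exons": len(model.exons)},
        "counts": {
            "reads_in": len(records) + 0,
            "unaligned": unaligned,
            "qc_retained": len(retained),
            "events": len(events),
            "partial_events": len(partial_candidates),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        model=model, records=records, retained=retained, events=ev_tab,
        calls=calls, catalog=catalog, partials=part_tab, psi=psi,
        consequences=cons, cooccurrence=cooc, manifest=manifest,
    )
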
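import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from skipfinder.align import AlignmentRecord, align_semiglobal
from skipfinder.model import IsoformSpec
from skipfinder.qc import presence_matrix, quality_filter
from skipfinder.simulate import SimulationConfig, simulate_reads
from skipfinder.skipdet import (
    GapEvent,
    aggregate_skip_events,
    catalog_isoforms,
    classify_read,
    classify_reads,
    cooccurrence_table,
    extract_gaps,
    normalize_gap_placement,
    score_gap,
)


class TestExtractGaps:
    def test_coordinate_arithmetic(self):
        rec = AlignmentRecord("r", 1000, [("M", 100), ("D", 213), ("M", 150)])
        gaps = extract_gaps(rec)
        assert [(g.start, g.end) for g in gaps] == [(1100, 1313)]

    def test_small_deletions_below_floor(self):
        rec = AlignmentRecord(
            "r", 0, [("M", 50), ("D", 1), ("M", 50), ("D", 3), ("M", 50)]
        )
        assert extract_gaps(rec) == []
        assert len(extract_gaps(rec, min_gap=1)) == 2

    def test_two_gaps_in_read_order(self):
        rec = AlignmentRecord(
            "r", 0, [("M", 10), ("D", 50), ("M", 10), ("D", 213), ("M", 10)]
        )
        gaps = extract_gaps(rec)
        assert [(g.start, g.end) for g in gaps] == [(10, 60), (70, 283)]


class TestScoreGap:
    def test_exact_boundary_scores_one(self, demo_model):
        exon = demo_model.exon(20)
        sg = score_gap(GapEvent("r", exon.start, exon.end), demo_model)
        assert sg.score == 1.0
        assert sg.span == (20,)

    def test_offsets_one_two(self, demo_model):
        exon = demo_model.exon(20)
        sg = score_gap(GapEvent("r", exon.start + 1, exon.end + 2), demo_model)
        assert sg.score == pytest.approx(0.5)  # (1+1+2)^(-1/2)

    def test_offsets_zero_eight(self, demo_model):
        exon = demo_model.exon(20)
        sg = score_gap(GapEvent("r", exon.start, exon.end - 8), demo_model)
        assert sg.score == pytest.approx(1 / 3)  # 9^(-1/2)

    @given(d1=st.integers(0, 20), d2=st.integers(0, 20))
    def test_monotone_in_offsets(self, demo_model, d1, d2):
        """Score strictly decreases as either boundary offset grows; the
        maximum 1 occurs exactly at (0, 0)."""
        exon = demo_model.exon(20)
        sg = score_gap(GapEvent("r", exon.start + d1, exon.end - d2), demo_model)
        expected = (1 + d1 + d2) ** -0.5
        assert sg.score == pytest.approx(expected)
        assert (sg.score == 1.0) == (d1 == 0 and d2 == 0)


class TestAggregateEvents:
    def test_ten_exact_gaps_total_ten(self, demo_model):
        exon = demo_model.exon(20)
        scored = [
            score_gap(GapEvent(f"r{i}", exon.start, exon.end), demo_model)
            for i in range(10)
        ]
        events = aggregate_skip_events(scored)
        assert len(events) == 1
        assert events[0].total_score == pytest.approx(10.0)
        assert events[0].supporting_reads == 10

    def test_single_half_score_discarded(self, demo_model):
        exon = demo_model.exon(20)
        scored = [score_gap(GapEvent("r", exon.start + 1, exon.end + 2), demo_model)]
        assert aggregate_skip_events(scored) == []

    def test_distinct_spans_never_merge(self, demo_model):
        e20 = demo_model.exon(20)
        scored = [
            score_gap(GapEvent(f"a{i}", e20.start, e20.end), demo_model)
            for i in range(3)
        ] + [
            score_gap(
                GapEvent(f"b{i}", demo_model.exon(5).start, demo_model.exon(6).end),
                demo_model,
            )
            for i in range(3)
        ]
        events = aggregate_skip_events(scored)
        assert sorted(ev.span for ev in events) == [(5, 6), (20,)]

    def test_matches_exhaustive_enumeration(self, demo_model, rng):
        """On small instances, aggregation equals a brute-force grouping of
        every (gap, span) assignment."""
        from skipfinder.model import nearest_boundaries

        exon_ids = [int(i) for i in rng.integers(1, 34, size=40)]
        scored = []
        for i, idx in enumerate(exon_ids):
            e = demo_model.exon(idx)
            jitter = int(rng.integers(0, 3))
            scored.append(
                score_gap(GapEvent(f"r{i}", e.start + jitter, e.end), demo_model)
            )
        events = aggregate_skip_events(scored, retention_threshold=1.0)
        # oracle: independent grouping via nearest_boundaries
        oracle: dict = {}
        for sg in scored:
            ns, ne, span = nearest_boundaries(sg.gap.start, sg.gap.end, demo_model)
            s = (1 + abs(sg.gap.start - ns) + abs(sg.gap.end - ne)) ** -0.5
            oracle[span] = oracle.get(span, 0.0) + s
        expected = {k: v for k, v in oracle.items() if v >= 1.0 and k}
        assert {ev.span: pytest.approx(ev.total_score) for ev in events} == expected


class TestClassifyRead:
    def _row(self, n=1000, interval=(400, 600), interior_unaligned=1.0,
             margin_aligned=1.0):
        s, e = interval
        w = max(1, round(0.2 * (e - s)))
        row = np.zeros(n, dtype=bool)
        row[:] = False
        # margins
        n_m = int(round(margin_aligned * 2 * w))
        margin_positions = list(range(s - w, s)) + list(range(e, e + w))
        for p in margin_positions[:n_m]:
            row[p] = True
        # interior aligned positions
        n_aligned = (e - s) - int(round(interior_unaligned * (e - s)))
        row[s:s + n_aligned] = True
        return row

    def test_clean_skip_called(self):
        row = self._row(interior_unaligned=1.0, margin_aligned=1.0)
        rc = classify_read(row, (400, 600), read_id="r")
        assert rc.call

    def test_interior_79_percent_not_called(self):
        row = self._row(interior_unaligned=0.79, margin_aligned=1.0)
        rc = classify_read(row, (400, 600), read_id="r")
        assert rc.interior_unaligned_fraction == pytest.approx(0.79)
        assert not rc.call

    def test_margins_40_percent_not_called(self):
        row = self._row(interior_unaligned=1.0, margin_aligned=0.40)
        rc = classify_read(row, (400, 600), read_id="r")
        assert rc.margin_aligned_fraction == pytest.approx(0.40)
        assert not rc.call

    def test_margin_width_is_twenty_percent(self):
        # 200 nt interval -> 40 nt margins; aligning exactly the margin
        # positions yields margin fraction 1.0
        row = np.zeros(1000, dtype=bool)
        row[360:400] = True
        row[600:640] = True
        rc = classify_read(row, (400, 600), read_id="r")
        assert rc.margin_aligned_fraction == 1.0

    def test_non_spanning_read_excluded_from_denominator(self):
        row = np.zeros(1000, dtype=bool)
        row[450:1000] = True
        rc = classify_read(row, (400, 600), read_id="r", read_bounds=(450, 1000))
        assert not rc.spanning and not rc.call


class TestCatalogAndCooccurrence:
    def _calls(self, pattern_counts):
        rows = []
        i = 0
        for pattern, count in pattern_counts.items():
            for _ in range(count):
                rid = f"r{i}"
                i += 1
                for span in ("20", "5+6"):
                    rows.append({
                        "read_id": rid, "span": span, "spanning": True,
                        "interior_unaligned_fraction": 0.0,
                        "margin_aligned_fraction": 1.0,
                        "call": span in pattern,
                    })
        return pd.DataFrame(rows)

    def test_two_pattern_catalog_percentages(self):
        calls = self._calls({(): 780, ("20",): 220})
        cat = catalog_isoforms(calls)
        sv1 = cat[cat["label"] == "SV1"].iloc[0]
        assert sv1["pattern"] == "20"
        assert sv1["read_count"] == 220
        assert sv1["percent"] == pytest.approx(22.0)
        full = cat[cat["label"] == "full-length"].iloc[0]
        assert full["read_count"] == 780

    def test_all_full_length(self):
        cat = catalog_isoforms(self._calls({(): 10}))
        assert list(cat["label"]) == ["full-length"]

    def test_multi_exon_pattern_grouped(self):
        cat = catalog_isoforms(self._calls({(): 20, ("5+6",): 5}))
        sv1 = cat[cat["label"] == "SV1"].iloc[0]
        assert sv1["pattern"] == "5+6" and sv1["read_count"] == 5

    def test_cooccurrence_mutually_exclusive(self):
        calls = self._calls({(): 10, ("20",): 5})
        skip_ids = set(calls.loc[calls["call"], "read_id"])
        other = {rid: rid not in skip_ids
                 for rid in calls["read_id"].unique()}
        # every non-skip read has the other feature; no overlap cell
        table = cooccurrence_table(calls, other)
        assert table.loc["skip", "other_feature"] == 0
        assert table.loc["no_skip", "other_feature"] == 10
        assert table.loc["skip", "no_other_feature"] == 5

    def test_zero_reads_all_zero(self):
        table = cooccurrence_table(pd.DataFrame(
            columns=["read_id", "span", "spanning", "call"]), {})
        assert (table.to_numpy() == 0).all()


class TestNoiselessCompleteness:
    def test_zero_error_zero_misclassification(self, small_model):
        """With no sequencing error every skip read is called and no
        full-length read is."""
        full = IsoformSpec()
        skip = IsoformSpec(skipped_exons={4})
        cfg = SimulationConfig(
            n_reads=60, isoform_mixture=((full, 0.7), (skip, 0.3)), seed=5,
        )
        reads, truths = simulate_reads(small_model, cfg)
        truth_skip = {t.read_id for t in truths if 4 in t.isoform.skipped_exons}
        records = [align_semiglobal(rid, seq, small_model) for rid, seq in reads]
        retained = quality_filter(records)
        assert len(retained) == len(records)
        retained = [normalize_gap_placement(r, small_model) for r in retained]
        pm = presence_matrix(retained, small_model)
        gaps = [g for r in retained for g in extract_gaps(r)]
        events = aggregate_skip_events([score_gap(g, small_model) for g in gaps])
        assert [ev.span for ev in events] == [(4,)]
        calls = classify_reads(pm, retained, small_model, events)
        called = set(calls.loc[calls["call"], "read_id"])
        assert called == truth_skip


class TestParameterRecovery:
    @pytest.mark.parametrize("true_fraction", [0.05, 0.22, 0.80])
    def test_recovers_skip_fraction_within_three_points(
        self, small_model, true_fraction
    ):
        """Estimated percent skipping tracks the simulated mixture weight at
        1% indel + 1% mismatch error."""
        from skipfinder.consequence import estimate_psi

        full = IsoformSpec()
        skip = IsoformSpec(skipped_exons={4})
        cfg = SimulationConfig(
            n_reads=400,
            isoform_mixture=((full, 1 - true_fraction), (skip, true_fraction)),
            mismatch_rate=0.01, insertion_rate=0.005, deletion_rate=0.005,
            seed=1,
        )
        reads, _ = simulate_reads(small_model, cfg)
        records = [align_semiglobal(rid, seq, small_model) for rid, seq in reads]
        retained = [
            normalize_gap_placement(r, small_model)
            for r in quality_filter(records)
        ]
        pm = presence_matrix(retained, small_model)
        gaps = [g for r in retained for g in extract_gaps(r)]
        events = aggregate_skip_events([score_gap(g, small_model) for g in gaps])
        calls = classify_reads(pm, retained, small_model, events)
        est = estimate_psi(calls, "4")
        assert est is not None
        assert abs(est.percent_skipping - 100 * true_fraction) <= 3.0
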
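import numpy as np
import pytest

from skipfinder.align import AlignmentRecord, Scoring, align_semiglobal, read_sam, write_sam
from skipfinder.errors import InputError
from skipfinder.model import IsoformSpec, build_isoform_sequence
from skipfinder.simulate import SimulationConfig, simulate_reads


def brute_force_semiglobal_score(read, ref, sc=Scoring()):
    """Full three-matrix affine DP, plain Python: the independent oracle.

    Same alignment model as the production kernel (free reference end gaps,
    read fully consumed), implemented without any shared code.
    """
    n, m = len(read), len(ref)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = sc.gap_open + sc.gap_extend * i
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.match if read[i - 1] == ref[j - 1] else sc.mismatch
            E[i][j] = max(E[i][j - 1] + sc.gap_extend,
                          H[i][j - 1] + sc.gap_open + sc.gap_extend)
            F[i][j] = max(F[i - 1][j] + sc.gap_extend,
                          H[i - 1][j] + sc.gap_open + sc.gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return max(H[n])


def cigar_score(rec, read, ref, sc=Scoring()):
    """Recompute the alignment score implied by the CIGAR."""
    score = 0
    i, j = 0, rec.ref_start
    for op, length in rec.cigar:
        if op == "M":
            for _ in range(length):
                score += sc.match if read[i] == ref[j] else sc.mismatch
                i += 1
                j += 1
        elif op == "D":
            score += sc.gap_open + sc.gap_extend * length
            j += length
        elif op in "IS":
            if op == "I":
                score += sc.gap_open + sc.gap_extend * length
            i += length
    return score


class TestAlignSemiglobal:
    def test_exact_substring_is_single_match_run(self, demo_model):
        read = demo_model.sequence[500:1500]
        rec = align_semiglobal("r", read, demo_model)
        assert rec.cigar == [("M", 1000)]
        assert rec.ref_start == 500
        assert rec.aligned_bases == 1000
        assert rec.cigar_instructions == 1

    def test_exon_sized_deletion_yields_three_runs(self, demo_model):
        exon = demo_model.exon(20)
        read = build_isoform_sequence(demo_model, IsoformSpec(skipped_exons={20}))
        rec = align_semiglobal("r", read, demo_model)
        assert rec.cigar == [
            ("M", exon.start), ("D", 213), ("M", len(demo_model) - exon.end)
        ]
        assert rec.cigar_instructions == 3

    def test_reverse_complement_flagged_unaligned(self, demo_model):
        comp = str.maketrans("ACGT", "TGCA")
        read = demo_model.sequence[1000:2000].translate(comp)[::-1]
        rec = align_semiglobal("r", read, demo_model)
        assert not rec.aligned

    def test_empty_read_rejected(self, demo_model):
        with pytest.raises(InputError):
            align_semiglobal("r", "", demo_model)

    def test_score_matches_brute_force_oracle(self, small_model, rng):
        """Kernel score equals the full-DP oracle on random pairs."""
        from skipfinder.model import TranscriptModel, ExonAnnotation

        bases = np.array(list("ACGT"))
        for trial in range(60):
            m = int(rng.integers(20, 120))
            ref = "".join(rng.choice(bases, size=m))
            model = TranscriptModel(
                name="t", sequence=ref, exons=(ExonAnnotation(1, 0, m),)
            )
            # read: mutated slice of the reference (realistic) or random
            if trial % 3 == 0:
                read = "".join(rng.choice(bases, size=int(rng.integers(10, 80))))
            else:
                lo = int(rng.integers(0, m // 2))
                hi = int(rng.integers(lo + 5, m + 1))
                chars = list(ref[lo:hi])
                for _ in range(int(rng.integers(0, 5))):
                    p = int(rng.integers(0, len(chars)))
                    chars[p] = str(rng.choice(bases))
                read = "".join(chars)
            rec = align_semiglobal("r", read, model)
            assert rec.score == brute_force_semiglobal_score(read, ref)
            # and the CIGAR must realize that score exactly
            assert cigar_score(rec, read, ref) == rec.score
            consumed = sum(n for op, n in rec.cigar if op in "MIS")
            assert consumed == len(read)

    def test_oracle_on_internal_block_deletion(self, rng):
        """A read missing one internal 213 nt block recovers it as one D run."""
        from skipfinder.model import TranscriptModel, ExonAnnotation

        ref = "".join(rng.choice(np.array(list("ACGT")), size=700))
        model = TranscriptModel(name="t", sequence=ref, exons=(ExonAnnotation(1, 0, 700),))
        read = ref[:300] + ref[513:]
        rec = align_semiglobal("r", read, model)
        assert rec.score == brute_force_semiglobal_score(read, ref)
        assert ("D", 213) in rec.cigar
        assert rec.cigar_instructions == 3

    def test_noiseless_skip_reads_round_trip(self, small_model):
        """Noiseless simulated skip reads give exactly one deletion at the
        skipped exon's boundaries."""
        spec = IsoformSpec(skipped_exons={4})
        cfg = SimulationConfig(n_reads=5, isoform_mixture=((spec, 1.0),), seed=3)
        reads, _ = simulate_reads(small_model, cfg)
        from skipfinder.skipdet import normalize_gap_placement

        exon = small_model.exon(4)
        for read_id, seq in reads:
            rec = align_semiglobal(read_id, seq, small_model)
            rec = normalize_gap_placement(rec, small_model)
            dels = [(op, n) for op, n in rec.cigar if op == "D"]
            assert dels == [("D", exon.length)]
            pos = rec.ref_start
            for op, n in rec.cigar:
                if op == "D":
                    assert (pos, pos + n) == (exon.start, exon.end)
                if op in "MD":
                    pos += n


class TestSamIO:
    def test_read_sam_field_arithmetic(self, tmp_path, demo_model):
        sam = tmp_path / "a.sam"
        sam.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{demo_model.name}\tLN:3900\n"
            f"r1\t0\t{demo_model.name}\t1001\t60\t100M213D150M\t*\t0\t0\t*\t*\n"
            f"r2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
            f"r3\t0\t{demo_model.name}\t1\t60\t5H100M\t*\t0\t0\t*\t*\n"
        )
        records = read_sam(sam, demo_model)
        assert [r.read_id for r in records] == ["r1", "r3"]  # unmapped dropped
        r1 = records[0]
        assert r1.ref_start == 1000
        assert r1.aligned_bases == 250
        assert r1.cigar_instructions == 3
        r3 = records[1]
        assert r3.aligned_bases == 100  # hard clip excluded from aligned bases
        assert r3.cigar_instructions == 2

    def test_reference_name_mismatch_rejected(self, tmp_path, demo_model):
        sam = tmp_path / "a.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:OTHER\tLN:100\n")
        with pytest.raises(InputError):
            read_sam(sam, demo_model)

    def test_write_read_round_trip(self, tmp_path, demo_model):
        read = demo_model.sequence[100:400] + demo_model.sequence[600:900]
        rec = align_semiglobal("rt", read, demo_model)
        out = tmp_path / "out.sam"
        write_sam([rec], demo_model, out, reads={"rt": read})
        back = read_sam(out, demo_model)
        assert len(back) == 1
        assert back[0].ref_start == rec.ref_start
        assert back[0].cigar == rec.cigar
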
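import pytest

from txcurate.framealign import AlignParams, translate
from txcurate.homopolymer import (
    CorrectionResult,
    DetectionFailedError,
    FrameshiftEvent,
    HomopolymerRun,
    correct_frameshifts,
    curate_sequence,
    detect_frameshifts,
    find_homopolymers,
)
from txcurate.io_formats import TranscriptRecord, apply_edits
from txcurate.simulate import _CODONS


def cds_for(prot: str) -> str:
    return "".join(_CODONS[aa][0] for aa in prot)


def rec(seq, id="t1"):
    return TranscriptRecord(id, seq, 1.0)


P = AlignParams(min_score=0)


class TestFindHomopolymers:
    def test_two_runs_found(self):
        runs = find_homopolymers("AATTTCGGGG", 3)
        assert [(r.start, r.length, r.base) for r in runs] == [(2, 3, "T"), (6, 4, "G")]

    def test_no_runs_below_min(self):
        assert find_homopolymers("ACGT", 2) == []

    def test_maximality(self):
        assert find_homopolymers("AAAA", 2) == [HomopolymerRun(0, 4, "A")]

    def test_n_never_forms_a_run(self):
        assert find_homopolymers("NNNNNA", 3) == []

    def test_runs_disjoint_sorted(self):
        runs = find_homopolymers("AAACCCAAAGGG", 3)
        starts = [r.start for r in runs]
        assert starts == sorted(starts)
        for a, b in zip(runs, runs[1:]):
            assert a.end <= b.start


class TestDetect:
    # a protein whose CDS contains a prominent AAAAAA (KK) run well inside
    # the sequence — indels in the first or last codons can be absorbed by
    # the aligner's free ends and are not reliably detectable
    prot = "MGWKKEWIDECRWMGW"

    def make_cds(self):
        return cds_for(self.prot)

    def interior_run(self, cds):
        runs = find_homopolymers(cds, 3)
        interior = [r for r in runs if 6 <= r.start and r.end <= len(cds) - 6]
        assert interior, "fixture needs an interior homopolymer run"
        return max(interior, key=lambda r: r.length)

    def test_clean_cds_no_events(self):
        assert detect_frameshifts(rec(self.make_cds()), self.prot, P) == []

    def test_deletion_in_run_detected_as_undercall(self):
        cds = self.make_cds()
        run = self.interior_run(cds)
        broken = cds[: run.end - 1] + cds[run.end :]
        events = detect_frameshifts(rec(broken), self.prot, P)
        assert len(events) == 1
        ev = events[0]
        assert ev.sense == "undercall"
        assert ev.anchor is not None and ev.anchor.base == run.base

    def test_insertion_in_run_detected_as_overcall(self):
        cds = self.make_cds()
        run = self.interior_run(cds)
        broken = cds[: run.end] + run.base + cds[run.end :]
        events = detect_frameshifts(rec(broken), self.prot, P)
        assert len(events) == 1 and events[0].sense == "overcall"

    def test_run_free_indel_unanchored(self):
        # strictly alternating CDS: no two adjacent bases are equal, so no
        # homopolymer run of any length exists near the indel
        cds = "ACGT" * 12
        prot = translate(cds, 0)  # TYVR repeats, stop-free
        assert find_homopolymers(cds, 2) == []
        broken = cds[:24] + cds[25:]
        events = detect_frameshifts(rec(broken), prot, P, anchor_window=10)
        assert len(events) == 1 and events[0].anchor is None

    def test_garbage_raises_detection_failed(self):
        with pytest.raises(DetectionFailedError):
            detect_frameshifts(rec("ACGT" * 10), "WWWWWWWWWWWW", AlignParams())


class TestCorrect:
    def test_empty_events_is_clean_identity(self):
        r = rec("ATGAAAACT")
        res = correct_frameshifts(r, [])
        assert res.status == "clean" and res.corrected_seq == r.seq and not res.edits

    def test_anchored_undercall_inserts_one_base(self):
        r = rec("ATGAAACT")
        run = find_homopolymers(r.seq, 3)[0]
        ev = FrameshiftEvent(4, "undercall", run, 0)
        res = correct_frameshifts(r, [ev])
        assert res.status == "corrected"
        assert len(res.corrected_seq) == len(r.seq) + 1
        (edit,) = res.edits
        assert edit.op == "insertion" and edit.base == run.base
        assert run.start <= edit.position <= run.end  # within the anchor run

    def test_unanchored_event_defers_everything_to_manual(self):
        r = rec("ATGAAAACTGGG")
        run = find_homopolymers(r.seq, 3)[0]
        events = [
            FrameshiftEvent(4, "undercall", run, 0),
            FrameshiftEvent(9, "undercall", None, 0),
        ]
        res = correct_frameshifts(r, events)
        assert res.status == "needs_manual" and res.edits == ()
        assert res.corrected_seq == r.seq

    def test_conflicting_events_on_one_run_defer_to_manual(self):
        r = rec("ATGAAAACT")
        run = find_homopolymers(r.seq, 3)[0]
        events = [
            FrameshiftEvent(3, "undercall", run, 0),
            FrameshiftEvent(5, "undercall", run, 0),
        ]
        assert correct_frameshifts(r, events).status == "needs_manual"


class TestCurate:
    prot = "MGWKKEWIDECRWMGWAAAGW"

    def test_clean_transcript_clean_status(self):
        res = curate_sequence(rec(cds_for(self.prot)), self.prot, P)
        assert res.status == "clean" and res.edits == ()

    def test_two_indels_in_distinct_runs_corrected(self):
        cds = cds_for(self.prot)
        runs = find_homopolymers(cds, 3)
        assert len(runs) >= 2
        r1, r2 = runs[0], runs[-1]
        # delete one base from each of two distant runs
        broken = cds[: r1.end - 1] + cds[r1.end : r2.end - 1] + cds[r2.end :]
        res = curate_sequence(rec(broken), self.prot, P)
        assert res.status == "corrected"
        assert len(res.edits) == 2
        assert self.prot in translate(res.corrected_seq, 0)

    def test_edit_positions_refer_to_original_sequence(self):
        cds = cds_for(self.prot)
        run = find_homopolymers(cds, 3)[0]
        broken = cds[: run.end - 1] + cds[run.end :]
        res = curate_sequence(rec(broken), self.prot, P)
        assert res.status == "corrected"
        assert apply_edits(broken, res.edits) == res.corrected_seq

    def test_unanchorable_indel_needs_manual(self):
        cds = "ACGT" * 12
        prot = translate(cds, 0)
        broken = cds[:24] + cds[25:]
        res = curate_sequence(rec(broken), prot, P, anchor_window=10)
        assert res.status == "needs_manual" and res.edits == ()

    def test_idempotent_on_corrected_output(self):
        cds = cds_for(self.prot)
        run = find_homopolymers(cds, 3)[0]
        broken = cds[: run.end - 1] + cds[run.end :]
        first = curate_sequence(rec(broken), self.prot, P)
        assert first.status == "corrected"
        second = curate_sequence(rec(first.corrected_seq, id="t2"), self.prot, P)
        assert second.status == "clean" and second.edits == ()


class TestSimulatedGroundTruth:
    def test_single_indel_recovery(self, noisy_transcriptome):
        corrected = 0
        total = 0
        for nrec, ntruth in noisy_transcriptome:
            total += 1
            res = curate_sequence(nrec, ntruth.protein)
            if res.status == "corrected":
                assert any(
                    ntruth.protein in translate(res.corrected_seq, f) for f in range(3)
                )
                corrected += 1
            # every applied edit lies inside a homopolymer run
            for e in res.edits:
                runs = find_homopolymers(nrec.seq, 2)
                assert any(r.start <= e.position <= r.end for r in runs)
        assert corrected / total >= 0.9

    def test_no_false_edits_on_clean_transcripts(self, small_transcriptome):
        records, truths = small_transcriptome
        for r in records:
            res = curate_sequence(r, truths[r.id].protein)
            assert res.status == "clean" and res.edits == ()
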
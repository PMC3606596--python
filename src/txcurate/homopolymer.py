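"""Homology-guided correction of homopolymer indel errors.

Pyrosequencing miscounts homopolymer run lengths, producing single-base
insertions and deletions that disrupt the reading frame of assembled
transcripts.  Given a trusted reference protein (the transcript's best
annotation hit), the frameshift-aware aligner localises each disruption;
events that anchor to a nearby homopolymer run are repaired by inserting or
deleting one copy of the run's base, and everything else is deferred to
manual curation rather than guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from txcurate.framealign import (
    AlignParams,
    FrameAlignment,
    align_protein_dna,
    _codon_table,
)
from txcurate.io_formats import EditRecord, TranscriptRecord

__all__ = [
    "HomopolymerRun", "FrameshiftEvent", "CorrectionResult",
    "DetectionFailedError", "find_homopolymers", "detect_frameshifts",
    "correct_frameshifts", "curate_sequence",
]

DEFAULT_ANCHOR_WINDOW = 10
DEFAULT_MIN_RUN = 3
DEFAULT_MAX_ITER = 3


class DetectionFailedError(RuntimeError):
    """No alignment above the minimum score: frameshift status is unknowable
    (distinct from a confident zero-event result)."""


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one repeated base (0-based ``start``)."""

    start: int
    length: int
    base: str

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


@dataclass(frozen=True)
class FrameshiftEvent:
    """A localised reading-frame disruption.

    ``sense`` is ``undercall`` when the aligner consumed 2 nt for a residue
    (a base is missing, repair = insertion) and ``overcall`` for 4 nt
    (a base is extra, repair = deletion).
    """

    position: int
    sense: str  # "undercall" | "overcall"
    anchor: HomopolymerRun | None
    distance_to_anchor: int

    def __post_init__(self) -> None:
        if self.sense not in ("undercall", "overcall"):
            raise ValueError(f"bad sense {self.sense!r}")
        if self.distance_to_anchor < 0:
            raise ValueError("negative anchor distance")


@dataclass(frozen=True)
class CorrectionResult:
    original: TranscriptRecord
    corrected_seq: str
    edits: tuple[EditRecord, ...]
    status: str  # "clean" | "corrected" | "needs_manual"

    def __post_init__(self) -> None:
        if self.status not in ("clean", "corrected", "needs_manual"):
            raise ValueError(f"bad status {self.status!r}")


def find_homopolymers(seq: str, min_run: int = DEFAULT_MIN_RUN) -> list[HomopolymerRun]:
    """All maximal runs of length >= ``min_run``; N never forms a run."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = seq.upper()
    runs: list[HomopolymerRun] = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run and seq[i] in "ACGT":
            runs.append(HomopolymerRun(i, j - i, seq[i]))
        i = j
    return runs


def _interval_distance(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> int:
    """Gap between half-open intervals; 0 when they touch or overlap."""
    if a_hi <= b_lo:
        return b_lo - a_hi
    if b_hi <= a_lo:
        return a_lo - b_hi
    return 0


def _repair_edit(seq_id: str, sense: str, run: HomopolymerRun) -> EditRecord:
    if sense == "undercall":
        # insert one copy of the run base at the run's right edge
        return EditRecord(seq_id, run.end, "insertion", run.base)
    return EditRecord(seq_id, run.end - 1, "deletion", run.base)


def _events_from_alignment(
    seq: str,
    prot: str,
    params: AlignParams,
    aln: FrameAlignment,
    anchor_window: int,
    min_run: int,
) -> list[FrameshiftEvent]:
    # an undercall shortens the true run by one, so anchor candidates are
    # scanned at one below the nominal minimum run length
    runs = find_homopolymers(seq, max(2, min_run - 1))
    events: list[FrameshiftEvent] = []
    for op in aln.frameshift_ops:
        sense = "undercall" if op.nuc_len == 2 else "overcall"
        op_lo, op_hi = op.nuc_start, op.nuc_start + op.nuc_len
        cands: list[tuple[int, HomopolymerRun]] = []
        for run in runs:
            d = _interval_distance(op_lo, op_hi, run.start, run.end)
            if d <= anchor_window:
                cands.append((d, run))
        if not cands:
            events.append(FrameshiftEvent(op.nuc_start, sense, None, 0))
            continue
        if len(cands) == 1:
            d, run = cands[0]
        else:
            # the DP may place the frameshift op at any co-optimal codon
            # boundary near the true indel, so proximity alone cannot choose
            # between neighbouring runs: test each candidate repair and keep
            # the one whose realignment scores best
            from txcurate.io_formats import apply_edits

            scored = []
            for d, run in sorted(cands, key=lambda c: (c[0], -c[1].length, c[1].start)):
                trial = apply_edits(seq, [_repair_edit("trial", sense, run)])
                s = align_protein_dna(trial, prot, params).score
                scored.append((-s, d, -run.length, run.start, run))
            scored.sort()
            d, run = scored[0][1], scored[0][4]
        events.append(FrameshiftEvent(op.nuc_start, sense, run, d))
    events.sort(key=lambda e: e.position)
    return events


def _alignment_is_continuous(seq: str, aln: FrameAlignment) -> bool:
    if aln.frameshift_ops:
        return False
    table = _codon_table()
    for k, op in enumerate(aln.ops):
        if op.nuc_len == 3:
            aa = table.get(seq[op.nuc_start : op.nuc_start + 3], "X")
            if aa == "*" and k < len(aln.ops) - 1:
                return False
    return True


def detect_frameshifts(
    record: TranscriptRecord,
    prot: str,
    params: AlignParams | None = None,
    anchor_window: int = DEFAULT_ANCHOR_WINDOW,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[FrameshiftEvent]:
    """Frameshift ops of the optimal alignment, each anchored to the nearest
    homopolymer run within ``anchor_window`` nt (anchor None otherwise).

    Raises :class:`DetectionFailedError` when the alignment scores below
    ``params.min_score`` — the protein does not support the transcript and
    no statement about frameshifts can be made.
    """
    params = params or AlignParams()
    aln = align_protein_dna(record.seq, prot, params)
    if aln.score < params.min_score:
        raise DetectionFailedError(
            f"{record.id}: alignment score {aln.score} below {params.min_score}"
        )
    return _events_from_alignment(record.seq, prot, params, aln, anchor_window, min_run)


def _edits_for_events(
    seq_id: str, events: Sequence[FrameshiftEvent]
) -> list[EditRecord] | None:
    """Edit list for fully anchored, conflict-free events; None otherwise."""
    seen_runs: set[tuple[int, int, str]] = set()
    edits: list[EditRecord] = []
    for ev in events:
        if ev.anchor is None:
            return None
        key = (ev.anchor.start, ev.anchor.length, ev.anchor.base)
        if key in seen_runs:  # two events over one run: ambiguous
            return None
        seen_runs.add(key)
        edits.append(_repair_edit(seq_id, ev.sense, ev.anchor))
    return edits


def _apply_edits_tracked(
    seq: str, orig_of: list[int], edits: Sequence[EditRecord]
) -> tuple[str, list[int], list[EditRecord]]:
    """Apply current-coordinate edits right-to-left while translating their
    positions back to original coordinates via ``orig_of``."""
    chars = list(seq)
    mapped: list[EditRecord] = []
    for e in sorted(edits, key=lambda e: -e.position):
        if e.op == "insertion":
            orig_pos = orig_of[e.position] if e.position < len(orig_of) else (
                orig_of[-1] + 1 if orig_of else 0
            )
            chars.insert(e.position, e.base)
            orig_of.insert(e.position, orig_pos)
            mapped.append(EditRecord(e.seq_id, orig_pos, "insertion", e.base))
        else:
            orig_pos = orig_of[e.position]
            mapped.append(EditRecord(e.seq_id, orig_pos, "deletion", chars[e.position]))
            del chars[e.position]
            del orig_of[e.position]
    return "".join(chars), orig_of, mapped


def correct_frameshifts(
    record: TranscriptRecord, events: Sequence[FrameshiftEvent]
) -> CorrectionResult:
    """Apply one round of single-base repairs for anchored events.

    Any unanchored event, or two events contending for one run, defers the
    whole sequence to manual curation with *no* edits applied.
    """
    if not events:
        return CorrectionResult(record, record.seq, (), "clean")
    edits = _edits_for_events(record.id, events)
    if edits is None:
        return CorrectionResult(record, record.seq, (), "needs_manual")
    from txcurate.io_formats import apply_edits

    corrected = apply_edits(record.seq, edits)
    return CorrectionResult(
        record, corrected, tuple(sorted(edits, key=lambda e: e.position)), "corrected"
    )


def curate_sequence(
    record: TranscriptRecord,
    prot: str,
    params: AlignParams | None = None,
    anchor_window: int = DEFAULT_ANCHOR_WINDOW,
    min_run: int = DEFAULT_MIN_RUN,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CorrectionResult:
    """Iterate detect -> correct -> verify until the ORF is continuous.

    Returns status ``clean`` (already continuous, no edits), ``corrected``
    (continuous after edits; edit positions refer to the ORIGINAL sequence),
    or ``needs_manual``.  Raises :class:`DetectionFailedError` if the
    reference protein never aligns above ``params.min_score``.
    """
    params = params or AlignParams()
    seq = record.seq
    orig_of = list(range(len(seq)))
    all_edits: list[EditRecord] = []

    rounds = 0
    while True:
        aln = align_protein_dna(seq, prot, params)
        if aln.score < params.min_score:
            raise DetectionFailedError(
                f"{record.id}: alignment score {aln.score} below {params.min_score}"
            )
        if _alignment_is_continuous(seq, aln):
            status = "clean" if not all_edits else "corrected"
            return CorrectionResult(record, seq, tuple(all_edits), status)
        if rounds >= max_iter:
            return CorrectionResult(record, seq, tuple(all_edits), "needs_manual")
        events = _events_from_alignment(seq, prot, params, aln, anchor_window, min_run)
        if not events:  # discontinuous (internal stop) but no frameshift op
            return CorrectionResult(record, seq, tuple(all_edits), "needs_manual")
        cur_edits = _edits_for_events(record.id, events)
        if cur_edits is None:
            return CorrectionResult(record, seq, tuple(all_edits), "needs_manual")
        seq, orig_of, mapped = _apply_edits_tracked(seq, orig_of, cur_edits)
        all_edits.extend(mapped)
        rounds += 1
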
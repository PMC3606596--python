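"""Pre-annotation cleaning: polyA trimming, entropy masking, contaminant
screening and the strict length filter.

The cleaning pass mirrors the standard EST/454 curation sequence — mask
low-complexity stretches, strip polyA/polyT tails, drop contaminants and
everything at or below the length cutoff — with simple, fully specified
primitives: Shannon-entropy window masking and exact k-mer contaminant
matching.  All thresholds are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from txcurate.io_formats import TranscriptRecord

__all__ = [
    "CleanReport", "trim_polya", "mask_low_complexity",
    "screen_contaminants", "filter_by_length", "clean_records",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CleanReport:
    """Accounting of one cleaning pass.

    Invariant: ``n_retained = n_input - n_removed_short - n_removed_contaminant``.
    """

    n_input: int
    n_removed_short: int
    n_removed_contaminant: int
    n_masked: int
    n_retained: int

    def __post_init__(self) -> None:
        counts = (self.n_input, self.n_removed_short, self.n_removed_contaminant,
                  self.n_masked, self.n_retained)
        if any(c < 0 for c in counts):
            raise ValueError("negative count in CleanReport")
        if self.n_retained != (
            self.n_input - self.n_removed_short - self.n_removed_contaminant
        ):
            raise ValueError("CleanReport counts do not reconcile")


def trim_polya(record: TranscriptRecord, min_tail: int = 10) -> TranscriptRecord:
    """Strip a terminal polyA run (3' end) or polyT run (5' end) of length
    >= ``min_tail``.

    PolyT at the 5' end handles reverse-complemented deposits.  Internal runs
    are untouched; the operation is idempotent.  A record trimmed to nothing
    comes back with sequence "N" and ``source`` unchanged — zero-length
    sequences are not representable, so the caller drops it via the length
    filter (any cutoff >= 1 removes it).
    """
    if min_tail < 1:
        raise ValueError("min_tail must be >= 1")
    seq = record.seq
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    if n - i >= min_tail:
        seq = seq[:i]
    j = 0
    while j < len(seq) and seq[j] == "T":
        j += 1
    if j >= min_tail:
        seq = seq[j:]
    if seq == record.seq:
        return record
    if not seq:
        seq = "N"  # placeholder; removed downstream by any length filter
    return replace(record, seq=seq)


def _window_entropy(counts: dict[str, int], size: int) -> float:
    # N carries no information: it is excluded from the sum while the
    # denominator stays the window size, so N-rich windows score low.
    h = 0.0
    for base in "ACGT":
        c = counts[base]
        if c:
            p = c / size
            h -= p * math.log2(p)
    return h


def _mask_pass(seq: str, window: int, entropy_bits: float) -> str:
    n = len(seq)
    if n < window:
        return seq
    mask = bytearray(n)
    counts = {b: 0 for b in "ACGTN"}
    for b in seq[:window]:
        counts[b] += 1
    lo = 0
    while True:
        if _window_entropy(counts, window) < entropy_bits:
            for k in range(lo, lo + window):
                mask[k] = 1
        if lo + window >= n:
            break
        counts[seq[lo]] -= 1
        counts[seq[lo + window]] += 1
        lo += 1
    if not any(mask):
        return seq
    return "".join("N" if m else b for b, m in zip(seq, mask))


def mask_low_complexity(
    record: TranscriptRecord, window: int = 12, entropy_bits: float = 1.0
) -> TranscriptRecord:
    """Replace with N every position covered by a window whose mononucleotide
    Shannon entropy is strictly below ``entropy_bits``.

    Sequence length is unchanged.  A two-symbol equifrequent window has
    entropy exactly 1 bit and therefore survives the default threshold
    (strict ``<``).  Masking runs to a fixpoint — newly introduced N lowers
    the information content of overlapping windows, and iterating until the
    mask stabilises makes the operation idempotent.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    seq = record.seq
    while True:
        nxt = _mask_pass(seq, window, entropy_bits)
        if nxt == seq:
            break
        seq = nxt
    if seq == record.seq:
        return record
    return replace(record, seq=seq)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_contaminant_index(
    contaminants: Iterable[TranscriptRecord], k: int = 21
) -> set[str]:
    """K-mer set over both strands of the contaminant sequences."""
    index: set[str] = set()
    for rec in contaminants:
        index |= _kmers(rec.seq, k)
        index |= _kmers(revcomp(rec.seq), k)
    return index


def screen_contaminants(
    record: TranscriptRecord,
    contaminants: Iterable[TranscriptRecord] | set[str],
    k: int = 21,
    frac: float = 0.5,
) -> bool:
    """True iff >= ``frac`` of the record's k-mers occur in the contaminant
    k-mer set (both contaminant strands indexed).

    ``contaminants`` may be records or a prebuilt index from
    :func:`build_contaminant_index`.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    index = (
        contaminants
        if isinstance(contaminants, set)
        else build_contaminant_index(contaminants, k)
    )
    kmers = _kmers(record.seq, k)
    if not kmers:
        warnings.warn(
            f"{record.id}: shorter than k={k}, cannot screen", stacklevel=2
        )
        return False
    shared = sum(1 for km in kmers if km in index)
    return shared / len(kmers) >= frac


def filter_by_length(
    records: Sequence[TranscriptRecord], min_exclusive: int = 100
) -> tuple[list[TranscriptRecord], CleanReport]:
    """Retain records strictly longer than ``min_exclusive`` bases."""
    retained = [r for r in records if len(r.seq) > min_exclusive]
    report = CleanReport(
        n_input=len(records),
        n_removed_short=len(records) - len(retained),
        n_removed_contaminant=0,
        n_masked=0,
        n_retained=len(retained),
    )
    return retained, report


def clean_records(
    records: Sequence[TranscriptRecord],
    contaminants: Sequence[TranscriptRecord] = (),
    min_exclusive: int = 100,
    min_tail: int = 10,
    window: int = 12,
    entropy_bits: float = 1.0,
    k: int = 21,
    frac: float = 0.5,
) -> tuple[list[TranscriptRecord], CleanReport]:
    """Full cleaning pass: trim polyA, mask low complexity, drop contaminants,
    apply the strict length filter.  Idempotent on its own output."""
    index = build_contaminant_index(contaminants, k) if contaminants else set()
    kept: list[TranscriptRecord] = []
    n_contaminant = 0
    n_masked = 0
    n_short = 0
    for rec in records:
        trimmed = trim_polya(rec, min_tail)
        rec2 = mask_low_complexity(trimmed, window, entropy_bits)
        if rec2.seq != trimmed.seq:
            n_masked += 1
        if index and len(rec2.seq) >= k and screen_contaminants(rec2, index, k, frac):
            n_contaminant += 1
            continue
        if len(rec2.seq) > min_exclusive:
            kept.append(rec2)
        else:
            n_short += 1
    report = CleanReport(
        n_input=len(records),
        n_removed_short=n_short,
        n_removed_contaminant=n_contaminant,
        n_masked=n_masked,
        n_retained=len(kept),
    )
    return kept, report
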
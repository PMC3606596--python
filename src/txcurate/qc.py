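"""Cross-species annotation quality control.

The check emulates the classic database-validation exercise: sample
transcripts from a well-annotated reference species, search each against the
newly curated database by translated alignment, and tally how often an
annotated reference transcript finds a database sequence carrying the same
annotation (and how often an unannotated one finds any confident hit at
all).  High recovery of reference annotations indicates broad protein-coding
coverage of the new database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from txcurate.framealign import AlignParams, align_protein_dna, translate
from txcurate.io_formats import ProteinHit, TranscriptRecord
from txcurate.preprocess import revcomp

__all__ = ["QCReport", "crosscheck_annotations", "qc_rates", "longest_orf_protein"]

DEFAULT_QC_EVALUE = 1e-9
DEFAULT_QC_MIN_SCORE = 50.0
_SEED_K = 11
_MAX_CANDIDATES = 5


@dataclass(frozen=True)
class QCReport:
    """Tallies of one cross-annotation check."""

    n_sampled: int
    n_annotated: int
    n_matched: int
    n_unannotated: int
    n_recovered: int
    evalue_max: float

    def __post_init__(self) -> None:
        if self.n_annotated + self.n_unannotated != self.n_sampled:
            raise ValueError("annotated + unannotated must equal sampled")
        if not (0 <= self.n_matched <= self.n_annotated):
            raise ValueError("n_matched out of range")
        if not (0 <= self.n_recovered <= self.n_unannotated):
            raise ValueError("n_recovered out of range")


def _normalize_description(desc: str) -> str:
    return " ".join(desc.split()).casefold()


def longest_orf_protein(seq: str) -> str:
    """Longest stop-free translation over all six reading frames.

    Used to give each database transcript a protein surrogate for the
    translated QC search.
    """
    best = ""
    for strand_seq in (seq, revcomp(seq)):
        for frame in (0, 1, 2):
            aa = translate(strand_seq, frame)
            for piece in aa.split("*"):
                if len(piece) > len(best):
                    best = piece
    return best


def _kmer_set(seq: str, k: int = _SEED_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _best_internal_hit(
    query: TranscriptRecord,
    db_records: Sequence[TranscriptRecord],
    db_proteins: Mapping[str, str],
    db_kmers: Mapping[str, set[str]],
    params: AlignParams,
) -> tuple[str, float] | None:
    """Best-scoring database id by translated local alignment, with a
    shared-k-mer prefilter standing in for a search seed stage."""
    qk = _kmer_set(query.seq) | _kmer_set(revcomp(query.seq))
    scored = []
    for rec in db_records:
        shared = len(qk & db_kmers[rec.id])
        if shared:
            scored.append((shared, rec.id))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], t[1]))
    best: tuple[float, str] | None = None
    for _, rid in scored[:_MAX_CANDIDATES]:
        prot = db_proteins[rid]
        if not prot:
            continue
        score = max(
            align_protein_dna(query.seq, prot, params).score,
            align_protein_dna(revcomp(query.seq), prot, params).score,
        )
        # ties broken by score desc, then database id lexicographic
        if best is None or score > best[0] or (score == best[0] and rid < best[1]):
            best = (score, rid)
    if best is None or best[0] < params.min_score:
        return None
    return best[1], best[0]


def crosscheck_annotations(
    reference: Sequence[TranscriptRecord],
    database: Sequence[TranscriptRecord],
    ref_annotations: Mapping[str, str],
    db_annotations: Mapping[str, str],
    n_sample: int,
    seed: int,
    evalue_max: float = DEFAULT_QC_EVALUE,
    params: AlignParams | None = None,
    hits: Sequence[ProteinHit] | None = None,
    by: str = "description",
) -> QCReport:
    """Sample ``n_sample`` reference transcripts and tally annotation
    agreement against the database.

    ``ref_annotations``/``db_annotations`` map record ids to description
    strings; ids absent from ``ref_annotations`` count as unannotated.
    With ``hits`` given (a precomputed translated-search table whose
    subject accessions are database ids), hits with ``evalue <= evalue_max``
    are used; otherwise an internal translated local alignment against each
    database record's longest-ORF protein decides, thresholded at
    ``params.min_score``.

    An annotated sample is *matched* when the best hit's database record
    shares its annotation (normalized description equality by default;
    ``by="accession"`` compares raw labels verbatim).  An unannotated sample
    is *recovered* when any hit passes the threshold.
    """
    if not database:
        raise ValueError("empty database")
    if n_sample > len(reference):
        raise ValueError("n_sample exceeds reference size")
    params = params or AlignParams(
        mode="local", min_score=DEFAULT_QC_MIN_SCORE
    )

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reference), size=n_sample, replace=False)
    sampled = [reference[int(i)] for i in sorted(idx)]

    hit_index: dict[str, list[ProteinHit]] = {}
    if hits is not None:
        for h in hits:
            if h.evalue <= evalue_max:
                hit_index.setdefault(h.query_id, []).append(h)
    else:
        db_proteins = {r.id: longest_orf_protein(r.seq) for r in database}
        db_kmers = {
            r.id: _kmer_set(r.seq) | _kmer_set(revcomp(r.seq)) for r in database
        }

    norm = (lambda s: s) if by == "accession" else _normalize_description

    n_annotated = n_matched = n_unannotated = n_recovered = 0
    for rec in sampled:
        if hits is not None:
            cand = hit_index.get(rec.id, [])
            top = (
                min(cand, key=lambda h: (h.evalue, -h.similarity, h.subject_accession))
                if cand
                else None
            )
            top_id = top.subject_accession if top else None
        else:
            found = _best_internal_hit(rec, database, db_proteins, db_kmers, params)
            top_id = found[0] if found else None

        ref_desc = ref_annotations.get(rec.id)
        if ref_desc is not None:
            n_annotated += 1
            if top_id is not None:
                db_desc = db_annotations.get(top_id)
                if db_desc is not None and norm(db_desc) == norm(ref_desc):
                    n_matched += 1
        else:
            n_unannotated += 1
            if top_id is not None:
                n_recovered += 1

    return QCReport(
        n_sampled=n_sample,
        n_annotated=n_annotated,
        n_matched=n_matched,
        n_unannotated=n_unannotated,
        n_recovered=n_recovered,
        evalue_max=evalue_max,
    )


def qc_rates(
    report: QCReport, display: bool = False
) -> tuple[float, float | None, float | None]:
    """(annotated %, matched-of-annotated %, recovered-of-unannotated %).

    Machine output is rounded to one decimal; ``display=True`` rounds to the
    nearest integer.  Undefined rates (zero denominator) come back as None.
    """
    if report.n_sampled == 0:
        raise ValueError("empty report")

    def _fmt(num: int, den: int) -> float | None:
        if den == 0:
            return None
        pct = num / den * 100.0
        return float(round(pct)) if display else round(pct, 1)

    annotated = _fmt(report.n_annotated, report.n_sampled)
    assert annotated is not None
    return (
        annotated,
        _fmt(report.n_matched, report.n_annotated),
        _fmt(report.n_recovered, report.n_unannotated),
    )
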
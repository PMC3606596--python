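"""Best-hit annotation assignment under an E-value cutoff.

A query is annotated with the hit of highest similarity among those passing
the E-value threshold (default 1e-5).  Ties are resolved by lower E-value,
then lexicographically smaller subject accession, so the assignment is a
pure function of the hit *set*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from txcurate.io_formats import ProteinHit

__all__ = ["Annotation", "assign_annotation", "annotate_all"]

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class Annotation:
    query_id: str
    accession: str
    description: str
    best_hit: ProteinHit


def assign_annotation(
    hits: Sequence[ProteinHit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> Annotation | None:
    """Pick the annotation for one query, or None if no hit survives.

    All hits must share a query id.  Survivors (``evalue <= evalue_max``)
    are ranked by similarity descending, E-value ascending, accession
    ascending; the top hit wins.
    """
    if not hits:
        return None
    qids = {h.query_id for h in hits}
    if len(qids) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(qids)}")
    survivors = [h for h in hits if h.evalue <= evalue_max]
    if not survivors:
        return None
    best = min(
        survivors, key=lambda h: (-h.similarity, h.evalue, h.subject_accession)
    )
    return Annotation(
        query_id=best.query_id,
        accession=best.subject_accession,
        description=best.description,
        best_hit=best,
    )


def annotate_all(
    hits: Iterable[ProteinHit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> dict[str, Annotation]:
    """Assign annotations per query over a mixed hit table."""
    by_query: dict[str, list[ProteinHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, Annotation] = {}
    for qid, group in by_query.items():
        ann = assign_annotation(group, evalue_max)
        if ann is not None:
            out[qid] = ann
    return out
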
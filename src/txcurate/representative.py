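"""Redundancy clustering and representative-sequence selection.

Transcripts sharing one annotation description are clustered at high
nucleotide identity (single linkage, default > 95%), and within each cluster
representatives are retained greedily by a composite score — the product of
normalized HSP query coverage, HSP subject coverage, similarity, reciprocal
E-value and assembly depth — keeping additionally any member that covers a
distinct (non-overlapping) region of the mapped subject protein or that is
essentially complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align

from txcurate.annotate import Annotation
from txcurate.io_formats import ProteinHit, TranscriptRecord

__all__ = [
    "RepresentativeScore", "AnnotationCluster",
    "score_algorithm1", "pairwise_identity",
    "cluster_by_annotation", "select_representatives",
    "curate_redundancy",
]

DEFAULT_EVALUE_FLOOR = 1e-180
DEFAULT_IDENTITY_MIN = 95.0
DEFAULT_OVERLAP_MAX = 0.2
DEFAULT_COMPLETE_COV = 95.0


@dataclass(frozen=True)
class RepresentativeScore:
    """Composite representativeness score of one annotated transcript.

    ``value = (Qcov/100) * (Scov/100) * (Sim/100) * (1/E) * depth`` with the
    E-value clamped from below at ``evalue_floor`` so exact zeros stay
    finite and order is preserved.
    """

    hsp_query_cov: float
    hsp_hit_cov: float
    similarity: float
    evalue: float
    depth: float
    value: float


def score_algorithm1(
    hit: ProteinHit, depth: float, evalue_floor: float = DEFAULT_EVALUE_FLOOR
) -> RepresentativeScore:
    """Score one best hit together with its transcript's assembly depth."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if evalue_floor <= 0:
        raise ValueError("evalue_floor must be positive")
    e = max(hit.evalue, evalue_floor)
    value = (
        (hit.hsp_query_cov / 100.0)
        * (hit.hsp_hit_cov / 100.0)
        * (hit.similarity / 100.0)
        * (1.0 / e)
        * depth
    )
    return RepresentativeScore(
        hsp_query_cov=hit.hsp_query_cov,
        hsp_hit_cov=hit.hsp_hit_cov,
        similarity=hit.similarity,
        evalue=hit.evalue,
        depth=depth,
        value=value,
    )


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free terminal gaps: containment costs nothing
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    else:  # older biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _nucleotide_aligner()


def pairwise_identity(
    a: TranscriptRecord | str,
    b: TranscriptRecord | str,
    denominator: str = "shorter",
) -> float:
    """Percent identity of a global alignment with free terminal gaps.

    With the default ``shorter`` denominator an exact fragment of a longer
    transcript scores 100 — the behaviour the redundancy filter needs.
    ``denominator="alignment"`` divides by aligned columns instead.
    """
    sa = a.seq if isinstance(a, TranscriptRecord) else a.upper()
    sb = b.seq if isinstance(b, TranscriptRecord) else b.upper()
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(sa, sb)[0]
    counts = aln.counts()
    matches = counts.identities
    if denominator == "shorter":
        denom = min(len(sa), len(sb))
    elif denominator == "alignment":
        denom = counts.identities + counts.mismatches + counts.gaps
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return matches / denom * 100.0


@dataclass(frozen=True)
class AnnotationCluster:
    """A same-description redundancy cluster.

    ``prot_intervals`` maps member id to its 1-based inclusive interval on
    the mapped subject protein; ``retained_ids`` is filled by
    :func:`select_representatives` (clusters are born retaining everything).
    """

    description: str
    member_ids: frozenset[str]
    retained_ids: frozenset[str]
    prot_intervals: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("empty cluster")
        if not self.retained_ids or not self.retained_ids <= self.member_ids:
            raise ValueError("retained_ids must be a non-empty subset of members")


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_by_annotation(
    records: Sequence[TranscriptRecord],
    annotations: Mapping[str, Annotation],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    denominator: str = "shorter",
) -> list[AnnotationCluster]:
    """Single-linkage clusters of annotated records sharing a description
    at pairwise identity strictly above ``identity_min``.

    Unannotated records are ignored; each unclustered record forms a
    singleton.  Output is a partition of the annotated ids, independent of
    input order (clusters sorted by smallest member id).
    """
    by_desc: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        ann = annotations.get(rec.id)
        if ann is None:
            continue
        by_desc.setdefault(ann.description, []).append(rec)

    clusters: list[AnnotationCluster] = []
    for desc in sorted(by_desc):
        group = sorted(by_desc[desc], key=lambda r: r.id)
        uf = _UnionFind(r.id for r in group)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                ident = pairwise_identity(group[i], group[j], denominator)
                if ident > identity_min:
                    uf.union(group[i].id, group[j].id)
        comps: dict[str, set[str]] = {}
        for r in group:
            comps.setdefault(uf.find(r.id), set()).add(r.id)
        for comp in comps.values():
            intervals = {
                rid: (
                    annotations[rid].best_hit.subject_start,
                    annotations[rid].best_hit.subject_end,
                )
                for rid in comp
            }
            clusters.append(
                AnnotationCluster(
                    description=desc,
                    member_ids=frozenset(comp),
                    retained_ids=frozenset(comp),
                    prot_intervals=intervals,
                )
            )
    clusters.sort(key=lambda c: min(c.member_ids))
    return clusters


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap of two 1-based inclusive intervals as a fraction of the
    shorter one."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    ov = max(0, hi - lo + 1)
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return ov / shorter


def select_representatives(
    cluster: AnnotationCluster,
    scores: Mapping[str, RepresentativeScore],
    overlap_max: float = DEFAULT_OVERLAP_MAX,
    complete_min_cov: float = DEFAULT_COMPLETE_COV,
) -> frozenset[str]:
    """Greedy retention by descending score.

    The top scorer is always kept; a further member is kept iff it covers
    >= ``complete_min_cov`` percent of the subject protein ("complete"), or
    its protein interval overlaps every already-retained interval by less
    than ``overlap_max`` of the shorter interval.
    """
    if not cluster.member_ids:
        raise ValueError("empty cluster")
    missing = cluster.member_ids - set(scores)
    if missing:
        raise ValueError(f"unscored members: {sorted(missing)}")
    order = sorted(cluster.member_ids, key=lambda i: (-scores[i].value, i))
    retained: list[str] = [order[0]]
    for rid in order[1:]:
        if scores[rid].hsp_hit_cov >= complete_min_cov:
            retained.append(rid)
            continue
        iv = cluster.prot_intervals[rid]
        if all(
            _overlap_fraction(iv, cluster.prot_intervals[r]) < overlap_max
            for r in retained
        ):
            retained.append(rid)
    return frozenset(retained)


def curate_redundancy(
    records: Sequence[TranscriptRecord],
    annotations: Mapping[str, Annotation],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    overlap_max: float = DEFAULT_OVERLAP_MAX,
    evalue_floor: float = DEFAULT_EVALUE_FLOOR,
) -> tuple[list[AnnotationCluster], frozenset[str]]:
    """Cluster annotated records and select representatives in one pass.

    Returns the clusters (with ``retained_ids`` filled in) and the union of
    all retained ids.
    """
    depth_of = {r.id: r.depth for r in records}
    scores = {
        rid: score_algorithm1(ann.best_hit, depth_of.get(rid, 1.0), evalue_floor)
        for rid, ann in annotations.items()
    }
    raw = cluster_by_annotation(records, annotations, identity_min)
    clusters: list[AnnotationCluster] = []
    kept: set[str] = set()
    for cl in raw:
        retained = select_representatives(cl, scores, overlap_max)
        clusters.append(
            AnnotationCluster(cl.description, cl.member_ids, retained, cl.prot_intervals)
        )
        kept |= retained
    return clusters, frozenset(kept)
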
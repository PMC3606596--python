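"""Assembly summary statistics, frameshift tallies and pathway enrichment.

Enrichment uses the one-sided Fisher exact (hypergeometric upper-tail) test:
given a query gene set of size ``n`` drawn from a universe of ``N`` genes of
which ``K`` belong to a pathway, the p-value is ``P(X >= k)`` for the
observed overlap ``k`` under sampling without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from txcurate.homopolymer import CorrectionResult
from txcurate.io_formats import TranscriptRecord

__all__ = [
    "AssemblyStats", "summarize_assembly", "frameshift_tally",
    "FrameshiftTally", "fisher_enrichment", "enrich_pathways",
]

DEFAULT_BIN_STEP = 250
DEFAULT_BIN_MAX = 3000
SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    n_contigs: int
    n_singletons: int
    mean_length: float
    mean_depth: float
    bin_edges: tuple[float, ...]           # last bin open-ended
    bin_counts: tuple[int, ...]
    bin_counts_annotated: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.bin_counts) != self.n_sequences:
            raise ValueError("histogram does not reconcile with n_sequences")
        if self.n_contigs + self.n_singletons != self.n_sequences:
            raise ValueError("contigs + singletons must equal n_sequences")


def summarize_assembly(
    records: Sequence[TranscriptRecord],
    annotations: Mapping[str, object] | None = None,
    bin_step: int = DEFAULT_BIN_STEP,
    bin_max: int = DEFAULT_BIN_MAX,
) -> AssemblyStats:
    """Counts, means and an annotated/non-annotated length histogram.

    Bins run every ``bin_step`` nt up to ``bin_max``, then one open-ended
    bin.  ``external`` records count with contigs.
    """
    annotations = annotations or {}
    n = len(records)
    lengths = np.array([len(r.seq) for r in records], dtype=float)
    depths = np.array([r.depth for r in records], dtype=float)
    singles = sum(1 for r in records if r.source == "singleton")

    edges = list(range(0, bin_max + 1, bin_step))
    n_bins = len(edges)  # edges[i]..edges[i+1], final bin open-ended
    counts = [0] * n_bins
    counts_ann = [0] * n_bins
    for r in records:
        L = len(r.seq)
        b = min(L // bin_step, n_bins - 1) if bin_step > 0 else 0
        counts[b] += 1
        if r.id in annotations:
            counts_ann[b] += 1

    return AssemblyStats(
        n_sequences=n,
        n_contigs=n - singles,
        n_singletons=singles,
        mean_length=float(lengths.mean()) if n else 0.0,
        mean_depth=float(depths.mean()) if n else 0.0,
        bin_edges=tuple(float(e) for e in edges),
        bin_counts=tuple(counts),
        bin_counts_annotated=tuple(counts_ann),
    )


@dataclass(frozen=True)
class FrameshiftTally:
    n_annotated_checked: int
    n_with_frameshift: int
    n_corrected: int
    n_manual: int
    pct_with_frameshift: float

    def __post_init__(self) -> None:
        if self.n_with_frameshift != self.n_corrected + self.n_manual:
            raise ValueError("frameshift tally does not reconcile")


def frameshift_tally(results: Sequence[CorrectionResult]) -> FrameshiftTally:
    """Aggregate correction outcomes over the checked annotated sequences.

    ``pct_with_frameshift`` is in percent; display convention is nearest
    integer.
    """
    n = len(results)
    n_corrected = sum(1 for r in results if r.status == "corrected")
    n_manual = sum(1 for r in results if r.status == "needs_manual")
    n_fs = n_corrected + n_manual
    return FrameshiftTally(
        n_annotated_checked=n,
        n_with_frameshift=n_fs,
        n_corrected=n_corrected,
        n_manual=n_manual,
        pct_with_frameshift=(n_fs / n * 100.0) if n else 0.0,
    )


def fisher_enrichment(
    hit_in_pathway: int,
    set_size: int,
    pathway_size: int,
    universe: int,
    two_sided: bool = False,
) -> float:
    """Fisher exact enrichment p-value.

    One-sided (default): ``P(X >= hit_in_pathway)`` with X hypergeometric
    (``universe`` genes, ``pathway_size`` in the pathway, ``set_size``
    drawn).  ``two_sided=True`` sums the probabilities of all tables at most
    as probable as the observed one.
    """
    if not (0 <= hit_in_pathway <= min(set_size, pathway_size)):
        raise ValueError("hit count exceeds set or pathway size")
    if pathway_size > universe or set_size > universe:
        raise ValueError("pathway/set larger than universe")
    if hit_in_pathway < set_size - (universe - pathway_size):
        raise ValueError("hit count below the feasible minimum")
    rv = hypergeom(universe, pathway_size, set_size)
    if not two_sided:
        return float(rv.sf(hit_in_pathway - 1))
    p_obs = rv.pmf(hit_in_pathway)
    ks = np.arange(max(0, set_size - (universe - pathway_size)),
                   min(set_size, pathway_size) + 1)
    pmf = rv.pmf(ks)
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())


def enrich_pathways(
    gene_set: Sequence[str],
    pathways: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    alpha: float = SIGNIFICANCE_ALPHA,
    two_sided: bool = False,
    fdr: bool = False,
) -> list[dict]:
    """Per-pathway Fisher enrichment of ``gene_set`` within ``universe``.

    Returns one row per pathway (sorted by p) with the overlap count, p-value
    and a significance flag at ``alpha``.  ``fdr=True`` adds
    Benjamini-Hochberg adjusted p-values and flags on those instead.
    """
    uni = set(universe)
    genes = set(gene_set) & uni
    rows: list[dict] = []
    for pid, members in pathways.items():
        path = set(members) & uni
        k = len(genes & path)
        p = fisher_enrichment(k, len(genes), len(path), len(uni), two_sided)
        rows.append(
            {"pathway": pid, "hits": k, "pathway_size": len(path),
             "set_size": len(genes), "universe": len(uni), "p_value": p}
        )
    rows.sort(key=lambda r: (r["p_value"], r["pathway"]))
    if fdr:
        m = len(rows)
        qs = []
        running = 1.0
        for rank, row in reversed(list(enumerate(rows, 1))):
            running = min(running, row["p_value"] * m / rank)
            qs.append(running)
        for row, q in zip(rows, reversed(qs)):
            row["q_value"] = q
            row["significant"] = q <= alpha
    else:
        for row in rows:
            row["significant"] = row["p_value"] <= alpha
    return rows
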
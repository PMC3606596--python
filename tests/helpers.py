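"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic program and scipy: the
aligner oracle enumerates every legal operation sequence recursively, and
the Fisher oracle evaluates the hypergeometric tail from binomial
coefficients directly.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

_BLM = substitution_matrices.load("BLOSUM62")
_TABLE = dict(unambiguous_dna_by_id[1].forward_table)
for _stop in unambiguous_dna_by_id[1].stop_codons:
    _TABLE[_stop] = "*"


def _aa(codon: str) -> str:
    return _TABLE.get(codon, "X")


def _fs2_score(two: str, res: str) -> float:
    """Best substitution over all single-base completions of a 2-nt codon."""
    best = -math.inf
    for b in "ACGT":
        for codon in (b + two, two[0] + b + two[1], two + b):
            best = max(best, _BLM[_aa(codon), res])
    return best


def _fs4_score(four: str, res: str) -> float:
    """Best substitution over all single-base drops of a 4-nt codon."""
    return max(
        _BLM[_aa(four[:k] + four[k + 1 :]), res] for k in range(4)
    )


def brute_force_align_score(
    nuc: str,
    prot: str,
    mode: str = "semiglobal",
    F: float = -12.0,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    codon_gap: float = -11.0,
) -> float:
    """Optimal score by exhaustive enumeration of op sequences.

    Ops consume (3 nt, 1 res) scored by BLOSUM62, (2 or 4 nt, 1 res) scored
    F plus the best-completion substitution, (0 nt, 1 res) affine residue
    gap, (3 nt, 0 res) flat codon gap.
    ``semiglobal``: full protein, free nucleotide ends.  ``local``: free
    clipping on both (score floored at 0).  ``global``: everything consumed.
    """
    n, m = len(nuc), len(prot)
    best = -math.inf

    def rec(i: int, j: int, score: float, in_gap: bool) -> None:
        nonlocal best
        if j == m:
            if mode == "global":
                rest = n - i
                if rest % 3 == 0:
                    cand = score + codon_gap * (rest // 3)
                    best = max(best, cand)
            else:
                best = max(best, score)
            if mode != "global":
                return
        if j < m:
            if i + 3 <= n:
                rec(i + 3, j + 1, score + _BLM[_aa(nuc[i : i + 3]), prot[j]], False)
            if i + 2 <= n:
                rec(i + 2, j + 1, score + F + _fs2_score(nuc[i : i + 2], prot[j]), False)
            if i + 4 <= n:
                rec(i + 4, j + 1, score + F + _fs4_score(nuc[i : i + 4], prot[j]), False)
            rec(i, j + 1, score + (gap_extend if in_gap else gap_open), True)
            if i + 3 <= n:
                rec(i + 3, j, score + codon_gap, False)

    if mode == "local":
        return brute_force_local_score(nuc, prot)
    if mode == "global":
        for lead in range(0, n + 1, 3):
            rec(lead, 0, codon_gap * (lead // 3), False)
    else:
        for start in range(n + 1):
            rec(start, 0, 0.0, False)
    return best


_LOCAL_BEST = [0.0]


def _local(nuc, prot, i, j, score, in_gap,
           F=-12.0, gap_open=-11.0, gap_extend=-1.0, codon_gap=-11.0):
    _LOCAL_BEST[0] = max(_LOCAL_BEST[0], score)
    n, m = len(nuc), len(prot)
    if j < m:
        if i + 3 <= n:
            _local(nuc, prot, i + 3, j + 1,
                   score + _BLM[_aa(nuc[i : i + 3]), prot[j]], False)
        if i + 2 <= n:
            _local(nuc, prot, i + 2, j + 1,
                   score + F + _fs2_score(nuc[i : i + 2], prot[j]), False)
        if i + 4 <= n:
            _local(nuc, prot, i + 4, j + 1,
                   score + F + _fs4_score(nuc[i : i + 4], prot[j]), False)
        _local(nuc, prot, i, j + 1, score + (gap_extend if in_gap else gap_open), True)
        if i + 3 <= n:
            _local(nuc, prot, i + 3, j, score + codon_gap, False)


def brute_force_local_score(nuc: str, prot: str) -> float:
    _LOCAL_BEST[0] = 0.0
    for start in range(len(nuc) + 1):
        for j0 in range(len(prot)):
            _local(nuc, prot, start, j0, 0.0, False)
    return _LOCAL_BEST[0]


def fisher_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n), from binomial coefficients."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def fisher_by_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by literal enumeration of all C(N, n) draws (tiny N only)."""
    from itertools import combinations

    hits = 0
    total = 0
    pathway = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(pathway.intersection(draw)) >= k:
            hits += 1
    return hits / total
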
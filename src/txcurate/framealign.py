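"""Frameshift-aware protein-to-DNA alignment.

The aligner scores a nucleotide sequence against a trusted protein with a
dynamic program in which one protein residue may be encoded by a 3-nt codon
(substitution-matrix score), or — at a frameshift penalty on top of the
best-completion substitution — by 2 nt (a base lost from the read, an
*undercall*) or 4 nt (a base gained, an *overcall*).  Codons may also be skipped (3 nt against no residue) and
residues may align to nothing (affine gap).  Frameshift ops in the optimal
traceback localise reading-frame disruptions at single-nucleotide
resolution, which is exactly what homology-guided indel correction needs.

Two modes are provided: ``semiglobal`` (the full protein must be aligned,
nucleotide ends are free — the default for correction, where the reference
protein is trusted end to end) and ``local`` (Smith-Waterman-style free
clipping on both sequences, used for QC search).

All scores are integer-valued, so DP cell comparisons are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "AlignParams", "FrameOp", "FrameAlignment",
    "translate", "align_protein_dna", "verify_orf_continuity",
    "AlignmentError",
]

NEG_INF = float(-1e18)

_PROT_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_PROT_INDEX = {aa: i for i, aa in enumerate(_PROT_ALPHABET)}


class AlignmentError(ValueError):
    """Invalid aligner input."""


@lru_cache(maxsize=1)
def _codon_table() -> dict[str, str]:
    table = unambiguous_dna_by_id[1]
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = "*"
    return codons


@lru_cache(maxsize=4)
def _matrix_array(name: str) -> np.ndarray:
    """Substitution matrix as a dense array over ``_PROT_ALPHABET``."""
    mat = substitution_matrices.load(name)
    arr = np.zeros((len(_PROT_ALPHABET), len(_PROT_ALPHABET)))
    for i, a in enumerate(_PROT_ALPHABET):
        for j, b in enumerate(_PROT_ALPHABET):
            arr[i, j] = mat[a, b]
    return arr


_BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@lru_cache(maxsize=4)
def _frameshift_tables(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Best-completion substitution rows for 2-nt and 4-nt codons.

    A frameshift codon still emits a residue: a 2-nt codon is scored as the
    best substitution over the 12 codons obtained by inserting one base at
    any position, a 4-nt codon over the 4 codons obtained by dropping one
    base (both on top of the flat frameshift penalty).  Windows containing N
    fall back to the X row.
    """
    blm = _matrix_array(name)
    table = _codon_table()
    x_row = blm[_PROT_INDEX["X"]]

    t2 = np.zeros((25, len(_PROT_ALPHABET)))
    for i1, b1 in enumerate(_BASES):
        for i2, b2 in enumerate(_BASES):
            code = i1 * 5 + i2
            if "N" in (b1, b2):
                t2[code] = x_row
                continue
            rows = []
            for b in "ACGT":
                for codon in (b + b1 + b2, b1 + b + b2, b1 + b2 + b):
                    rows.append(blm[_PROT_INDEX[table.get(codon, "X")]])
            t2[code] = np.max(rows, axis=0)

    t4 = np.zeros((625, len(_PROT_ALPHABET)))
    for code in range(625):
        digits = [(code // 125) % 5, (code // 25) % 5, (code // 5) % 5, code % 5]
        quad = "".join(_BASES[d] for d in digits)
        if "N" in quad:
            t4[code] = x_row
            continue
        rows = []
        for drop in range(4):
            codon = quad[:drop] + quad[drop + 1 :]
            rows.append(blm[_PROT_INDEX[table.get(codon, "X")]])
        t4[code] = np.max(rows, axis=0)
    return t2, t4


def translate(seq: str, frame: int = 0) -> str:
    """Translate ``seq`` in reading frame 0, 1 or 2 with the standard code.

    Codons containing N yield ``X``; stops are ``*``; a trailing partial
    codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise AlignmentError(f"frame must be 0, 1 or 2, got {frame}")
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise AlignmentError("nucleotide sequence contains invalid characters")
    table = _codon_table()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(table.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for the frameshift-aware DP.

    A 2- or 4-nt frameshift codon still emits its residue: it scores the
    ``frameshift`` penalty plus the best substitution over the codon's
    single-base completions (2 nt) or single-base drops (4 nt), so a lone
    frameshift inside an otherwise good alignment costs about the penalty
    net of the recovered substitution and is preferred over abandoning the
    downstream alignment.
    ``gap_open``/``gap_extend`` are the affine penalties for residues
    aligned to no nucleotides; ``codon_gap`` is the flat per-codon penalty
    for 3 nt aligned to no residue.
    """

    matrix: str = "BLOSUM62"
    frameshift: float = -12.0
    gap_open: float = -11.0
    gap_extend: float = -1.0
    codon_gap: float = -11.0
    mode: Literal["semiglobal", "local", "global"] = "semiglobal"
    min_score: float = 50.0


@dataclass(frozen=True)
class FrameOp:
    """One alignment operation consuming ``nuc_len`` in {0,2,3,4} nucleotides
    and ``prot_len`` in {0,1} residues, starting at ``nuc_start`` /
    ``prot_start`` (0-based)."""

    nuc_start: int
    nuc_len: int
    prot_start: int
    prot_len: int

    @property
    def is_frameshift(self) -> bool:
        return self.nuc_len in (2, 4)


@dataclass(frozen=True)
class FrameAlignment:
    """Optimal frameshift-aware alignment with its traceback."""

    score: float
    ops: tuple[FrameOp, ...]
    nuc_span: tuple[int, int]   # 0-based half-open
    prot_span: tuple[int, int]  # 0-based half-open

    @property
    def frameshift_ops(self) -> tuple[FrameOp, ...]:
        return tuple(op for op in self.ops if op.is_frameshift)

    def __post_init__(self) -> None:
        nuc_used = sum(op.nuc_len for op in self.ops)
        prot_used = sum(op.prot_len for op in self.ops)
        if nuc_used != self.nuc_span[1] - self.nuc_span[0]:
            raise ValueError("ops do not tile the nucleotide span")
        if prot_used != self.prot_span[1] - self.prot_span[0]:
            raise ValueError("ops do not tile the protein span")


def _encode_protein(prot: str) -> np.ndarray:
    try:
        return np.array([_PROT_INDEX[a] for a in prot.upper()], dtype=np.intp)
    except KeyError as exc:
        raise AlignmentError(f"invalid amino acid {exc.args[0]!r}") from exc


def _codon_aa_index(nuc: str) -> np.ndarray:
    """aa index of the codon *ending* at nucleotide offset i, for i in 0..N
    (entries for i < 3 are the index of X; callers mask them out)."""
    table = _codon_table()
    n = len(nuc)
    idx = np.full(n + 1, _PROT_INDEX["X"], dtype=np.intp)
    for i in range(3, n + 1):
        idx[i] = _PROT_INDEX[table.get(nuc[i - 3 : i], "X")]
    return idx


def _shift(row: np.ndarray, by: int) -> np.ndarray:
    """row[i - by] with NEG_INF where i < by."""
    out = np.full_like(row, NEG_INF)
    if by == 0:
        return row.copy()
    out[by:] = row[:-by]
    return out


def _codon_gap_accumulate(cand: np.ndarray, cg: float) -> np.ndarray:
    """H[i] = max(cand[i], H[i-3] + cg) solved per stride-3 phase."""
    out = cand.copy()
    n = cand.shape[0]
    for phase in range(min(3, n)):
        v = out[phase::3]
        t = np.arange(v.shape[0], dtype=np.float64)
        a = v - cg * t
        np.maximum.accumulate(a, out=a)
        out[phase::3] = a + cg * t
    return out


def _window_codes(nuc: str) -> tuple[np.ndarray, np.ndarray]:
    """Base-5 codes of the 2-nt and 4-nt windows *ending* at offset i."""
    n = len(nuc)
    b = np.array([_BASE_INDEX[c] for c in nuc], dtype=np.intp)
    pair = np.zeros(n + 1, dtype=np.intp)
    quad = np.zeros(n + 1, dtype=np.intp)
    if n >= 2:
        pair[2:] = b[:-1] * 5 + b[1:]
    if n >= 4:
        quad[4:] = b[:-3] * 125 + b[1:-2] * 25 + b[2:-1] * 5 + b[3:]
    return pair, quad


def _dp_matrices(
    nuc: str, prot: str, params: AlignParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fill the H (best) and Iy (residue-gap) matrices."""
    n, m = len(nuc), len(prot)
    blm = _matrix_array(params.matrix)
    t2, t4 = _frameshift_tables(params.matrix)
    pair, quad = _window_codes(nuc)
    aa_idx = _codon_aa_index(nuc)
    prot_idx = _encode_protein(prot)
    local = params.mode == "local"

    H = np.full((m + 1, n + 1), NEG_INF)
    Iy = np.full((m + 1, n + 1), NEG_INF)
    if params.mode == "global":
        # leading nucleotides must be consumed by whole-codon gaps
        H[0, 0] = 0.0
        H[0, 3::3] = params.codon_gap * np.arange(1, n // 3 + 1)
    else:
        H[0, :] = 0.0  # free leading nucleotides

    F = params.frameshift
    for j in range(1, m + 1):
        prev = H[j - 1]
        Iy[j] = np.maximum(prev + params.gap_open, Iy[j - 1] + params.gap_extend)
        pj = prot_idx[j - 1]
        cand = _shift(prev, 3) + blm[aa_idx, pj]
        np.maximum(cand, _shift(prev, 2) + F + t2[pair, pj], out=cand)
        np.maximum(cand, _shift(prev, 4) + F + t4[quad, pj], out=cand)
        np.maximum(cand, Iy[j], out=cand)
        if local:
            np.maximum(cand, 0.0, out=cand)
        H[j] = _codon_gap_accumulate(cand, params.codon_gap)
    return H, Iy, aa_idx, prot_idx


def align_protein_dna(
    nuc: str, prot: str, params: AlignParams | None = None
) -> FrameAlignment:
    """Optimal frameshift-aware alignment of ``nuc`` against ``prot``.

    Ties are broken during traceback toward fewer frameshift ops, then fewer
    gaps, then leftmost: at equal score a codon match is preferred over a
    residue gap, over a codon gap, over a 2-nt and finally a 4-nt frameshift.
    """
    params = params or AlignParams()
    nuc = nuc.upper()
    prot = prot.upper()
    if not nuc or not prot:
        raise AlignmentError("both sequences must be non-empty")
    if set(nuc) - set("ACGTN"):
        raise AlignmentError("nucleotide sequence contains invalid characters")

    H, Iy, aa_idx, prot_idx = _dp_matrices(nuc, prot, params)
    n, m = len(nuc), len(prot)
    local = params.mode == "local"

    if local:
        j, i = np.unravel_index(int(np.argmax(H)), H.shape)
        score = float(H[j, i])
    elif params.mode == "global":
        i, j = n, m
        score = float(H[m, n])
        if score <= NEG_INF / 2:
            raise AlignmentError(
                "no global alignment exists for these sequence lengths"
            )
    else:
        i = int(np.argmax(H[m]))
        j = m
        score = float(H[m, i])

    blm = _matrix_array(params.matrix)
    t2, t4 = _frameshift_tables(params.matrix)
    pair, quad = _window_codes(nuc)
    F = params.frameshift
    ops: list[FrameOp] = []
    end = (int(i), int(j))
    state = "H"
    while j > 0:
        if local and state == "H" and H[j, i] == 0.0:
            break
        if state == "H":
            val = H[j, i]
            pj = prot_idx[j - 1]
            sub = blm[aa_idx[i], pj] if i >= 3 else NEG_INF
            if i >= 3 and val == H[j - 1, i - 3] + sub:
                ops.append(FrameOp(i - 3, 3, j - 1, 1))
                i, j = i - 3, j - 1
            elif val == Iy[j, i]:
                state = "Iy"
            elif i >= 3 and val == H[j, i - 3] + params.codon_gap:
                ops.append(FrameOp(i - 3, 3, j, 0))
                i -= 3
            elif i >= 2 and val == H[j - 1, i - 2] + F + t2[pair[i], pj]:
                ops.append(FrameOp(i - 2, 2, j - 1, 1))
                i, j = i - 2, j - 1
            elif i >= 4 and val == H[j - 1, i - 4] + F + t4[quad[i], pj]:
                ops.append(FrameOp(i - 4, 4, j - 1, 1))
                i, j = i - 4, j - 1
            else:  # pragma: no cover - DP invariant
                raise AssertionError("traceback failed to reproduce DP value")
        else:  # Iy: the residue j-1 aligns to zero nucleotides
            val = Iy[j, i]
            ops.append(FrameOp(i, 0, j - 1, 1))
            if val == H[j - 1, i] + params.gap_open:
                state = "H"
            elif val != Iy[j - 1, i] + params.gap_extend:  # pragma: no cover
                raise AssertionError("traceback failed in gap state")
            j -= 1

    if params.mode == "global":
        while i >= 3:  # leading whole-codon gaps down to the origin
            ops.append(FrameOp(i - 3, 3, 0, 0))
            i -= 3
    ops.reverse()
    start = (int(i), int(j))
    return FrameAlignment(
        score=score,
        ops=tuple(ops),
        nuc_span=(start[0], end[0]),
        prot_span=(start[1], end[1]),
    )


def verify_orf_continuity(
    nuc: str, prot: str, params: AlignParams | None = None
) -> bool:
    """True iff the optimal alignment is frameshift-free and its aligned
    region translates without an internal stop codon."""
    params = params or AlignParams()
    aln = align_protein_dna(nuc, prot, params)
    if aln.frameshift_ops:
        return False
    table = _codon_table()
    seq = nuc.upper()
    for k, op in enumerate(aln.ops):
        if op.nuc_len != 3:
            continue
        aa = table.get(seq[op.nuc_start : op.nuc_start + 3], "X")
        # a stop is internal unless it is the very last aligned codon
        if aa == "*" and k < len(aln.ops) - 1:
            return False
    return True
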
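"""On-disk formats: FASTA with per-contig depth, tabular hit tables, edit logs.

All internal coordinates are 0-based half-open.  Tabular hit files use the
standard 1-based inclusive convention of BLAST ``-outfmt 6``; conversion to
internal conventions happens exactly once, at parse time (and subject-protein
coordinates, which stay 1-based inclusive as in the source format, are
documented as such on :class:`ProteinHit`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "TranscriptRecord", "ProteinHit", "EditRecord",
    "FormatError", "DuplicateIdError",
    "read_fasta", "write_fasta", "read_length_table",
    "read_protein_fasta", "write_protein_fasta",
    "read_hit_table", "write_edit_log", "read_edit_log",
    "apply_edits",
]

_VALID_NUC = set("ACGTN")
_DEPTH_RE = re.compile(r"\bdepth=([0-9.eE+-]+)")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class DuplicateIdError(FormatError):
    """Two records in one collection share an identifier."""


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled contig or singleton.

    Parameters
    ----------
    id : str
        Whitespace-free identifier, unique within a collection.
    seq : str
        Nucleotide sequence over ``{A,C,G,T,N}``; stored uppercase.
    depth : float
        Assembly depth (reads per contig); singletons carry 1.0.
    source : str
        One of ``contig``, ``singleton``, ``external``.
    """

    id: str
    seq: str
    depth: float = 1.0
    source: str = "contig"

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise ValueError(f"record id must be a whitespace-free token: {self.id!r}")
        seq = self.seq.upper()
        if len(seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - _VALID_NUC
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "seq", seq)
        if not (self.depth >= 1.0):
            raise ValueError(f"{self.id}: depth must be >= 1, got {self.depth}")
        if self.source not in ("contig", "singleton", "external"):
            raise ValueError(f"{self.id}: unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinHit:
    """One homology hit (HSP) of a nucleotide query against a protein subject.

    ``subject_start``/``subject_end`` are 1-based inclusive protein
    coordinates, as in tabular BLAST output.  Coverage and similarity are
    percentages in [0, 100].
    """

    query_id: str
    subject_accession: str
    description: str
    hsp_query_cov: float
    hsp_hit_cov: float
    similarity: float
    evalue: float
    subject_start: int
    subject_end: int
    query_frame: int = 1

    def __post_init__(self) -> None:
        for name in ("hsp_query_cov", "hsp_hit_cov", "similarity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} out of [0,100]: {v}")
        if self.evalue < 0 or math.isnan(self.evalue):
            raise ValueError(f"negative E-value: {self.evalue}")
        if not (1 <= self.subject_start <= self.subject_end):
            raise ValueError(
                f"bad subject interval [{self.subject_start},{self.subject_end}]"
            )
        if self.query_frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"bad query frame {self.query_frame}")


@dataclass(frozen=True, order=True)
class EditRecord:
    """A single-nucleotide edit, positioned on the ORIGINAL sequence.

    ``position`` is a 0-based offset into the sequence the edit applies to.
    ``insertion`` inserts ``base`` before that offset (so position may equal
    the sequence length, meaning append); ``deletion`` removes the base at
    that offset.
    """

    seq_id: str
    position: int
    op: Literal["insertion", "deletion"]
    base: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if self.op not in ("insertion", "deletion"):
            raise ValueError(f"unknown op {self.op!r}")
        if self.base not in ("A", "C", "G", "T"):
            raise ValueError(f"base must be one of ACGT, got {self.base!r}")


def apply_edits(seq: str, edits: Sequence[EditRecord]) -> str:
    """Apply edits whose positions all refer to ``seq``.

    Edits are applied right-to-left so earlier applications cannot shift the
    coordinates of later ones.
    """
    out = seq
    for e in sorted(edits, key=lambda e: (-e.position, e.op)):
        if e.op == "insertion":
            if e.position > len(out):
                raise ValueError(f"insertion beyond sequence end: {e}")
            out = out[: e.position] + e.base + out[e.position:]
        else:
            if e.position >= len(seq):
                raise ValueError(f"deletion beyond sequence end: {e}")
            out = out[: e.position] + out[e.position + 1 :]
    return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, source: str = "contig") -> list[TranscriptRecord]:
    """Read transcripts from FASTA; ``depth=<float>`` in headers is honoured.

    Missing depth defaults to 1.0.  Raises :class:`FormatError` with the
    offending line number on malformed input, :class:`DuplicateIdError` on
    repeated identifiers.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        name = header.split()[0] if header.split() else ""
        if not name:
            raise FormatError(f"{path}:{header_line}: empty FASTA header")
        if name in seen:
            raise DuplicateIdError(f"{path}:{header_line}: duplicate id {name!r}")
        seen.add(name)
        m = _DEPTH_RE.search(header)
        depth = float(m.group(1)) if m else 1.0
        seq = "".join(chunks)
        try:
            records.append(TranscriptRecord(name, seq, depth, source))
        except ValueError as exc:
            raise FormatError(f"{path}:{header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before any header")
                bad = set(line.upper()) - _VALID_NUC
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid characters {sorted(bad)}"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(
    records: Iterable[TranscriptRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA, embedding depth in each header.

    Round-trips with :func:`read_fasta` losslessly (ids, sequences, depths).
    """
    if width < 1:
        raise ValueError("width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} depth={rec.depth!r}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_length_table(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>length`` companion table."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return lengths


_VALID_AA = set("ARNDCQEGHILKMFPSTWYVBZX*U")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping (uppercased)."""
    path = Path(path)
    out: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in out:
                    raise DuplicateIdError(f"{path}:{lineno}: duplicate id {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence before any header")
                up = line.upper()
                bad = set(up) - _VALID_AA
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid amino acids {sorted(bad)}"
                    )
                chunks.append(up)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_protein_fasta(
    proteins: dict[str, str], path: str | Path, width: int = 60
) -> None:
    """Write an id -> protein mapping as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hit tables

_TAB12_NCOL = 12
_TAB12EXT_NCOL = 16


def read_hit_table(
    path: str | Path,
    dialect: Literal["tab12", "tab12ext"] = "tab12ext",
    lengths: dict[str, int] | None = None,
) -> list[ProteinHit]:
    """Parse a tabular hit file into :class:`ProteinHit` records.

    ``tab12`` is the standard 12-column tabular format (query, subject,
    %identity, length, mismatches, gapopens, qstart, qend, sstart, send,
    evalue, bitscore); HSP coverages are then computed from the alignment
    spans and a companion ``lengths`` table covering every query and subject
    id, and similarity falls back to %identity.  ``tab12ext`` appends four
    columns: hsp_query_cov, hsp_hit_cov, similarity, description.
    """
    if dialect not in ("tab12", "tab12ext"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncol = _TAB12_NCOL if dialect == "tab12" else _TAB12EXT_NCOL
    if dialect == "tab12" and lengths is None:
        raise ValueError("tab12 dialect requires a companion length table")

    hits: list[ProteinHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncol} columns, got {len(parts)}"
                )
            try:
                (qid, sid, pident, _length, _mm, _go,
                 qstart, qend, sstart, send, evalue, _bits) = parts[:12]
                pident_f = float(pident)
                qstart_i, qend_i = int(qstart), int(qend)
                sstart_i, send_i = int(sstart), int(send)
                evalue_f = float(evalue)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if evalue_f < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value {evalue_f}")

            # minus-strand hits arrive with qstart > qend; keep the span,
            # flag the frame
            frame = 1 if qstart_i <= qend_i else -1
            qlo, qhi = sorted((qstart_i, qend_i))
            slo, shi = sorted((sstart_i, send_i))

            if dialect == "tab12":
                assert lengths is not None
                for key in (qid, sid):
                    if key not in lengths:
                        raise FormatError(
                            f"{path}:{lineno}: id {key!r} missing from length table"
                        )
                qcov = (qhi - qlo + 1) / lengths[qid] * 100.0
                scov = (shi - slo + 1) / lengths[sid] * 100.0
                sim = pident_f
                desc = sid
            else:
                try:
                    qcov = float(parts[12])
                    scov = float(parts[13])
                    sim = float(parts[14])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
                desc = parts[15]
            try:
                hits.append(
                    ProteinHit(
                        query_id=qid,
                        subject_accession=sid,
                        description=desc,
                        hsp_query_cov=qcov,
                        hsp_hit_cov=scov,
                        similarity=sim,
                        evalue=evalue_f,
                        subject_start=slo,
                        subject_end=shi,
                        query_frame=frame,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Edit logs

_EDIT_HEADER = "seq_id\tposition\top\tbase"


def write_edit_log(edits: Iterable[EditRecord], path: str | Path) -> None:
    """Write edits as a tab-separated log, sorted by (seq_id, position)."""
    with open(path, "w") as fh:
        fh.write(_EDIT_HEADER + "\n")
        for e in sorted(edits, key=lambda e: (e.seq_id, e.position)):
            fh.write(f"{e.seq_id}\t{e.position}\t{e.op}\t{e.base}\n")


def read_edit_log(path: str | Path) -> list[EditRecord]:
    """Read an edit log written by :func:`write_edit_log`."""
    edits: list[EditRecord] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first and first != _EDIT_HEADER:
            raise FormatError(f"{path}:1: unexpected header {first!r}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                edits.append(
                    EditRecord(parts[0], int(parts[1]), parts[2], parts[3])  # type: ignore[arg-type]
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return edits
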
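"""Synthetic 454-style transcript simulator with full ground truth.

The generator emulates the features of a pyrosequencing transcriptome that
the curation stages consume: transcripts carrying a single ORF flanked by
UTRs, run-length-dependent homopolymer indel errors (the dominant 454 error
mode, biased toward undercalls), redundant partial homolog fragments for the
clustering/selection stages, and a diverged sister-species transcript set
for annotation QC.  Every stochastic step is driven by an explicit seed and
every introduced edit is recorded, so clean + recorded edits always
reproduces the noisy sequence exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from txcurate.io_formats import EditRecord, ProteinHit, TranscriptRecord, apply_edits
from txcurate.homopolymer import find_homopolymers

__all__ = [
    "SimTruth", "generate_transcriptome", "apply_454_noise",
    "fragmentize", "mutate_homologs", "make_hits",
]

DEFAULT_LAMBDA_HP = 0.05
UNDERCALL_PROB = 0.7  # 454 undercalls dominate over overcalls
DEFAULT_MEDIAN_PROT = 250
DEFAULT_SIGMA_PROT = 0.35
MIN_PROT_LEN = 60
UTR_MIN, UTR_MAX = 20, 200

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _codon_choices() -> dict[str, list[str]]:
    table = unambiguous_dna_by_id[1]
    choices: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        choices.setdefault(aa, []).append(codon)
    choices["*"] = sorted(table.stop_codons)
    for aa in choices:
        choices[aa].sort()
    return choices

_CODONS = _codon_choices()


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated transcript.

    ``edits`` transform ``clean_seq`` into the record's (possibly noisy)
    sequence; ``cds_start``/``cds_end`` are 0-based half-open on the clean
    sequence and include the terminal stop codon.
    """

    gene_id: str
    description: str
    protein: str
    cds_start: int
    cds_end: int
    depth: float
    clean_seq: str
    edits: tuple[EditRecord, ...] = ()
    # 0-based half-open residue interval of ``protein`` covered by the CDS
    prot_start: int = 0
    prot_end: int = -1

    def __post_init__(self) -> None:
        if self.prot_end < 0:
            object.__setattr__(self, "prot_end", len(self.protein))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.integers(0, len(_AA20), size=length - 1)
    return "M" + "".join(_AA20[i] for i in body)


def _back_translate(rng: np.random.Generator, prot: str) -> str:
    codons = [
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in prot
    ]
    codons.append(_CODONS["*"][rng.integers(0, 3)])
    return "".join(codons)


def _random_nuc(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def generate_transcriptome(
    n_genes: int,
    seed: int,
    median_prot: int = DEFAULT_MEDIAN_PROT,
    sigma_prot: float = DEFAULT_SIGMA_PROT,
    polya_prob: float = 0.0,
    depth_median: float = 20.0,
    depth_sigma: float = 0.8,
) -> tuple[list[TranscriptRecord], dict[str, SimTruth]]:
    """Simulate clean transcripts, one ORF each.

    Protein lengths are lognormal (median ``median_prot`` aa); each CDS is a
    random-codon back-translation (start M, terminal stop, no internal stop)
    flanked by uniform 20-200 nt UTRs; with probability ``polya_prob`` a
    polyA tail is appended.  Depths are lognormal with median
    ``depth_median``.  Fully deterministic given the seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    truths: dict[str, SimTruth] = {}
    for g in range(n_genes):
        plen = max(MIN_PROT_LEN, int(round(rng.lognormal(math.log(median_prot), sigma_prot))))
        prot = _random_protein(rng, plen)
        cds = _back_translate(rng, prot)
        utr5 = _random_nuc(rng, int(rng.integers(UTR_MIN, UTR_MAX + 1)))
        utr3 = _random_nuc(rng, int(rng.integers(UTR_MIN, UTR_MAX + 1)))
        if rng.random() < polya_prob:
            utr3 += "A" * int(rng.integers(12, 31))
        seq = utr5 + cds + utr3
        depth = max(1.0, float(rng.lognormal(math.log(depth_median), depth_sigma)))
        gid = f"g{g:05d}"
        desc = f"hypothetical protein {gid}"
        records.append(TranscriptRecord(gid, seq, depth, "contig"))
        truths[gid] = SimTruth(
            gene_id=gid,
            description=desc,
            protein=prot,
            cds_start=len(utr5),
            cds_end=len(utr5) + len(cds),
            depth=depth,
            clean_seq=seq,
        )
    return records, truths


def apply_454_noise(
    record: TranscriptRecord,
    truth: SimTruth,
    lambda_hp: float = DEFAULT_LAMBDA_HP,
    seed: int = 0,
    min_run: int = 2,
    cds_only: bool = False,
) -> tuple[TranscriptRecord, SimTruth]:
    """Introduce run-length-dependent homopolymer indels.

    Each maximal run of length ``L >= min_run`` independently receives one
    indel with probability ``1 - exp(-lambda_hp * (L - 1))``; the indel is an
    undercall (base deleted) with probability 0.7, an overcall (base
    inserted) otherwise.  ``cds_only`` restricts errors to runs inside the
    CDS.  Edits are recorded in clean-sequence coordinates.
    """
    if lambda_hp < 0:
        raise ValueError("lambda_hp must be >= 0")
    rng = np.random.default_rng(seed)
    edits: list[EditRecord] = []
    for run in find_homopolymers(truth.clean_seq, min_run=min_run):
        if cds_only and not (
            truth.cds_start <= run.start and run.end <= truth.cds_end
        ):
            continue
        p = 1.0 - math.exp(-lambda_hp * (run.length - 1))
        if rng.random() >= p:
            continue
        if rng.random() < UNDERCALL_PROB:
            edits.append(EditRecord(record.id, run.end - 1, "deletion", run.base))
        else:
            edits.append(EditRecord(record.id, run.end, "insertion", run.base))
    noisy_seq = apply_edits(truth.clean_seq, edits)
    new_truth = replace(truth, edits=tuple(sorted(edits, key=lambda e: e.position)))
    return replace(record, seq=noisy_seq), new_truth


def apply_single_indel(
    record: TranscriptRecord,
    truth: SimTruth,
    seed: int = 0,
    min_run: int = 3,
) -> tuple[TranscriptRecord, SimTruth] | None:
    """Introduce exactly one homopolymer indel in a random run of length
    >= ``min_run`` strictly inside the CDS (the controlled error scenario
    used for parameter-recovery checks).

    Returns None when the transcript has no eligible run.
    """
    rng = np.random.default_rng(seed)
    runs = [
        r
        for r in find_homopolymers(truth.clean_seq, min_run=min_run)
        if truth.cds_start <= r.start and r.end <= truth.cds_end - 3
    ]
    if not runs:
        return None
    run = runs[int(rng.integers(0, len(runs)))]
    if rng.random() < UNDERCALL_PROB:
        edit = EditRecord(record.id, run.end - 1, "deletion", run.base)
    else:
        edit = EditRecord(record.id, run.end, "insertion", run.base)
    noisy_seq = apply_edits(truth.clean_seq, [edit])
    new_truth = replace(truth, edits=(edit,))
    return replace(record, seq=noisy_seq), new_truth


def fragmentize(
    record: TranscriptRecord,
    truth: SimTruth,
    k_fragments: int,
    mutation_rate: float = 0.0,
    seed: int = 0,
    min_len: int = 150,
) -> tuple[list[TranscriptRecord], list[SimTruth]]:
    """Emit ``k_fragments`` partial copies of one transcript.

    Fragments take random coordinates (>= ``min_len`` nt when the parent
    allows), point mutations at ``mutation_rate``, log-uniform depths in
    [1, 50], and inherit the parent's description — fodder for the
    redundancy clustering and representative-selection stages.
    """
    if k_fragments < 1:
        raise ValueError("k_fragments must be >= 1")
    if not (0 <= mutation_rate <= 0.1):
        raise ValueError("mutation_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    n = len(truth.clean_seq)
    frag_len_min = min(min_len, n)
    out_records: list[TranscriptRecord] = []
    out_truths: list[SimTruth] = []
    for j in range(k_fragments):
        length = int(rng.integers(frag_len_min, n + 1))
        start = int(rng.integers(0, n - length + 1))
        sub = list(truth.clean_seq[start : start + length])
        n_mut = rng.binomial(length, mutation_rate)
        for pos in rng.choice(length, size=n_mut, replace=False):
            alt = "ACGT".replace(sub[pos], "")
            sub[pos] = alt[rng.integers(0, 3)]
        depth = float(np.exp(rng.uniform(0.0, math.log(50.0))))
        fid = f"{record.id}.f{j}"
        seq = "".join(sub)
        ov_lo = max(truth.cds_start, start)
        ov_hi = min(truth.cds_end, start + length)
        if ov_hi > ov_lo:
            prot_lo = (ov_lo - truth.cds_start) // 3
            prot_hi = min(len(truth.protein), (ov_hi - truth.cds_start) // 3)
        else:
            ov_lo = ov_hi = start
            prot_lo = prot_hi = 0
        out_records.append(TranscriptRecord(fid, seq, max(1.0, depth), "contig"))
        out_truths.append(
            SimTruth(
                gene_id=fid,
                description=truth.description,
                protein=truth.protein,
                cds_start=max(0, ov_lo - start),
                cds_end=max(0, ov_hi - start),
                depth=max(1.0, depth),
                clean_seq=seq,
                prot_start=prot_lo,
                prot_end=max(prot_lo, prot_hi),
            )
        )
    return out_records, out_truths


def mutate_homologs(
    records: Sequence[TranscriptRecord],
    truths: Mapping[str, SimTruth],
    protein_identity: float = 0.85,
    seed: int = 0,
    unannotated_fraction: float = 0.29,
    id_suffix: str = "_hom",
) -> tuple[list[TranscriptRecord], dict[str, SimTruth], dict[str, str]]:
    """Build a diverged sister-species transcript set.

    Each protein receives nonsynonymous substitutions (never the initial M)
    until the target identity is reached, the CDS is re-encoded with random
    synonymous codons, and fresh UTRs are attached.  A
    ``unannotated_fraction`` of the outputs is stripped of its annotation
    label, emulating unannotated consortium transcripts; the returned
    mapping holds descriptions for the annotated remainder only.
    """
    if not (0.5 < protein_identity <= 1.0):
        raise ValueError("protein_identity must be in (0.5, 1]")
    rng = np.random.default_rng(seed)
    out_records: list[TranscriptRecord] = []
    out_truths: dict[str, SimTruth] = {}
    annotations: dict[str, str] = {}
    ids = [r.id for r in records]
    n_strip = int(round(unannotated_fraction * len(ids)))
    stripped = set(
        rng.choice(len(ids), size=n_strip, replace=False).tolist()
    ) if n_strip else set()

    for k, rec in enumerate(records):
        truth = truths[rec.id]
        prot = list(truth.protein)
        n_sub = int(round((1.0 - protein_identity) * (len(prot) - 1)))
        if n_sub:
            pos = rng.choice(np.arange(1, len(prot)), size=n_sub, replace=False)
            for p in pos:
                alt = _AA20.replace(prot[p], "")
                prot[p] = alt[rng.integers(0, len(alt))]
        new_prot = "".join(prot)
        cds = _back_translate(rng, new_prot)
        utr5 = _random_nuc(rng, int(rng.integers(UTR_MIN, UTR_MAX + 1)))
        utr3 = _random_nuc(rng, int(rng.integers(UTR_MIN, UTR_MAX + 1)))
        seq = utr5 + cds + utr3
        hid = rec.id + id_suffix
        out_records.append(TranscriptRecord(hid, seq, 1.0, "external"))
        out_truths[hid] = SimTruth(
            gene_id=hid,
            description=truth.description,
            protein=new_prot,
            cds_start=len(utr5),
            cds_end=len(utr5) + len(cds),
            depth=1.0,
            clean_seq=seq,
        )
        if k not in stripped:
            annotations[hid] = truth.description
    return out_records, out_truths, annotations


def make_hits(
    truths: Mapping[str, SimTruth],
    evalue_per_aa: float = 0.5,
    similarity: float = 98.0,
) -> list[ProteinHit]:
    """Best-hit table derived from ground truth, for pipeline-stage tests.

    Each transcript hits its own reference protein over the protein interval
    its CDS covers; the E-value shrinks exponentially with the aligned
    length (floored at 1e-180) so longer fragments score better, as real
    search statistics would give.
    """
    hits: list[ProteinHit] = []
    for tid, truth in truths.items():
        cds_len = truth.cds_end - truth.cds_start
        aa_len = truth.prot_end - truth.prot_start
        if cds_len < 9 or aa_len < 3:
            continue
        s_start, s_end = truth.prot_start + 1, truth.prot_end
        qcov = min(100.0, cds_len / len(truth.clean_seq) * 100.0)
        scov = min(100.0, aa_len / len(truth.protein) * 100.0)
        evalue = 10.0 ** (-min(180.0, evalue_per_aa * aa_len))
        hits.append(
            ProteinHit(
                query_id=tid,
                subject_accession=f"ref|{truth.description.split()[-1]}",
                description=truth.description,
                hsp_query_cov=qcov,
                hsp_hit_cov=scov,
                similarity=similarity,
                evalue=evalue,
                subject_start=s_start,
                subject_end=s_end,
                query_frame=1,
            )
        )
    return hits
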
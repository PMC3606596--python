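# txcurate

Curation toolkit for de novo transcriptome assemblies built from 454-era
pyrosequencing reads.

Pyrosequencing miscounts homopolymer run lengths, so assembled transcripts
carry single-base insertions and deletions that disrupt the reading frame of
otherwise well-supported protein-coding sequences. A transcriptome database
built from such an assembly needs, beyond the assembly itself: cleaning
(polyA trimming, low-complexity masking, contaminant and length filters),
best-hit annotation, *in silico* frameshift correction guided by each
transcript's reference protein, redundancy clustering with representative
selection, cross-species annotation quality control, and enrichment
statistics. `txcurate` implements all of these as a tested library and CLI,
together with a synthetic 454-style transcript simulator (with full ground
truth) so every stage runs and is verifiable without external data.

## The core computations

**Frameshift-aware protein–DNA alignment.** Transcripts are aligned against
their trusted reference protein by a dynamic program in which one residue
may be encoded by a 3-nt codon (BLOSUM62 score `s(aa(c), r)`), or — at a
frameshift penalty `F = −12` on top of the best-completion substitution —
by 2 nt (an *undercall*: a base lost from the read) or 4 nt (an *overcall*:
a base gained). Residues may align to nothing (affine gap, −11/−1) and
codons may be skipped (−11). The 2- and 4-nt ops in the optimal traceback
localise reading-frame disruptions at single-nucleotide resolution. Each
disruption is anchored to the nearest homopolymer run within 10 nt (testing
every candidate repair when several runs qualify) and repaired by inserting
or deleting one copy of the run's base; anything unanchorable is deferred to
manual curation rather than guessed at. Detect → correct → verify iterates
until the open reading frame is continuous.

**Representative selection.** Annotated transcripts sharing a description
are clustered at > 95 % nucleotide identity (single linkage; identity =
matches / shorter length, so fragments cluster with their parent).
Within a cluster each member is scored by

```
score = (HSPquery/100) × (HSPhit/100) × (Similarity/100) × (1/E-value) × Depth
```

(E-values clamped at 1e−180), and representatives are retained greedily by
descending score, keeping members that cover non-overlapping regions of the
mapped subject protein or are essentially complete (≥ 95 % subject
coverage).

**Quality control.** A random sample of transcripts from a well-annotated
reference species is searched against the curated database by translated
local alignment; annotated samples count as *matched* when the best hit
shares their annotation, unannotated ones as *recovered* when any hit
passes the threshold.

**Enrichment.** Pathway over-representation uses the one-sided Fisher exact
test: `p = P(X ≥ k)` with `X ~ Hypergeometric(N, K, n)` for a gene set of
size `n`, a pathway of size `K` and a universe of `N` genes.

## Worked example

Simulate a transcript, corrupt one homopolymer run, and repair it:

```python
from txcurate.simulate import generate_transcriptome, apply_single_indel
from txcurate.homopolymer import curate_sequence, detect_frameshifts

records, truths = generate_transcriptome(5, seed=7)
rec, truth = records[0], truths[records[0].id]
noisy, ntruth = apply_single_indel(rec, truth, seed=13)

for e in detect_frameshifts(noisy, ntruth.protein):
    print("event:", e.position, e.sense, e.anchor)
res = curate_sequence(noisy, ntruth.protein)
print("status:", res.status)
for ed in res.edits:
    print("edit:", ed)
print("restored:", res.corrected_seq == truth.clean_seq)
```

prints

```
event: 658 overcall HomopolymerRun(start=661, length=4, base='A')
status: corrected
edit: EditRecord(seq_id='g00000', position=664, op='deletion', base='A')
restored: True
```

— the aligner placed a 4-nt frameshift op at offset 658, anchored it to the
adjacent A-run (an extra A was simulated into that run), and deleting one A
at offset 664 restored the original sequence exactly.

The same stages are available from the shell:

```
txcurate simulate --genes 500 --seed 7 --out-prefix sim
txcurate pipeline --fasta sim.fasta --annotations sim.annotations.tsv \
                  --proteins sim.proteins.fasta --outdir run/
```

which writes `run/cleaned.fasta`, `run/corrected.fasta` + `run/edits.tsv`,
`run/representatives.fasta` and `run/report.tsv`. Other subcommands
(`clean`, `annotate`, `correct`, `select`, `qc`, `report`, `enrich`) expose
each stage separately; every tunable lives in a `key=value` config file
overridable on the command line.

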
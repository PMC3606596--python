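# Methods

## Scope and assumptions

`txcurate` operates downstream of assembly: its inputs are assembled
contigs/singletons (FASTA, with per-contig depth carried as a
`depth=<float>` header key), BLAST-style tabular hit tables, reference
proteins, and pathway membership tables. It assumes that each annotated
transcript's best protein hit is trustworthy end to end — homology-guided
correction edits the transcript toward agreement with that protein, which
is only sound when the annotation itself is sound. Correction is therefore
restricted to annotated sequences, and anything the rules cannot resolve
unambiguously is handed to manual curation instead of being guessed.

## Frameshift-aware alignment

The aligner is a protein-to-DNA dynamic program over two matrices: `H`
(best score ending in any op) and `Iy` (affine residue-gap state). The ops
and their scores:

| op | consumes | score |
|----|----------|-------|
| codon match | 3 nt, 1 res | BLOSUM62(aa(codon), res) |
| undercall frameshift | 2 nt, 1 res | `F` + max over single-base completions |
| overcall frameshift | 4 nt, 1 res | `F` + max over single-base drops |
| residue gap | 0 nt, 1 res | −11 open / −1 extend |
| codon gap | 3 nt, 0 res | −11 per codon |

A frameshift codon still emits its residue: the 2-nt (4-nt) window is
scored as the best substitution over the 12 codons obtained by inserting
one base (the 4 codons obtained by dropping one base). This matters: with a
flat penalty a lone frameshift would lose to opening a residue gap
(−12 < −11) and terminal disruptions would go undetected, whereas with the
emission term a single indel inside a good alignment costs roughly
`|F|` minus the recovered substitution and is always preferred over
abandoning the downstream alignment. `F = −12` keeps a spurious frameshift
pair (one op in, one op out, −24 plus weak emissions) far more expensive
than any plausible pair of codon substitutions, which is what keeps the
false-edit rate on clean transcripts at zero in the test suite.

Codons containing N score through the matrix's X row. All scores are
integer-valued, so DP-cell comparisons during traceback are exact. Ties are
broken during traceback toward the codon match, then residue gap, then
codon gap, then the 2-nt and finally the 4-nt frameshift — i.e. toward
fewer frameshift ops, then fewer gaps.

Three modes share the recurrence and differ in boundary conditions:
`semiglobal` (full protein, free nucleotide ends — the correction default,
since transcripts carry UTRs the protein says nothing about), `local`
(free clipping both sides, used by the QC search), and `global` (everything
consumed, useful for oracle comparisons on constructed fragments). A
consequence of free ends worth knowing: an indel within the first or last
couple of codons can be absorbed by shifting the alignment terminus at the
cost of one residue, so such edge disruptions are not reliably detectable —
on full-length transcripts with UTRs this affects only runs overlapping the
extreme CDS ends.

The DP is row-vectorised with numpy (the within-row codon-gap recurrence is
solved per stride-3 phase with a running maximum), giving a few
milliseconds per transcript-sized alignment without compiled extensions.

## Homopolymer correction

Frameshift ops from the optimal semiglobal alignment are anchored to
homopolymer runs. Two refinements proved necessary:

- **Anchor scan at `min_run − 1`.** An undercall shortens the true run by
  one, so a deletion in a minimum-length run would otherwise leave no
  anchorable run behind. With the default `min_run = 3`, anchors are
  scanned at observed length ≥ 2.
- **Repair hypothesis testing.** The DP places a frameshift op at a
  co-optimal codon boundary near — not exactly at — the true indel, so
  when several runs fall within the 10-nt anchor window, proximity alone
  misanchors a substantial fraction of cases. Each candidate single-base
  repair is applied in turn and the realignment score decides; the correct
  repair restores exact agreement with the protein and dominates.

Repairs are canonical: an undercall inserts one copy of the run's base at
the run's right edge, an overcall deletes the run's last base (for a pure
run the result is position-invariant, so this is canonicalisation, not an
assumption). Events that anchor nowhere, or two events contending for one
run, defer the whole sequence to manual curation with no edits applied.
`curate_sequence` iterates detect → correct → verify up to 3 rounds;
verification requires a frameshift-free optimal alignment whose aligned
codons contain no internal stop. Edit positions are mapped back through all
rounds so the recorded edit log always refers to the original input
sequence, and replaying the log reproduces the corrected output.

A minimum alignment score (default 50) separates "no frameshifts found"
from "the protein does not support this transcript at all"; the latter
raises a distinct detection-failure condition and the CLI routes such
records to manual curation.

## Cleaning

PolyA trimming removes a maximal terminal A-run (3′) or T-run (5′,
reverse-complement deposits) of length ≥ 10. Low-complexity masking
replaces every position covered by a 12-nt window of mononucleotide Shannon
entropy strictly below 1.0 bit (an equifrequent two-base repeat sits
exactly at 1.0 and survives). N contributes no information to the entropy
sum while the denominator stays the window size, and masking iterates to a
fixpoint — both choices exist to make the full cleaning pass idempotent,
which the suite asserts. Contaminant screening flags a record when ≥ 50 %
of its 21-mers occur in the (both-strand) contaminant k-mer set. The length
filter keeps records strictly longer than 100 nt. All thresholds are
config-exposed.

## Annotation and redundancy

Best-hit assignment keeps hits with E ≤ 1e−5 and picks the highest
similarity, breaking ties by lower E-value then lexicographic accession, so
the result is order-independent. Note the rule's consequence: tightening
the threshold can promote the runner-up once the leader is excluded.

Clustering groups same-description records connected by pairwise identity
> 95 % (single linkage — the most inclusive reading, and order-invariant).
Identity is computed from a global nucleotide alignment with free terminal
gaps (match +1, mismatch −1, gap −2, via Biopython's `PairwiseAligner`) and
divided by the shorter sequence length, so exact fragments of a longer
transcript score 100 and cluster with it; an alignment-length denominator
is selectable. Representative selection is greedy by the composite score
(coverage × similarity × reciprocal E-value × depth; E clamped at 1e−180 so
zero E-values stay finite and ordered), always keeps the top scorer, and
additionally keeps members whose subject-protein intervals overlap every
retained interval by < 0.2 of the shorter interval, or that cover ≥ 95 % of
the subject protein.

## Quality control

`crosscheck_annotations` samples `n` reference transcripts without
replacement (seeded generator; identical inputs and seed give identical
reports). The internal search stands in for a translated database search at
desk scale: database records are represented by their longest six-frame
stop-free translation, candidates are prefiltered by shared 11-mers (both
strands) and the top five are aligned in local mode, thresholded at score
≥ 50; a precomputed tabular hit table (E ≤ 1e−9) can be supplied instead
for fidelity at scale. Annotation agreement is case-insensitive,
whitespace-normalised description equality (accession-level comparison
selectable). Rates are reported to one decimal in machine output and to the
nearest integer for display.

## Enrichment

The one-sided p-value is the hypergeometric upper tail
`P(X ≥ k)` via `scipy.stats.hypergeom.sf`; the suite pins it to a
binomial-coefficient oracle over every feasible table with universe ≤ 25.
Significance is flagged at p ≤ 0.05 with no multiple-testing correction by
default (Benjamini–Hochberg available by flag), matching the convention of
reporting raw Fisher p-values for pathway incidence.

## The simulator

The generator emulates exactly the features the curation stages consume:

- **Transcripts** — one ORF per gene (random protein, start M, terminal
  stop, no internal stop; random-codon back-translation) flanked by
  uniform 20–200 nt UTRs; protein lengths lognormal with median 250 aa
  (σ = 0.35); depths lognormal with median 20 reads (σ = 0.8), echoing
  deep multi-library assemblies; optional polyA tails.
- **454 noise** — each homopolymer run of length L ≥ 2 independently
  receives one indel with probability `1 − exp(−λ(L−1))` (default
  λ = 0.05), undercall:overcall 0.7:0.3 (undercalls dominate in
  pyrosequencing). This is the simplest monotone run-length-dependent
  model; it does not emulate flowgram noise, substitution errors or
  quality values. A controlled variant plants exactly one indel in a run
  ≥ 3 inside the CDS for parameter-recovery measurements.
- **Redundancy** — fragments (≥ 150 nt, point mutations, log-uniform
  depths in [1, 50]) inheriting the parent's description, with their
  subject-protein interval tracked for selection tests.
- **A diverged sister species** — nonsynonymous substitutions to a target
  protein identity (default 85 %), full synonymous re-encoding, fresh
  UTRs, and a configurable fraction (default 29 %) stripped of annotation
  labels.

Every stochastic step is seeded and every introduced edit is recorded;
clean + recorded edits reproduces the noisy sequence exactly, which the
suite asserts for all simulated data. Because simulated UTRs and CDSs are
uniform-random, the simulator under-represents real low-complexity and
repeat content; passing tests demonstrate the machinery's correctness under
the stated error model, not performance on real 454 assemblies.

## Problem sizes

The default test and acceptance runs use 500 + 500 simulated transcripts
for correction recovery (observed: ≥ 99 % recovered, 0 % false edits),
120 random instances at ≤ 12 nt / ≤ 4 residues against the exhaustive
aligner oracle (the suite additionally sweeps all size combinations), the
full table sweep at universe ≤ 25 for Fisher, and an 80-gene database with
50 sampled homologs for the end-to-end QC check.

## Known limitations

- Corrections are single-base and anchored to homopolymer runs only;
  multi-base indels, substitution errors and run-free indels all defer to
  manual curation.
- Frameshifts in the extreme first/last codons of an alignment can be
  absorbed by free ends and go undetected (see above).
- The internal QC search is a desk-scale surrogate; for large databases a
  real translated search should be run externally and supplied as a hit
  table.
- The aligner provides scores, not E-values; statistical thresholds apply
  only to consumed hit tables.
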
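import pytest

from txcurate.simulate import generate_transcriptome, apply_single_indel


@pytest.fixture(scope="session")
def small_transcriptome():
    """30 clean simulated transcripts with ground truth (session-cached)."""
    return generate_transcriptome(30, seed=11)


@pytest.fixture(scope="session")
def noisy_transcriptome(small_transcriptome):
    """The same transcripts, each with exactly one homopolymer indel
    (where an eligible run exists)."""
    records, truths = small_transcriptome
    noisy = []
    for i, rec in enumerate(records):
        out = apply_single_indel(rec, truths[rec.id], seed=500 + i)
        if out is not None:
            noisy.append(out)
    return noisy
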
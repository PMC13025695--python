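import numpy as np
import pytest

from exoboost import regions, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def two_exon_model():
    """Plus-strand 2-exon transcript, CDS spanning both exons."""
    ref = simulate.make_reference(3000, 11)
    model, ref = simulate.embed_transcript(
        ref, transcript_id="TX2E", start=200,
        exon_lengths=[120, 180], intron_lengths=[400],
        utr5=30, utr3=30, rng=11,
    )
    return model, ref


@pytest.fixture(scope="session")
def noncoding_rich_model():
    """Transcript with an untranslated first exon and a long intron.

    The structure exposes every non-coding consequence class: deep
    intronic positions (intron 2 is 5 kb), 5'/3' UTR exonic bases, and
    the splice donor of a leading exon that lies wholly 5' of the CDS.
    """
    ref = simulate.make_reference(12000, 13)
    model, ref = simulate.embed_transcript(
        ref, transcript_id="TXNC", start=800,
        exon_lengths=[180, 300, 500, 400], intron_lengths=[800, 5000, 900],
        utr5=250, utr3=149, rng=13,
    )
    return model, ref


@pytest.fixture(scope="session")
def mnv_cis_fixture():
    """The adjacent het G>C pair in cis, with clean 30x reads."""
    return simulate.make_mnv_fixture(seed=101, phase="cis", depth=30.0,
                                     per_base_error=0.0)


@pytest.fixture(scope="session")
def mnv_trans_fixture():
    return simulate.make_mnv_fixture(seed=102, phase="trans", depth=30.0,
                                     per_base_error=0.0)


def random_transcript(rng, contig_len=2000, max_exons=5):
    """A random small transcript model plus its reference (walk-oracle prey)."""
    n_exons = int(rng.integers(1, max_exons + 1))
    exon_lengths = [int(rng.integers(30, 120)) for _ in range(n_exons)]
    intron_lengths = [int(rng.integers(20, 150)) for _ in range(n_exons - 1)]
    tlen = sum(exon_lengths)
    # CDS of >= 2 codons, leaving room for UTRs
    max_utr = tlen - 6
    utr5 = int(rng.integers(0, max_utr // 2 + 1))
    cds_len = ((tlen - utr5 - int(rng.integers(0, max_utr // 2 + 1))) // 3) * 3
    cds_len = max(6, cds_len)
    utr3 = tlen - utr5 - cds_len
    if utr3 < 0:
        utr5 += utr3
        utr3 = 0
    strand = "+" if rng.random() < 0.5 else "-"
    span = tlen + sum(intron_lengths)
    start = int(rng.integers(0, contig_len - span))
    ref = simulate.make_reference(contig_len, rng)
    model, ref = simulate.embed_transcript(
        ref, transcript_id="TXR", start=start, exon_lengths=exon_lengths,
        intron_lengths=intron_lengths, strand=strand, utr5=utr5, utr3=utr3,
        rng=rng,
    )
    return model, ref


def spliced_walk_oracle(model):
    """Exhaustive (gpos -> tpos) map built by walking exon bases directly."""
    pairs = []
    for e in model.exons:
        for g in range(e.start + 1, e.end + 1):
            pairs.append(g)
    if model.strand == "-":
        mapping = {g: i + 1 for i, g in enumerate(reversed(pairs))}
    else:
        mapping = {g: i + 1 for i, g in enumerate(pairs)}
    return mapping
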
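"""Synthetic-data generation for the whole pipeline.

Produces every input the other modules consume — reference sequence,
transcript models, ClinVar-style tables, cohort depth matrices, and
phased paired-end reads with a truth table — so that the repository
tests and demonstrates itself without downloads.  Every generator is
byte-deterministic under a fixed seed.

Reads are emitted directly as aligned SAM records (the simulator knows
where it placed each fragment), which keeps the package aligner-free; a
FASTQ emitter is provided for completeness.  Capture "boosting" is
modelled as class-specific fragment-rate multipliers over target
intervals: fragments arrive as a Poisson process whose rate per region
class is chosen to hit a requested mean depth, which is the simplest
mechanism reproducing the spike-in-versus-backbone coverage contrast of
a real enhanced-exome run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .coverage_qc import DepthProfile
from .regions import (
    GenomicInterval,
    TranscriptModel,
    hgvs_c_position,
    reverse_complement,
)
from .target_design import ClinVarRecord

__all__ = [
    "SimulationConfig",
    "SimulatedReads",
    "make_reference",
    "embed_transcript",
    "set_codon",
    "simulate_reads",
    "make_clinvar_fixture",
    "make_depth_profiles",
    "make_mnv_fixture",
    "write_fasta",
    "write_sam",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for read simulation.

    Defaults emulate the sequencing context the pipeline is built for:
    150 nt paired-end reads, ~350 nt fragments, 1% per-base error.
    """

    seed: int = 1
    contig: str = "chr1"
    contig_length: int = 20_000
    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    per_base_error: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.per_base_error <= 0.1):
            raise ValueError("per_base_error must be within [0, 0.1]")
        if self.contig_length < self.read_length:
            raise ValueError("contig shorter than one read")


def make_reference(length: int, seed: int | np.random.Generator = 0) -> str:
    """Seeded uniform ACGT sequence."""
    if length <= 0:
        raise ValueError(f"reference length must be positive, got {length}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.choice(_BASES, size=length).tobytes().decode()


def _random_codons(n: int, rng: np.random.Generator) -> str:
    out = []
    while len(out) < n:
        codon = rng.choice(_BASES, size=3).tobytes().decode()
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def embed_transcript(
    reference: str,
    *,
    transcript_id: str,
    start: int,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int] = (),
    strand: str = "+",
    utr5: int = 0,
    utr3: int = 0,
    contig: str = "chr1",
    rng: np.random.Generator | int = 0,
) -> tuple[TranscriptModel, str]:
    """Write a well-formed transcript into a reference sequence.

    The spliced transcript is UTR5 + CDS + UTR3 where the CDS is an ATG,
    internal-stop-free random codons and a terminal TAA; it is placed at
    the given exon layout (reverse-complemented for minus strand) and the
    edited reference is returned alongside the model (which carries the
    spliced sequence).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if len(intron_lengths) != max(0, len(exon_lengths) - 1):
        raise ValueError("need exactly len(exons)-1 intron lengths")
    tlen = sum(exon_lengths)
    cds_len = tlen - utr5 - utr3
    if cds_len < 6 or cds_len % 3:
        raise ValueError(
            f"CDS length {cds_len} must be >= 6 and divisible by 3"
        )
    span = tlen + sum(intron_lengths)
    if start < 0 or start + span > len(reference):
        raise ValueError(
            f"transcript span [{start}, {start + span}) does not fit the "
            f"reference of length {len(reference)}"
        )
    cds = "ATG" + _random_codons((cds_len - 6) // 3, rng) + "TAA"
    u5 = make_reference(utr5, rng) if utr5 else ""
    u3 = make_reference(utr3, rng) if utr3 else ""
    tx = u5 + cds + u3
    # lay exons out in ascending genomic order
    exons: list[GenomicInterval] = []
    g = start
    for elen, ilen in zip(exon_lengths, list(intron_lengths) + [0]):
        exons.append(GenomicInterval(contig, g, g + elen))
        g += elen + ilen
    asc = tx if strand == "+" else reverse_complement(tx)
    ref = list(reference)
    off = 0
    for e in exons:
        ref[e.start : e.end] = asc[off : off + e.length]
        off += e.length
    model = TranscriptModel(
        transcript_id=transcript_id,
        contig=contig,
        strand=strand,
        exons=tuple(exons),
        cds_start=utr5 + 1,
        cds_end=utr5 + cds_len,
        sequence=tx,
    )
    return model, "".join(ref)


def set_codon(
    model: TranscriptModel, reference: str, codon_index: int, bases: str
) -> tuple[TranscriptModel, str]:
    """Overwrite one codon of a transcript in both sequence spaces."""
    if len(bases) != 3:
        raise ValueError("a codon is exactly 3 bases")
    first = 3 * (codon_index - 1) + 1
    if first + 2 > model.cds_length:
        raise ValueError(f"codon {codon_index} outside CDS")
    ref = list(reference)
    seq = list(model.sequence)
    for k, base in enumerate(bases):
        cds_pos = first + k
        tpos = model.cds_start + cds_pos - 1
        seq[tpos - 1] = base
        gpos = model.genomic_position(tpos)
        ref[gpos - 1] = base if model.strand == "+" else reverse_complement(base)
    from dataclasses import replace

    return replace(model, sequence="".join(seq)), "".join(ref)


@dataclass
class SimulatedReads:
    """Aligned read pairs plus the per-fragment haplotype truth table."""

    records: list
    header: "pysam.AlignmentHeader"
    truth: pd.DataFrame
    contig: str
    reference: str


def simulate_reads(
    reference: str,
    variants: Sequence[tuple[int, str, str, tuple[int, ...]]],
    depth_targets: Sequence[tuple[GenomicInterval, float]],
    config: SimulationConfig = SimulationConfig(),
) -> SimulatedReads:
    """Simulate phased paired-end reads over a reference.

    ``variants`` are equal-length substitutions ``(pos1, ref, alt,
    haplotypes)`` with haplotypes a subset of {0, 1} (both = homozygous).
    ``depth_targets`` lists (interval, mean depth) classes; fragment
    counts per class are Poisson with mean depth*len/(2*read_length), so
    overlapping classes add up (spike-in boosting on top of a backbone).
    Mates lie on opposite strands with M-only CIGARs; sequencing errors
    are injected per base at ``per_base_error``.  The truth table records
    each fragment's haplotype of origin.
    """
    rng = np.random.default_rng(config.seed)
    haps = [list(reference), list(reference)]
    for pos, ref_a, alt_a, which in variants:
        if len(ref_a) != len(alt_a):
            raise ValueError("read simulation supports substitutions only")
        if reference[pos - 1 : pos - 1 + len(ref_a)].upper() != ref_a.upper():
            raise ValueError(f"ref allele mismatch at {pos}")
        for h in which:
            for k, b in enumerate(alt_a):
                haps[h][pos - 1 + k] = b
    hap_seqs = ["".join(h) for h in haps]
    rl = config.read_length
    records: list = []
    truth_rows = []
    header = pysam.AlignmentHeader.from_references(
        [config.contig], [len(reference)]
    )
    frag_idx = 0
    if not depth_targets and not variants:
        raise ValueError("nothing to simulate")
    total_expected = sum(
        d * iv.length / (2 * rl) for iv, d in depth_targets
    )
    if total_expected <= 0:
        import warnings

        warnings.warn("all depth targets are zero: no reads simulated")
    for iv, depth in depth_targets:
        n_frag = rng.poisson(depth * iv.length / (2 * rl)) if depth > 0 else 0
        for _ in range(n_frag):
            flen = int(
                np.clip(
                    rng.normal(config.fragment_mean, config.fragment_sd),
                    rl,
                    len(reference),
                )
            )
            lo = max(0, iv.start - flen + rl)
            hi = min(len(reference) - flen, iv.end - rl)
            if hi < lo:
                lo, hi = max(0, iv.start), max(0, iv.start)
            start = int(rng.integers(lo, hi + 1))
            h = int(rng.integers(2))
            name = f"frag{frag_idx:07d}"
            frag_idx += 1
            r1 = _errorify(hap_seqs[h][start : start + rl], rng, config.per_base_error)
            r2_start = start + flen - rl
            r2 = _errorify(
                hap_seqs[h][r2_start : r2_start + rl], rng, config.per_base_error
            )
            records.append(
                _make_segment(header, name, r1, start, r2_start, flen, True)
            )
            records.append(
                _make_segment(header, name, r2, r2_start, start, -flen, False)
            )
            truth_rows.append(
                {"fragment": name, "haplotype": h, "start": start, "length": flen}
            )
    records.sort(key=lambda r: (r.reference_start, r.query_name, not r.is_read1))
    truth = pd.DataFrame(
        truth_rows, columns=["fragment", "haplotype", "start", "length"]
    )
    return SimulatedReads(
        records=records, header=header, truth=truth,
        contig=config.contig, reference=reference,
    )


def _errorify(seq: str, rng: np.random.Generator, error: float) -> str:
    if error <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < error)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def _make_segment(header, name, seq, start, mate_start, tlen, is_read1):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    flag = 0x1 | 0x2  # paired, proper pair
    if is_read1:
        flag |= 0x40 | 0x20  # read1, mate reverse
    else:
        flag |= 0x80 | 0x10  # read2, reverse
    a.flag = flag
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    a.cigarstring = f"{len(seq)}M"
    a.next_reference_id = 0
    a.next_reference_start = mate_start
    a.template_length = tlen
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


# -- cohort depth fixtures ---------------------------------------------


def make_depth_profiles(
    intervals: Sequence[GenomicInterval],
    n_samples: int,
    *,
    mean_depth: float = 100.0,
    lowcov_spots: Sequence[tuple[GenomicInterval, float, int]] = (),
    rng: np.random.Generator | int = 0,
) -> list[DepthProfile]:
    """Cohort depth matrix: Poisson baseline with planted low-coverage spots.

    Each ``(interval, depth, n_affected)`` spot overrides the baseline
    with a Poisson draw at the (lower) depth for the first ``n_affected``
    samples, emulating systematically undercaptured segments.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    total = sum(iv.length for iv in intervals)
    offsets = {}
    off = 0
    for iv in intervals:
        offsets[(iv.contig, iv.start)] = off
        off += iv.length
    profiles = []
    for s in range(n_samples):
        depth = rng.poisson(mean_depth, size=total).astype(np.int32)
        for spot, spot_depth, n_aff in lowcov_spots:
            if s >= n_aff:
                continue
            for iv in intervals:
                if iv.contig != spot.contig:
                    continue
                lo = max(iv.start, spot.start)
                hi = min(iv.end, spot.end)
                if lo < hi:
                    base = offsets[(iv.contig, iv.start)]
                    depth[base + lo - iv.start : base + hi - iv.start] = rng.poisson(
                        spot_depth, size=hi - lo
                    )
        profiles.append(
            DepthProfile(
                sample_id=f"sample{s + 1:02d}",
                intervals=tuple(intervals),
                depth=depth,
            )
        )
    return profiles


# -- ClinVar-style fixture ---------------------------------------------

_PLP_STRINGS = (
    "Pathogenic",
    "Likely pathogenic",
    "Pathogenic/Likely pathogenic",
    "Likely pathogenic;Uncertain significance",
)
_NON_PLP_STRINGS = ("Benign", "Uncertain significance", "Likely benign")


def _positions_for_class(
    model: TranscriptModel, cls: str, deep_min: int = 8
) -> list[int]:
    """All genomic positions of a transcript with a given consequence class.

    Enumerates the transcript span once; callers sample from the result.
    """
    from .target_design import classify_consequence

    out = []
    probe = ClinVarRecord(
        gene_symbol="X", contig=model.contig, pos=1, ref="A", alt="C",
        clinical_significance="Pathogenic",
    )
    for gpos in range(model.exons[0].start + 1, model.exons[-1].end + 1):
        probe.pos = gpos
        if classify_consequence(probe, model, deep_min) == cls:
            out.append(gpos)
    return out


def make_clinvar_fixture(
    models: Sequence[TranscriptModel],
    reference: str,
    class_counts: Mapping[str, int],
    *,
    gene_names: Sequence[str] | None = None,
    n_non_plp_coding: int = 0,
    rng: np.random.Generator | int = 0,
) -> list[ClinVarRecord]:
    """Generate ClinVar-style records with ground-truth classes.

    ``class_counts`` requests P/LP records per consequence class (drawn
    uniformly from all qualifying positions of the supplied transcripts);
    ``n_non_plp_coding`` adds benign/VUS coding records as harvest
    decoys.  Each record's ``consequence_class`` stores the ground truth
    for downstream assertions.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gene_names = list(gene_names or [f"GENE{i + 1:03d}" for i in range(len(models))])
    records: list[ClinVarRecord] = []
    pools = {
        m.transcript_id: {} for m in models
    }  # lazily filled per class

    def draw(cls: str, significance: str) -> ClinVarRecord:
        # pick among transcripts that actually offer positions of this class
        order = list(rng.permutation(len(models)))
        mi = model = pool = None
        for cand in order:
            cand_model = models[cand]
            cand_pool = pools[cand_model.transcript_id].setdefault(
                cls, _positions_for_class(cand_model, cls)
            )
            if cand_pool:
                mi, model, pool = cand, cand_model, cand_pool
                break
        if model is None:
            raise ValueError(f"no supplied transcript offers {cls} positions")
        gpos = int(pool[int(rng.integers(len(pool)))])
        ref_base = reference[gpos - 1].upper()
        alt_base = "ACGT".replace(ref_base, "")[int(rng.integers(3))]
        if model.strand == "+":
            c_ref, c_alt = ref_base, alt_base
        else:
            c_ref, c_alt = (
                reverse_complement(ref_base), reverse_complement(alt_base)
            )
        return ClinVarRecord(
            gene_symbol=gene_names[mi % len(gene_names)],
            contig=model.contig,
            pos=gpos,
            ref=ref_base,
            alt=alt_base,
            clinical_significance=significance,
            hgvs_c=f"{hgvs_c_position(model, gpos)}{c_ref}>{c_alt}",
            consequence_class=cls,
        )

    for cls, n in class_counts.items():
        for k in range(n):
            records.append(draw(cls, _PLP_STRINGS[k % len(_PLP_STRINGS)]))
    for k in range(n_non_plp_coding):
        records.append(draw("coding", _NON_PLP_STRINGS[k % len(_NON_PLP_STRINGS)]))
    return records


# -- canned MNV scenario ------------------------------------------------


def make_mnv_fixture(
    seed: int = 1,
    *,
    phase: str = "cis",
    depth: float = 30.0,
    per_base_error: float = 0.0,
):
    """The two-adjacent-substitutions rescue scenario, end to end.

    Builds a single-exon plus-strand transcript whose codon 647 is GGG
    (Gly), plants het G>C substitutions at CDS 1939 and 1940 on the same
    haplotype (``phase='cis'``) or opposite haplotypes (``'trans'``), and
    simulates reads at the requested depth over the surrounding window.

    Returns (model, reference, (v1, v2), SimulatedReads).
    """
    from .mnv_phasing import VariantCall

    if phase not in ("cis", "trans"):
        raise ValueError("phase must be 'cis' or 'trans'")
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        seed=int(rng.integers(2**31 - 1)),
        contig_length=4000,
        per_base_error=per_base_error,
    )
    reference = make_reference(cfg.contig_length, rng)
    model, reference = embed_transcript(
        reference,
        transcript_id="TX_MNV_DEMO",
        start=500,
        exon_lengths=[2100],
        strand="+",
        rng=rng,
        contig=cfg.contig,
    )
    model, reference = set_codon(model, reference, 647, "GGG")
    g1 = model.cds_to_genomic(1939)
    g2 = model.cds_to_genomic(1940)
    v1 = VariantCall(cfg.contig, g1, "G", "C", "het")
    v2 = VariantCall(cfg.contig, g2, "G", "C", "het")
    hap_spec = (
        [(g1, "G", "C", (1,)), (g2, "G", "C", (1,))]
        if phase == "cis"
        else [(g1, "G", "C", (0,)), (g2, "G", "C", (1,))]
    )
    window = GenomicInterval(cfg.contig, max(0, g1 - 400), min(len(reference), g2 + 400))
    sim = simulate_reads(reference, hap_spec, [(window, depth)], cfg)
    return model, reference, (v1, v2), sim


# -- writers ------------------------------------------------------------


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(sim: SimulatedReads, path: str | Path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=sim.header) as fh:
        for r in sim.records:
            fh.write(r)


def write_fastq(sim: SimulatedReads, path1: str | Path, path2: str | Path) -> None:
    """Emit the simulated pairs as FASTQ (read 2 reverse-complemented)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in sim.records:
            seq = r.query_sequence
            qual = "I" * len(seq)
            if r.is_read1:
                f1.write(f"@{r.query_name}/1\n{seq}\n+\n{qual}\n")
            else:
                f2.write(
                    f"@{r.query_name}/2\n{reverse_complement(seq)}\n+\n{qual}\n"
                )
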
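"""Spike-in capture target design.

Builds the custom probe set that supplements a commercial exome panel:
cohort-wide detection of poorly covered bases, harvesting of clinically
asserted pathogenic/likely-pathogenic (P/LP) non-coding variants from a
ClinVar-style table, assembly of padded target regions, and probe tiling.

The driving design rule: a base belongs in the spike-in set when it is
covered by fewer than ``min_depth`` reads in at least ``min_samples`` of a
``cohort_size``-sample reference cohort (defaults 35 / 2 / 12 at a
50-million-read budget per sample).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval, TranscriptModel, merge_intervals

__all__ = [
    "DesignParams",
    "ClinVarRecord",
    "DesignReport",
    "CONSEQUENCE_CLASSES",
    "NONCODING_CLASSES",
    "count_plp",
    "low_coverage_bases",
    "harvest_noncoding",
    "classify_consequence",
    "build_targets",
    "tile_probes",
    "design_report",
    "read_clinvar_table",
    "write_clinvar_table",
    "read_gene_set",
]

CONSEQUENCE_CLASSES = (
    "deep_intronic",
    "utr_exonic",
    "noncoding_exon_splice",
    "coding",
    "canonical_splice",
    "other",
)

#: classes that qualify a P/LP variant for spike-in targeting: sites a
#: plain exome capture does not reliably see.
NONCODING_CLASSES = frozenset(
    {"deep_intronic", "utr_exonic", "noncoding_exon_splice"}
)


@dataclass(frozen=True)
class DesignParams:
    """Tunable knobs of the spike-in design.

    min_depth / min_samples / cohort_size / read_budget encode the
    low-coverage rule (defaults: < 35 reads in >= 2 of 12 samples at 50M
    reads per sample).  Padding, merging and tiling defaults follow
    common hybridization-capture practice: 60 nt around a harvested
    variant, 25 nt around a low-coverage run, 50 nt merge gap, 120-mer
    probes at 1x tiling.
    """

    min_depth: int = 35
    min_samples: int = 2
    cohort_size: int = 12
    read_budget: int = 50_000_000
    variant_pad: int = 60
    lowcov_pad: int = 25
    merge_gap: int = 50
    probe_length: int = 120
    probe_stride: int = 120

    def __post_init__(self) -> None:
        if not (0 < self.min_samples <= self.cohort_size):
            raise ValueError(
                f"need 0 < min_samples <= cohort_size, got "
                f"{self.min_samples} / {self.cohort_size}"
            )
        if self.min_depth <= 0:
            raise ValueError("min_depth must be positive")
        if self.probe_stride > self.probe_length:
            raise ValueError("probe_stride must not exceed probe_length")
        for name in ("variant_pad", "lowcov_pad", "merge_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ClinVarRecord:
    """One row of a ClinVar-style variant table.

    ``clinical_significance`` holds per-submitter assertions separated by
    ';' (slash-combined forms like "Pathogenic/Likely pathogenic" are a
    single submitter's assertion).  ``n_plp_submitters`` is derived from
    it when not given explicitly.
    """

    gene_symbol: str
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    clinical_significance: str
    hgvs_c: str = ""
    consequence_class: str = "other"
    n_plp_submitters: int | None = None

    def __post_init__(self) -> None:
        if self.n_plp_submitters is None:
            self.n_plp_submitters = count_plp(self.clinical_significance)
        if self.n_plp_submitters < 0:
            raise ValueError("n_plp_submitters must be >= 0")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"unknown consequence class {self.consequence_class!r}"
            )


def count_plp(significance: str) -> int:
    """Count submitters asserting Pathogenic or Likely pathogenic.

    Assertions are ';'-separated; within one assertion, slash-combined
    values ("Pathogenic/Likely pathogenic") are split and matched
    case-insensitively.  A submitter counts once however many of their
    slash-parts match.
    """
    n = 0
    for assertion in significance.split(";"):
        parts = {p.strip().lower() for p in assertion.split("/")}
        if parts & {"pathogenic", "likely pathogenic"}:
            n += 1
    return n


@dataclass(frozen=True)
class DesignReport:
    """Summary counts of a finished spike-in design."""

    n_genes: int
    n_noncoding_variants: int
    n_genes_with_noncoding: int
    n_target_regions: int
    n_probes: int
    total_target_bases: int

    def __post_init__(self) -> None:
        for f in (
            "n_genes", "n_noncoding_variants", "n_genes_with_noncoding",
            "n_target_regions", "n_probes", "total_target_bases",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.n_genes_with_noncoding > self.n_genes:
            raise ValueError("n_genes_with_noncoding cannot exceed n_genes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# -- low-coverage detection --------------------------------------------


def low_coverage_bases(profiles: Sequence, params: DesignParams) -> list[GenomicInterval]:
    """Flag bases underscovered across a cohort and regionize them.

    A base is flagged iff its depth falls below ``params.min_depth`` in at
    least ``params.min_samples`` of the profiles.  Flagged runs are padded
    by ``lowcov_pad`` on each side and merged with ``merge_gap``.

    All profiles must share the identical interval layout; the number of
    profiles must equal ``params.cohort_size``.
    """
    if not profiles:
        raise ValueError("no depth profiles supplied")
    intervals = tuple(profiles[0].intervals)
    for p in profiles[1:]:
        if tuple(p.intervals) != intervals:
            raise ValueError(
                f"profile {p.sample_id!r} has mismatched intervals"
            )
    if len(profiles) != params.cohort_size:
        raise ValueError(
            f"cohort_size is {params.cohort_size} but {len(profiles)} "
            f"profiles were supplied"
        )
    matrix = np.stack([np.asarray(p.depth) for p in profiles])
    flagged = (matrix < params.min_depth).sum(axis=0) >= params.min_samples
    raw = _mask_to_intervals(flagged, intervals)
    padded = [
        GenomicInterval(
            iv.contig, max(0, iv.start - params.lowcov_pad), iv.end + params.lowcov_pad
        )
        for iv in raw
    ]
    return merge_intervals(padded, max_gap=params.merge_gap)


def _mask_to_intervals(
    mask: np.ndarray, intervals: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Turn a boolean mask over concatenated interval bases into intervals."""
    out: list[GenomicInterval] = []
    offset = 0
    for iv in intervals:
        sub = mask[offset : offset + iv.length]
        # run-length extraction on the padded diff
        edges = np.flatnonzero(np.diff(np.concatenate(([0], sub.astype(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(iv.contig, iv.start + int(s), iv.start + int(e)))
        offset += iv.length
    return out


# -- ClinVar harvest ----------------------------------------------------


def harvest_noncoding(
    records: Iterable[ClinVarRecord], gene_set: frozenset | set
) -> list[ClinVarRecord]:
    """Keep P/LP non-coding variants in genes of interest.

    A record survives iff its gene is in ``gene_set``, at least one
    submitter asserted P/LP, and its consequence class is one an exome
    capture misses (deep intronic, untranslated exonic, or the splice
    donor of an untranslated leading exon).  Output is sorted by
    (contig, pos), stably.
    """
    kept = [
        r
        for r in records
        if r.gene_symbol in gene_set
        and (r.n_plp_submitters or 0) >= 1
        and r.consequence_class in NONCODING_CLASSES
    ]
    kept.sort(key=lambda r: (r.contig, r.pos))
    return kept


def classify_consequence(
    record: ClinVarRecord,
    model: TranscriptModel,
    deep_intronic_min_offset: int = 8,
) -> str:
    """Assign a consequence class from a variant's position in a transcript.

    Deep intronic means beyond ``deep_intronic_min_offset`` (default 8 nt,
    past the splice-region neighbourhood an exome capture's padding
    already reaches).  Donor positions +1/+2 of an exon lying wholly 5'
    of the CDS are classed ``noncoding_exon_splice`` (they precede any
    coding sequence, so exome capture has no reason to cover them).
    """
    loc = model.locate(record.pos)  # raises OutOfTranscriptError outside span
    if loc.region == "coding":
        return "coding"
    if loc.region in ("utr5", "utr3"):
        return "utr_exonic"
    # intronic: anchor tpos is the nearest exon boundary base
    if loc.offset in (1, 2) and loc.tpos < model.cds_start:
        return "noncoding_exon_splice"
    if abs(loc.offset) <= 2:
        return "canonical_splice"
    if abs(loc.offset) > deep_intronic_min_offset:
        return "deep_intronic"
    return "other"


# -- target assembly and probe tiling ----------------------------------


def build_targets(
    lowcov: Iterable[GenomicInterval],
    variants: Iterable[ClinVarRecord],
    params: DesignParams,
) -> list[GenomicInterval]:
    """Union low-coverage regions with padded harvested-variant windows.

    Each variant at 1-based ``pos`` contributes the 0-based window
    ``[pos - 1 - variant_pad, pos + variant_pad)``; the union with the
    low-coverage intervals is merged with ``merge_gap``.
    """
    var_ivs = [
        GenomicInterval(
            v.contig, max(0, v.pos - 1 - params.variant_pad), v.pos + params.variant_pad
        )
        for v in variants
    ]
    return merge_intervals(list(lowcov) + var_ivs, max_gap=params.merge_gap)


def tile_probes(
    targets: Iterable[GenomicInterval],
    probe_length: int = 120,
    probe_stride: int = 120,
) -> list[GenomicInterval]:
    """Tile capture probes across targets.

    Probes start at the target start and advance by ``probe_stride``; the
    final probe is right-aligned to the target end.  Targets shorter than
    one probe get a single centered probe (clamped at position 0).  Probe
    count per target is ``max(1, ceil((len - probe_length)/stride) + 1)``.
    """
    if probe_length <= 0:
        raise ValueError("probe_length must be positive")
    if probe_stride <= 0:
        raise ValueError("probe_stride must be positive")
    probes: list[GenomicInterval] = []
    idx = 0
    for t in targets:
        if t.length < probe_length:
            start = max(0, t.start - (probe_length - t.length) // 2)
            starts = [start]
        else:
            n = max(1, math.ceil((t.length - probe_length) / probe_stride) + 1)
            starts = [t.start + i * probe_stride for i in range(n - 1)]
            starts.append(t.end - probe_length)
        for s in starts:
            idx += 1
            probes.append(
                GenomicInterval(t.contig, s, s + probe_length, name=f"probe{idx:05d}")
            )
    return probes


def design_report(
    gene_set: Iterable[str],
    harvested: Sequence[ClinVarRecord],
    targets: Sequence[GenomicInterval],
    probes: Sequence[GenomicInterval],
) -> DesignReport:
    """Tally the design: genes, harvested variants, regions, probes, bases."""
    genes = set(gene_set)
    return DesignReport(
        n_genes=len(genes),
        n_noncoding_variants=len(harvested),
        n_genes_with_noncoding=len({r.gene_symbol for r in harvested}),
        n_target_regions=len(targets),
        n_probes=len(probes),
        total_target_bases=sum(t.length for t in targets),
    )


# -- tabular I/O --------------------------------------------------------

_CLINVAR_COLUMNS = [
    "gene_symbol", "contig", "pos", "ref", "alt",
    "clinical_significance", "hgvs_c", "consequence_class",
]


def read_clinvar_table(path: str | Path) -> list[ClinVarRecord]:
    """Read the documented tab-delimited ClinVar subset (with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str}, keep_default_na=False)
    missing = [c for c in _CLINVAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        ClinVarRecord(
            gene_symbol=str(r.gene_symbol),
            contig=str(r.contig),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            clinical_significance=str(r.clinical_significance),
            hgvs_c=str(r.hgvs_c),
            consequence_class=str(r.consequence_class),
        )
        for r in df.itertuples()
    ]


def write_clinvar_table(records: Sequence[ClinVarRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(r, c) for c in _CLINVAR_COLUMNS} for r in records],
        columns=_CLINVAR_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> frozenset:
    """Read a one-symbol-per-line gene list."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
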
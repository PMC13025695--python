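"""Genomic interval algebra and transcript coordinate arithmetic.

This module is the coordinate foundation of the package.  Conventions:

* On disk, BED records are 0-based half-open (the BED standard).
* In memory, :class:`GenomicInterval` mirrors BED (0-based half-open).
* Anything that mirrors VCF or HGVS (variant positions, CDS positions,
  codon indices) is 1-based inclusive.
* Transcript arithmetic always operates in spliced 5'->3' space; genomic
  inputs are flipped once at entry for minus-strand models, so orientation
  handling lives in exactly one place.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "CdsCoordinate",
    "TranscriptModel",
    "TranscriptLocus",
    "BedParseError",
    "OutOfTranscriptError",
    "merge_intervals",
    "cds_to_codon",
    "codon_first_base",
    "genomic_to_cds",
    "read_bed",
    "write_bed",
    "read_transcript_table",
    "write_transcript_table",
    "hgvs_c_position",
]

_STRANDS = {"+", "-", "."}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class BedParseError(ValueError):
    """Raised on malformed BED input; message names the offending line."""


class OutOfTranscriptError(ValueError):
    """Raised when a genomic position falls outside a transcript's span."""


@dataclass(frozen=True)
class GenomicInterval:
    """Contig-anchored half-open interval (0-based start, exclusive end)."""

    contig: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos1(self, contig: str, pos: int) -> bool:
        """Membership test for a 1-based position."""
        return self.contig == contig and self.start < pos <= self.end


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Sort and merge intervals, bridging gaps of up to ``max_gap`` bases.

    Abutting intervals (gap 0) merge when ``max_gap`` is 0, matching how
    capture targets treat adjacent segments as one region.  Names and
    strands are dropped on output (merged regions are anonymous).
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be non-negative, got {max_gap}")
    items = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    cur_contig: str | None = None
    cur_start = cur_end = 0
    for iv in items:
        if iv.contig == cur_contig and iv.start - cur_end <= max_gap:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_contig is not None:
                out.append(GenomicInterval(cur_contig, cur_start, cur_end))
            cur_contig, cur_start, cur_end = iv.contig, iv.start, iv.end
    if cur_contig is not None:
        out.append(GenomicInterval(cur_contig, cur_start, cur_end))
    return out


@dataclass(frozen=True)
class CdsCoordinate:
    """A 1-based coding-sequence position and its codon decomposition.

    Invariant: ``cds_pos == 3 * (codon_index - 1) + codon_offset + 1``.
    """

    cds_pos: int
    codon_index: int
    codon_offset: int


def cds_to_codon(cds_pos: int) -> CdsCoordinate:
    """Map a 1-based CDS nucleotide position to its codon.

    Codon ``i`` spans CDS positions ``3i-2 .. 3i``, so e.g. CDS position
    1939 is the first base of codon 647.
    """
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    return CdsCoordinate(
        cds_pos=cds_pos,
        codon_index=(cds_pos + 2) // 3,
        codon_offset=(cds_pos - 1) % 3,
    )


def codon_first_base(codon_index: int) -> int:
    """First CDS position of a 1-based codon index (inverse of cds_to_codon)."""
    if codon_index < 1:
        raise ValueError(f"codon_index must be >= 1, got {codon_index}")
    return 3 * (codon_index - 1) + 1


@dataclass(frozen=True)
class TranscriptLocus:
    """Where a genomic position falls relative to a transcript.

    ``region`` is one of ``coding``, ``utr5``, ``utr3``, ``intron``.
    ``tpos`` is the anchor position in spliced transcript coordinates
    (for intronic loci, the nearest exonic base in HGVS style).
    ``cds_pos`` is ``tpos`` re-expressed relative to the CDS start; it is
    <= 0 in the 5' UTR and > CDS length in the 3' UTR.  ``offset`` is the
    signed HGVS intronic offset (+n downstream of a donor, -n upstream of
    an acceptor), 0 for exonic loci.
    """

    region: str
    tpos: int
    cds_pos: int
    offset: int = 0

    @property
    def is_exonic(self) -> bool:
        return self.region != "intron"

    @property
    def codon(self) -> CdsCoordinate:
        if self.region != "coding":
            raise ValueError(f"no codon for {self.region} locus")
        return cds_to_codon(self.cds_pos)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure, CDS extent and (optionally) the spliced sequence.

    ``exons`` are stored sorted by genomic start regardless of strand;
    5'->3' order is derived from ``strand``.  ``cds_start``/``cds_end``
    are transcript-relative, 1-based, inclusive, and include the stop
    codon.
    """

    transcript_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        exons = tuple(sorted(self.exons, key=GenomicInterval.sort_key))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("transcript needs at least one exon")
        for a, b in zip(exons, exons[1:]):
            if a.contig != b.contig:
                raise ValueError("all exons must share one contig")
            if b.start < a.end:
                raise ValueError("exons must be non-overlapping")
        if not (1 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(
                f"CDS bounds [{self.cds_start}, {self.cds_end}] outside "
                f"transcript of length {self.length}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != exon total {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end,
            name=self.transcript_id, strand=self.strand,
        )

    @property
    def cds_sequence(self) -> str:
        if self.sequence is None:
            raise ValueError(f"{self.transcript_id} has no sequence attached")
        return self.sequence[self.cds_start - 1 : self.cds_end]

    # -- coordinate maps ------------------------------------------------

    def _cumlens(self) -> list[int]:
        cum = [0]
        for e in self.exons:
            cum.append(cum[-1] + e.length)
        return cum

    def transcript_position(self, gpos: int) -> int | None:
        """Spliced 1-based transcript position of a 1-based genomic position.

        Returns None for intronic positions; raises OutOfTranscriptError
        outside the transcript span.
        """
        if gpos <= self.exons[0].start or gpos > self.exons[-1].end:
            raise OutOfTranscriptError(
                f"{self.contig}:{gpos} outside {self.transcript_id}"
            )
        cum = self._cumlens()
        for i, e in enumerate(self.exons):
            if e.start < gpos <= e.end:
                asc = cum[i] + (gpos - e.start)  # 1-based along ascending coords
                return asc if self.strand == "+" else self.length - asc + 1
        return None

    def genomic_position(self, tpos: int) -> int:
        """Inverse of :meth:`transcript_position` for exonic positions."""
        if not (1 <= tpos <= self.length):
            raise OutOfTranscriptError(
                f"transcript position {tpos} outside {self.transcript_id}"
            )
        asc = tpos if self.strand == "+" else self.length - tpos + 1
        cum = self._cumlens()
        i = bisect_right(cum, asc - 1) - 1
        return self.exons[i].start + (asc - cum[i])

    def cds_to_genomic(self, cds_pos: int) -> int:
        return self.genomic_position(self.cds_start + cds_pos - 1)

    def locate(self, gpos: int) -> TranscriptLocus:
        """Classify a 1-based genomic position against this transcript."""
        tpos = self.transcript_position(gpos)  # raises if outside span
        if tpos is not None:
            return TranscriptLocus(
                region=self._exonic_region(tpos),
                tpos=tpos,
                cds_pos=tpos - self.cds_start + 1,
            )
        # intronic: find flanking exons in genomic coordinates
        i = bisect_right([e.start for e in self.exons], gpos - 1) - 1
        left, right = self.exons[i], self.exons[i + 1]
        d_left = gpos - left.end          # distance past the left exon's last base
        d_right = right.start + 1 - gpos  # distance to the right exon's first base
        if self.strand == "+":
            donor_d, acceptor_d = d_left, d_right
            donor_g, acceptor_g = left.end, right.start + 1
        else:
            donor_d, acceptor_d = d_right, d_left
            donor_g, acceptor_g = right.start + 1, left.end
        if donor_d <= acceptor_d:  # tie goes to the donor side, as in HGVS
            anchor = self.transcript_position(donor_g)
            offset = donor_d
        else:
            anchor = self.transcript_position(acceptor_g)
            offset = -acceptor_d
        assert anchor is not None
        return TranscriptLocus(
            region="intron",
            tpos=anchor,
            cds_pos=anchor - self.cds_start + 1,
            offset=offset,
        )

    def _exonic_region(self, tpos: int) -> str:
        if tpos < self.cds_start:
            return "utr5"
        if tpos > self.cds_end:
            return "utr3"
        return "coding"

    def spliced_sequence(self, reference: str | Mapping[str, str]) -> str:
        """Extract the spliced 5'->3' sequence from a reference."""
        contig_seq = reference if isinstance(reference, str) else str(reference[self.contig])
        asc = "".join(contig_seq[e.start : e.end] for e in self.exons)
        return asc if self.strand == "+" else reverse_complement(asc)

    def with_sequence(self, reference: str | Mapping[str, str]) -> "TranscriptModel":
        return replace(self, sequence=self.spliced_sequence(reference))


def genomic_to_cds(model: TranscriptModel, gpos: int) -> TranscriptLocus:
    """Functional alias for :meth:`TranscriptModel.locate`."""
    return model.locate(gpos)


def hgvs_c_position(model: TranscriptModel, gpos: int) -> str:
    """Render a genomic position in HGVS c. position syntax.

    Coding -> ``c.123``; 5' UTR -> ``c.-15``; 3' UTR -> ``c.*20``;
    intronic -> anchor plus signed offset, e.g. ``c.867+1`` or
    ``c.7595-2144``.
    """
    loc = model.locate(gpos)
    if loc.tpos < model.cds_start:
        anchor = f"-{model.cds_start - loc.tpos}"
    elif loc.tpos > model.cds_end:
        anchor = f"*{loc.tpos - model.cds_end}"
    else:
        anchor = str(loc.cds_pos)
    if loc.offset == 0:
        return f"c.{anchor}"
    sign = "+" if loc.offset > 0 else "-"
    return f"c.{anchor}{sign}{abs(loc.offset)}"


# -- BED I/O -----------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 (tab-delimited, 0-based half-open, no header)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if end <= start:
                raise BedParseError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else None
            try:
                out.append(GenomicInterval(fields[0], start, end, name=name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.contig, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


# -- transcript table I/O ----------------------------------------------

_TX_COLUMNS = [
    "transcript_id", "contig", "strand", "exon_start", "exon_end",
    "cds_start", "cds_end",
]


def read_transcript_table(
    path: str | Path, spliced_fasta: str | Path | None = None
) -> list[TranscriptModel]:
    """Read transcript models from a tab-delimited exon table.

    One row per exon, columns ``transcript_id contig strand exon_start
    exon_end cds_start cds_end``; exon coordinates 0-based half-open,
    CDS bounds transcript-relative 1-based.  An optional FASTA supplies
    spliced sequences keyed by transcript_id.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = [c for c in _TX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    seqs: dict[str, str] = {}
    if spliced_fasta is not None:
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(spliced_fasta), "fasta")}
    models = []
    for tid, grp in df.groupby("transcript_id", sort=False):
        exons = tuple(
            GenomicInterval(r.contig, int(r.exon_start), int(r.exon_end))
            for r in grp.itertuples()
        )
        first = grp.iloc[0]
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                contig=str(first.contig),
                strand=str(first.strand),
                exons=exons,
                cds_start=int(first.cds_start),
                cds_end=int(first.cds_end),
                sequence=seqs.get(str(tid)),
            )
        )
    return models


def write_transcript_table(
    models: Sequence[TranscriptModel],
    path: str | Path,
    spliced_fasta: str | Path | None = None,
) -> None:
    import pandas as pd

    rows = [
        {
            "transcript_id": m.transcript_id,
            "contig": m.contig,
            "strand": m.strand,
            "exon_start": e.start,
            "exon_end": e.end,
            "cds_start": m.cds_start,
            "cds_end": m.cds_end,
        }
        for m in models
        for e in m.exons
    ]
    pd.DataFrame(rows, columns=_TX_COLUMNS).to_csv(path, sep="\t", index=False)
    if spliced_fasta is not None:
        with open(spliced_fasta, "w") as fh:
            for m in models:
                if m.sequence is not None:
                    fh.write(f">{m.transcript_id}\n{m.sequence}\n")
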
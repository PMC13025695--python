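"""Pair-aware downsampling, per-base depth and DP-threshold reporting.

DPk is the percentage of target bases covered by at least k reads (DP20
and DP50 are the conventional thresholds).  Depth is per-read: every
alignment record contributes its aligned blocks, so overlapping mates of
one fragment count twice; duplicate, secondary, supplementary and
unmapped records are excluded.  Downsampling to a fixed read budget
operates on fragments so that exactly budget/2 read-1 and budget/2
read-2 records survive, with both mates kept or dropped together.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval, merge_intervals

__all__ = [
    "DownsampleSpec",
    "DepthProfile",
    "CoverageReport",
    "PairingError",
    "ContigError",
    "EmptyProfileError",
    "downsample_pairs",
    "depth_from_alignments",
    "dp_metric",
    "mean_coverage",
    "coverage_table",
    "read_depth_tsv",
    "write_depth_tsv",
]


class PairingError(ValueError):
    """A read without its mate where intact pairing is required."""


class ContigError(ValueError):
    """An alignment maps to a contig absent from the target namespace."""


class EmptyProfileError(ValueError):
    """A coverage metric was requested over zero bases."""


@dataclass(frozen=True)
class DownsampleSpec:
    """Total read budget (both mates combined) and the sampling seed."""

    total_read_budget: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_read_budget <= 0:
            raise ValueError("total_read_budget must be positive")
        if self.total_read_budget % 2:
            raise ValueError(
                "total_read_budget must be even (split across two mates)"
            )


@dataclass(frozen=True)
class DepthProfile:
    """Per-base depth over a fixed interval set for one sample.

    ``depth`` is a non-negative integer vector concatenated in interval
    order; its length equals the total interval bases.
    """

    sample_id: str
    intervals: tuple[GenomicInterval, ...]
    depth: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        d = np.asarray(self.depth)
        object.__setattr__(self, "depth", d)
        if d.ndim != 1 or len(d) != self.n_bases:
            raise ValueError(
                f"depth vector length {d.size} != total interval bases "
                f"{self.n_bases}"
            )
        if d.size and d.min() < 0:
            raise ValueError("depth values must be non-negative")

    @property
    def n_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)


def downsample_pairs(records: Sequence, spec: DownsampleSpec) -> list:
    """Subsample mate-paired records to a total read budget.

    If the input already fits the budget it is returned unchanged.
    Otherwise exactly ``budget/2`` fragments are retained by seeded
    uniform sampling without replacement — i.e. budget/2 read-1 and
    budget/2 read-2 records — preserving input order.  Records must
    arrive fully paired (one read-1 and one read-2 per query name).
    """
    slots: dict[str, list[bool]] = {}
    order: list[str] = []
    for r in records:
        name = r.query_name
        if name not in slots:
            slots[name] = [False, False]
            order.append(name)
        idx = 0 if r.is_read1 else 1
        if slots[name][idx]:
            raise PairingError(f"duplicate mate for fragment {name!r}")
        slots[name][idx] = True
    for name, (r1, r2) in slots.items():
        if not (r1 and r2):
            raise PairingError(f"orphan read: fragment {name!r} lacks a mate")
    total = len(records)
    if total <= spec.total_read_budget:
        return list(records)
    n_keep = spec.total_read_budget // 2
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(len(order), size=n_keep, replace=False)
    keep = {order[i] for i in chosen}
    return [r for r in records if r.query_name in keep]


def _iter_alignments(alignments):
    if isinstance(alignments, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def depth_from_alignments(
    alignments,
    targets: Iterable[GenomicInterval],
    *,
    sample_id: str = "sample",
    include_duplicates: bool = False,
    on_unknown_contig: str = "error",
) -> DepthProfile:
    """Per-base read depth over merged target intervals.

    ``alignments`` may be a SAM/BAM path or an iterable of alignment
    records.  A base's depth is the number of records whose aligned
    blocks (CIGAR M/=/X, i.e. skipping deletions, introns and clips)
    include it; unmapped, secondary and supplementary records are always
    excluded, duplicates unless ``include_duplicates``.  Overlapping
    mates each contribute (per-read counting).
    """
    if on_unknown_contig not in ("error", "skip"):
        raise ValueError("on_unknown_contig must be 'error' or 'skip'")
    merged = merge_intervals(targets, max_gap=0)
    # per-contig lookup: sorted starts plus the offset of each interval
    # in the concatenated depth vector
    index: dict[str, tuple[list[int], list[GenomicInterval], list[int]]] = {}
    offset = 0
    for iv in merged:
        starts, ivs, offs = index.setdefault(iv.contig, ([], [], []))
        starts.append(iv.start)
        ivs.append(iv)
        offs.append(offset)
        offset += iv.length
    depth = np.zeros(offset, dtype=np.int32)
    for read in _iter_alignments(alignments):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_duplicate and not include_duplicates:
            continue
        contig = read.reference_name
        if contig not in index:
            if on_unknown_contig == "error":
                raise ContigError(
                    f"read {read.query_name!r} maps to unknown contig {contig!r}"
                )
            continue
        starts, ivs, offs = index[contig]
        for bstart, bend in read.get_blocks():
            i = bisect_right(starts, bstart) - 1
            if i < 0:
                i = 0
            while i < len(ivs) and ivs[i].start < bend:
                iv = ivs[i]
                lo = max(bstart, iv.start)
                hi = min(bend, iv.end)
                if lo < hi:
                    depth[offs[i] + lo - iv.start : offs[i] + hi - iv.start] += 1
                i += 1
    return DepthProfile(sample_id=sample_id, intervals=tuple(merged), depth=depth)


def dp_metric(profile: DepthProfile, k: int) -> float:
    """Percent of profile bases with depth >= k."""
    if profile.n_bases == 0:
        raise EmptyProfileError("DP metric undefined over an empty profile")
    return float(100.0 * np.count_nonzero(profile.depth >= k) / profile.n_bases)


def mean_coverage(profile: DepthProfile) -> float:
    """Average depth per base over the profile."""
    if profile.n_bases == 0:
        raise EmptyProfileError("mean coverage undefined over an empty profile")
    return float(profile.depth.mean())


@dataclass(frozen=True)
class CoverageReport:
    """One coverage-summary row: a sample against a named region set."""

    region_set_name: str
    sample_id: str
    dp_percent: Mapping[int, float]
    mean_cov: float

    @classmethod
    def from_profile(
        cls,
        profile: DepthProfile,
        region_set_name: str,
        thresholds: Sequence[int] = (20, 50),
    ) -> "CoverageReport":
        return cls(
            region_set_name=region_set_name,
            sample_id=profile.sample_id,
            dp_percent={int(k): dp_metric(profile, k) for k in thresholds},
            mean_cov=mean_coverage(profile),
        )


def coverage_table(
    profiles: Mapping[str, Mapping[str, DepthProfile]],
    thresholds: Mapping[str, Sequence[int]] | Sequence[int] = (20, 50),
) -> pd.DataFrame:
    """Coverage summary rows per sample per region set, plus averages.

    ``profiles`` maps sample id -> region-set name -> DepthProfile; every
    sample must cover the same region sets.  ``thresholds`` is either one
    threshold list for all sets or a per-set mapping (the mitochondrial
    set conventionally uses DP50 where nuclear sets use DP20 — both
    columns are emitted so either convention can be read off).  Percent
    columns are rounded half-even to 2 decimals; the final "Average" row
    per set is the arithmetic mean over samples.
    """
    samples = list(profiles)
    if not samples:
        raise ValueError("no samples supplied")
    set_names = list(profiles[samples[0]])
    for s in samples:
        if list(profiles[s]) != set_names:
            raise ValueError(f"sample {s!r} reports different region sets")

    def ks_for(set_name: str) -> list[int]:
        if isinstance(thresholds, Mapping):
            if set_name not in thresholds:
                raise ValueError(f"no thresholds configured for set {set_name!r}")
            return [int(k) for k in thresholds[set_name]]
        return [int(k) for k in thresholds]

    all_ks = sorted({k for name in set_names for k in ks_for(name)})
    rows = []
    for name in set_names:
        ks = ks_for(name)
        accum = {k: [] for k in ks}
        mean_accum = []
        for s in samples:
            rep = CoverageReport.from_profile(profiles[s][name], name, ks)
            row = {"sample": s, "region_set": name}
            for k in all_ks:
                row[f"DP{k}"] = (
                    round(rep.dp_percent[k], 2) if k in rep.dp_percent else np.nan
                )
            row["mean_cov"] = round(rep.mean_cov, 2)
            rows.append(row)
            for k in ks:
                accum[k].append(rep.dp_percent[k])
            mean_accum.append(rep.mean_cov)
        avg = {"sample": "Average", "region_set": name}
        for k in all_ks:
            avg[f"DP{k}"] = (
                round(float(np.mean(accum[k])), 2) if k in accum else np.nan
            )
        avg["mean_cov"] = round(float(np.mean(mean_accum)), 2)
        rows.append(avg)
    cols = ["sample", "region_set"] + [f"DP{k}" for k in all_ks] + ["mean_cov"]
    return pd.DataFrame(rows, columns=cols)


# -- depth-profile TSV I/O ---------------------------------------------


def write_depth_tsv(profile: DepthProfile, path: str | Path) -> None:
    """Write a profile as tab-delimited (contig, pos0, depth), no header."""
    with open(path, "w") as fh:
        offset = 0
        for iv in profile.intervals:
            for i in range(iv.length):
                fh.write(f"{iv.contig}\t{iv.start + i}\t{profile.depth[offset + i]}\n")
            offset += iv.length


def read_depth_tsv(path: str | Path, sample_id: str | None = None) -> DepthProfile:
    """Read (contig, pos0, depth) rows; intervals are maximal position runs."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "pos0", "depth"],
        dtype={"contig": str},
    )
    intervals: list[GenomicInterval] = []
    depths: list[np.ndarray] = []
    if len(df):
        pos = df["pos0"].to_numpy()
        contig = df["contig"].to_numpy()
        breaks = np.flatnonzero(
            (np.diff(pos) != 1) | (contig[1:] != contig[:-1])
        )
        bounds = np.concatenate(([0], breaks + 1, [len(df)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            intervals.append(
                GenomicInterval(str(contig[lo]), int(pos[lo]), int(pos[hi - 1]) + 1)
            )
            depths.append(df["depth"].to_numpy()[lo:hi])
    depth = np.concatenate(depths) if depths else np.zeros(0, dtype=np.int32)
    return DepthProfile(
        sample_id=sample_id or Path(path).stem,
        intervals=tuple(intervals),
        depth=depth.astype(np.int32),
    )
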
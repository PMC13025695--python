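"""Read-backed phasing and multinucleotide-variant (MNV) rescue.

Variant callers and annotation platforms report two adjacent heterozygous
substitutions as independent events even when they sit on the same
haplotype, where the correct interpretation is a single delins allele —
e.g. two het G>C calls at consecutive CDS positions within one codon are
really one delins changing that codon once, with a different amino-acid
consequence than either substitution alone.

This module infers cis/trans configuration of nearby het variants from
fragment-level evidence (a read pair shares one haplotype), merges cis
substitution pairs into delins records, and recomputes HGVS c./p.
consequences on the merged allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .regions import TranscriptModel, reverse_complement

__all__ = [
    "VariantCall",
    "PhaseEvidence",
    "PhasingParams",
    "ProteinConsequence",
    "PhasingNotApplicableError",
    "phase_pair",
    "merge_cis_substitutions",
    "protein_consequence",
    "rescue_mnvs",
    "hgvs_c",
    "annotate_consequence",
    "read_vcf",
    "write_vcf",
]

_ZYGOSITIES = {"het", "hom", "hemi"}
_ALLELE_CHARS = set("ACGT")


class PhasingNotApplicableError(ValueError):
    """Phasing was requested for variants it cannot apply to (non-het)."""


@dataclass(frozen=True)
class VariantCall:
    """A substitution/indel/delins call with 1-based position.

    Alleles are uppercase ACGT strings; symbolic alleles are rejected.
    ``sources`` records parent variant names when this call was produced
    by merging.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    zygosity: str = "het"
    phase_set: str | None = None
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValueError(
                    f"{label} allele must be non-empty uppercase ACGT, "
                    f"got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.zygosity not in _ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref) - 1

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PhaseEvidence:
    """Fragment tallies behind a phase call.

    cis_support: fragments carrying both alt alleles; trans_support:
    exactly one alt plus the other ref; ref_ref_support: both refs;
    ambiguous: fragments touching the pair with a missing, low-quality,
    conflicting or third-allele observation.
    """

    cis_support: int = 0
    trans_support: int = 0
    ref_ref_support: int = 0
    ambiguous: int = 0

    def __post_init__(self) -> None:
        for f in ("cis_support", "trans_support", "ref_ref_support", "ambiguous"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def informative(self) -> int:
        return self.cis_support + self.trans_support + self.ref_ref_support

    @property
    def total(self) -> int:
        return self.informative + self.ambiguous


@dataclass(frozen=True)
class PhasingParams:
    """Thresholds for phase calling and merge eligibility.

    min_fragments: informative fragments required before any call.
    min_consistency: fraction of allele-configuration evidence
    (cis vs trans fragments) that must agree.  max_gap: largest number of
    reference bases allowed between two substitutions for merging
    (default 2 keeps merges to same-codon/near-adjacent events).
    min_baseq: base observations below this Phred quality count as
    ambiguous, not evidence.
    """

    min_fragments: int = 2
    min_consistency: float = 0.9
    max_gap: int = 2
    min_baseq: int = 13

    def __post_init__(self) -> None:
        if self.min_fragments < 1:
            raise ValueError("min_fragments must be >= 1")
        if not (0.5 < self.min_consistency <= 1.0):
            raise ValueError("min_consistency must be in (0.5, 1.0]")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


# -- fragment evidence --------------------------------------------------


def _load_alignments(alignments) -> list:
    if isinstance(alignments, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            return [r for r in fh if not r.is_unmapped]
    return list(alignments)


def _read_base(read, pos: int, min_baseq: int) -> str | None:
    """Query base aligned at 1-based reference pos, or None.

    None means: position not covered by this read, deleted, or below the
    quality floor.
    """
    if read.reference_start is None or read.reference_name is None:
        return None
    rpos0 = pos - 1
    if not (read.reference_start <= rpos0 < (read.reference_end or -1)):
        return None
    for qpos, rp in read.get_aligned_pairs():
        if rp == rpos0:
            if qpos is None:
                return None  # deletion spanning the site
            quals = read.query_qualities
            if quals is not None and quals[qpos] < min_baseq:
                return None
            return read.query_sequence[qpos].upper()
    return None


def _fragment_observation(reads, pos: int, min_baseq: int) -> str | None:
    """Consensus base at a site across a fragment's mates.

    Conflicting mate observations yield None (ambiguous).
    """
    seen = {
        b for b in (_read_base(r, pos, min_baseq) for r in reads) if b is not None
    }
    if len(seen) == 1:
        return seen.pop()
    return None


def phase_pair(
    alignments,
    v1: VariantCall,
    v2: VariantCall,
    params: PhasingParams = PhasingParams(),
) -> tuple[str, PhaseEvidence]:
    """Call cis/trans/unknown for two het variants from fragment evidence.

    Fragments (read pairs pooled by query name) observing both sites are
    classified alt-alt (cis support), ref-ref, or one-alt-one-ref (trans
    support); anything else touching the pair is ambiguous.  For two het
    variants the cis diplotype is {alt-alt, ref-ref} and the trans
    diplotype is {alt-ref, ref-alt}, so ref-ref fragments count as
    cis-consistent evidence.  The call is cis iff informative fragments
    reach ``min_fragments``, at least one alt-alt fragment exists, and
    cis-consistent fragments make up ``min_consistency`` of the
    informative total; trans symmetrically; otherwise unknown.  The
    result is invariant under swapping v1 and v2.
    """
    if v1.contig != v2.contig:
        raise ValueError(
            f"variants on different contigs: {v1.contig} vs {v2.contig}"
        )
    for v in (v1, v2):
        if v.zygosity != "het":
            raise PhasingNotApplicableError(
                f"phasing applies to heterozygous variants, got {v.zygosity} "
                f"at {v.contig}:{v.pos}"
            )
    a, b = sorted((v1, v2), key=VariantCall.key)
    records = _load_alignments(alignments)
    fragments: dict[str, list] = {}
    for r in records:
        if r.reference_name != a.contig:
            continue
        fragments.setdefault(r.query_name, []).append(r)
    cis = trans = ref_ref = ambiguous = 0
    for reads in fragments.values():
        o1 = _fragment_observation(reads, a.pos, params.min_baseq)
        o2 = _fragment_observation(reads, b.pos, params.min_baseq)
        covers1 = any(_covers(r, a.pos) for r in reads)
        covers2 = any(_covers(r, b.pos) for r in reads)
        if not (covers1 or covers2):
            continue  # fragment does not touch the pair at all
        if o1 is None or o2 is None:
            ambiguous += 1
        elif o1 == a.alt and o2 == b.alt:
            cis += 1
        elif o1 == a.ref and o2 == b.ref:
            ref_ref += 1
        elif (o1 == a.alt and o2 == b.ref) or (o1 == a.ref and o2 == b.alt):
            trans += 1
        else:
            ambiguous += 1  # third allele at either site
    ev = PhaseEvidence(cis, trans, ref_ref, ambiguous)
    call = "unknown"
    if ev.informative >= params.min_fragments:
        cis_score = (cis + ref_ref) / ev.informative
        trans_score = trans / ev.informative
        if cis > 0 and cis_score >= params.min_consistency:
            call = "cis"
        elif trans > 0 and trans_score >= params.min_consistency:
            call = "trans"
    return call, ev


def _covers(read, pos: int) -> bool:
    if read.reference_start is None or read.reference_end is None:
        return False
    return read.reference_start <= pos - 1 < read.reference_end


# -- merging ------------------------------------------------------------


def _ref_slice(reference, contig: str, start1: int, end1: int) -> str:
    """Reference bases for 1-based inclusive [start1, end1]."""
    if end1 < start1:
        return ""
    if reference is None:
        raise ValueError(
            "a reference sequence is required to fill bases between "
            "non-adjacent substitutions"
        )
    if callable(reference):
        return str(reference(contig, start1, end1)).upper()
    return str(reference[contig][start1 - 1 : end1]).upper()


def merge_cis_substitutions(
    v1: VariantCall,
    v2: VariantCall,
    reference=None,
    max_gap: int = 2,
    phase_call: str = "cis",
):
    """Merge two cis substitutions into one delins variant.

    Returns a single :class:`VariantCall` spanning both positions, with
    intervening reference bases carried through unchanged.  Non-cis input
    or a gap beyond ``max_gap`` returns the (sorted) pair unchanged.
    ``reference`` (mapping contig -> sequence, or callable
    ``(contig, start1, end1) -> str``) is only needed when the gap is
    positive.  Order of v1/v2 does not matter.
    """
    if phase_call not in ("cis", "trans", "unknown"):
        raise ValueError(f"invalid phase call {phase_call!r}")
    a, b = sorted((v1, v2), key=VariantCall.key)
    if phase_call != "cis":
        return (a, b)
    if a.contig != b.contig:
        raise ValueError("cannot merge variants on different contigs")
    if not (a.is_substitution and b.is_substitution):
        raise ValueError("only simple substitutions are merged")
    if a.pos == b.pos:
        raise ValueError("cannot merge two variants at the same position")
    gap = b.pos - a.pos - 1
    if gap > max_gap:
        return (a, b)
    mid = _ref_slice(reference, a.contig, a.pos + 1, b.pos - 1) if gap else ""
    return VariantCall(
        contig=a.contig,
        pos=a.pos,
        ref=a.ref + mid + b.ref,
        alt=a.alt + mid + b.alt,
        zygosity="het",
        phase_set=a.phase_set or b.phase_set,
        sources=(hgvs_like(a), hgvs_like(b)),
    )


def hgvs_c(variant: VariantCall) -> str:
    """Render a CDS-space variant in HGVS c. syntax."""
    return "c." + _hgvs_body(variant)


def hgvs_like(variant: VariantCall) -> str:
    """Position-space-agnostic rendering used in audit trails."""
    return f"{variant.contig}:{_hgvs_body(variant)}"


def _hgvs_body(v: VariantCall) -> str:
    if v.is_substitution:
        return f"{v.pos}{v.ref}>{v.alt}"
    return f"{v.pos}_{v.end}delins{v.alt}"


# -- protein consequence ------------------------------------------------


@dataclass(frozen=True)
class ProteinConsequence:
    """A protein-level consequence with its HGVS p. rendering.

    ``hgvs_p`` uses three-letter amino-acid codes with ``*`` for stops,
    e.g. ``p.(Gly647Pro)`` or ``p.(Lys53Argfs*35)``.
    """

    kind: str
    hgvs_p: str

    _KINDS = (
        "missense", "nonsense", "synonymous", "frameshift",
        "inframe_delins", "no_protein",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown consequence kind {self.kind!r}")


def _aa3(aa: str) -> str:
    return "*" if aa == "*" else seq3(aa)


def _translate(nt: str) -> str:
    """Translate, truncating at the first stop codon (kept, as '*')."""
    nt = nt[: len(nt) // 3 * 3]
    aa = str(Seq(nt).translate())
    i = aa.find("*")
    return aa if i < 0 else aa[: i + 1]


def protein_consequence(
    variant: VariantCall, model: TranscriptModel
) -> ProteinConsequence:
    """Protein consequence of a CDS-space variant on a transcript.

    ``variant.pos`` is a 1-based CDS position; the model must carry its
    spliced sequence.  Length-preserving edits compare codons
    (missense/nonsense/synonymous, or an in-frame delins when several
    residues change); length changes that are not a multiple of 3 give a
    frameshift ``fs*N`` where N is the 1-based position of the new stop
    in the shifted frame, counting the first changed residue as 1
    (``fs*?`` when no downstream stop exists).
    """
    cds = model.cds_sequence.upper()
    pos = variant.pos
    if pos < 1 or pos > len(cds):
        return ProteinConsequence("no_protein", "p.?")
    if variant.end > len(cds):
        raise ValueError(
            f"edit spans past CDS end ({variant.end} > {len(cds)})"
        )
    observed = cds[pos - 1 : variant.end]
    if observed != variant.ref:
        raise ValueError(
            f"reference allele mismatch at CDS {pos}: expected "
            f"{variant.ref!r}, CDS has {observed!r}"
        )
    edited = cds[: pos - 1] + variant.alt + cds[variant.end :]
    p_ref = _translate(cds)
    p_alt = _translate(edited)
    dlen = len(variant.alt) - len(variant.ref)
    if dlen % 3 == 0:
        return _inframe_consequence(p_ref, p_alt, dlen)
    return _frameshift_consequence(p_ref, p_alt)


def _first_diff(p_ref: str, p_alt: str) -> int:
    n = min(len(p_ref), len(p_alt))
    for i in range(n):
        if p_ref[i] != p_alt[i]:
            return i
    return n


def _inframe_consequence(p_ref: str, p_alt: str, dlen: int) -> ProteinConsequence:
    if p_ref == p_alt:
        return ProteinConsequence("synonymous", "p.(=)")
    i = _first_diff(p_ref, p_alt)
    if i >= len(p_ref):  # pure C-terminal extension; treat as delins
        return ProteinConsequence("inframe_delins", "p.?")
    if i < len(p_alt) and p_alt[i] == "*":
        return ProteinConsequence("nonsense", f"p.({_aa3(p_ref[i])}{i + 1}*)")
    if dlen == 0 and len(p_ref) == len(p_alt):
        if p_ref[i + 1 :] == p_alt[i + 1 :]:
            return ProteinConsequence(
                "missense", f"p.({_aa3(p_ref[i])}{i + 1}{_aa3(p_alt[i])})"
            )
    # multi-residue change or in-frame indel: align the common tail
    k = 0
    while (
        k < min(len(p_ref), len(p_alt)) - i
        and p_ref[len(p_ref) - 1 - k] == p_alt[len(p_alt) - 1 - k]
    ):
        k += 1
    jr = len(p_ref) - k - 1
    ja = len(p_alt) - k - 1
    alt_seg = p_alt[i : ja + 1]
    if not alt_seg:  # pure in-frame deletion
        if jr == i:
            body = f"{_aa3(p_ref[i])}{i + 1}del"
        else:
            body = f"{_aa3(p_ref[i])}{i + 1}_{_aa3(p_ref[jr])}{jr + 1}del"
        return ProteinConsequence("inframe_delins", f"p.({body})")
    ins3 = "".join(_aa3(a) for a in alt_seg)
    if jr < i:  # pure insertion between residues i and i+1
        body = f"{_aa3(p_ref[i - 1])}{i}_{_aa3(p_ref[i])}{i + 1}ins{ins3}"
    elif jr == i:
        body = f"{_aa3(p_ref[i])}{i + 1}delins{ins3}"
    else:
        body = f"{_aa3(p_ref[i])}{i + 1}_{_aa3(p_ref[jr])}{jr + 1}delins{ins3}"
    return ProteinConsequence("inframe_delins", f"p.({body})")


def _frameshift_consequence(p_ref: str, p_alt: str) -> ProteinConsequence:
    i = _first_diff(p_ref, p_alt)
    if i >= len(p_ref):
        return ProteinConsequence("frameshift", "p.?")
    ref_res = _aa3(p_ref[i])
    if i >= len(p_alt):  # shifted frame ran off the sequence with no stop
        return ProteinConsequence("frameshift", f"p.({ref_res}{i + 1}fs*?)")
    alt_res = p_alt[i]
    if alt_res == "*":
        return ProteinConsequence("nonsense", f"p.({ref_res}{i + 1}*)")
    stop = p_alt.find("*", i)
    if stop < 0:
        return ProteinConsequence(
            "frameshift", f"p.({ref_res}{i + 1}{_aa3(alt_res)}fs*?)"
        )
    return ProteinConsequence(
        "frameshift",
        f"p.({ref_res}{i + 1}{_aa3(alt_res)}fs*{stop - i + 1})",
    )


# -- genomic-space annotation ------------------------------------------


def annotate_consequence(
    variant: VariantCall, model: TranscriptModel
) -> tuple[str, ProteinConsequence]:
    """HGVS c. name and protein consequence for a genomic-space variant.

    The variant's reference span must lie fully within the CDS; anything
    else is reported as (c.?, no_protein).  Minus-strand models get their
    alleles reverse-complemented and coordinates flipped once here.
    """
    try:
        loc_start = model.locate(variant.pos)
        loc_end = model.locate(variant.end)
    except Exception:
        return "c.?", ProteinConsequence("no_protein", "p.?")
    if loc_start.region != "coding" or loc_end.region != "coding":
        return "c.?", ProteinConsequence("no_protein", "p.?")
    if model.strand == "+":
        cds_pos = loc_start.cds_pos
        ref, alt = variant.ref, variant.alt
    else:
        cds_pos = loc_end.cds_pos
        ref = reverse_complement(variant.ref)
        alt = reverse_complement(variant.alt)
    cds_variant = VariantCall(
        contig=model.transcript_id, pos=cds_pos, ref=ref, alt=alt,
        zygosity=variant.zygosity,
    )
    return hgvs_c(cds_variant), protein_consequence(cds_variant, model)


# -- the rescue driver --------------------------------------------------


def rescue_mnvs(
    variants: Sequence[VariantCall],
    alignments,
    model: TranscriptModel | None = None,
    *,
    reference=None,
    params: PhasingParams = PhasingParams(),
) -> tuple[list[VariantCall], list[dict]]:
    """Scan calls for mergeable het substitution pairs and rescue MNVs.

    Adjacent (within ``params.max_gap``) heterozygous substitutions are
    phased against the alignments; cis pairs are replaced by a single
    delins record, everything else passes through untouched.  Pairs
    without usable fragment evidence are logged as unknown and left
    unmerged.  Returns the revised variant list and an audit log with
    one row per candidate pair (evidence counts and the action taken);
    when a transcript model is given, audit rows and merged calls carry
    recomputed HGVS c./p. consequences.
    """
    records = _load_alignments(alignments)
    vs = sorted(variants, key=VariantCall.key)
    out: list[VariantCall] = []
    audit: list[dict] = []
    consumed: set[int] = set()
    i = 0
    while i < len(vs):
        if i in consumed:
            i += 1
            continue
        v = vs[i]
        merged_here = False
        j = i + 1
        if (
            _is_candidate(v)
            and j < len(vs)
            and j not in consumed
            and _is_candidate(vs[j])
            and vs[j].contig == v.contig
            and vs[j].pos - v.pos - 1 <= params.max_gap
        ):
            w = vs[j]
            try:
                call, ev = phase_pair(records, v, w, params)
            except PhasingNotApplicableError:
                call, ev = "unknown", PhaseEvidence()
            row = {
                "contig": v.contig,
                "pos1": v.pos,
                "pos2": w.pos,
                "variant1": hgvs_like(v),
                "variant2": hgvs_like(w),
                "phase_call": call,
                "cis_support": ev.cis_support,
                "trans_support": ev.trans_support,
                "ref_ref_support": ev.ref_ref_support,
                "ambiguous": ev.ambiguous,
            }
            if call == "cis":
                merged = merge_cis_substitutions(
                    v, w, reference=reference, max_gap=params.max_gap,
                    phase_call="cis",
                )
                if isinstance(merged, VariantCall):
                    row["action"] = "merged"
                    row["merged_variant"] = hgvs_like(merged)
                    if model is not None:
                        c, p = annotate_consequence(merged, model)
                        row["hgvs_c"] = c
                        row["hgvs_p"] = p.hgvs_p
                    out.append(merged)
                    consumed.update((i, j))
                    merged_here = True
                else:
                    row["action"] = "kept"
            else:
                row["action"] = "kept"
            audit.append(row)
        if not merged_here:
            out.append(v)
            consumed.add(i)
        i += 1
    return out, audit


def _is_candidate(v: VariantCall) -> bool:
    return v.zygosity == "het" and v.is_substitution


# -- VCF I/O ------------------------------------------------------------


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read a single-sample VCF into VariantCalls (GT field honoured).

    Records with symbolic or non-ACGT alleles are skipped.  Multiallelic
    records contribute one call per alt allele present in the genotype.
    """
    import pysam

    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            gt: tuple = ()
            if rec.samples:
                gt = rec.samples[0].get("GT") or ()
            for ai, alt in enumerate(rec.alts, start=1):
                if alt is None or not set(alt.upper()) <= _ALLELE_CHARS:
                    continue
                if not set(rec.ref.upper()) <= _ALLELE_CHARS:
                    continue
                if gt and ai not in gt:
                    continue
                called = [g for g in gt if g is not None]
                if len(called) == 1:
                    zyg = "hemi"
                elif called and all(g == ai for g in called):
                    zyg = "hom"
                else:
                    zyg = "het"
                out.append(
                    VariantCall(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        zygosity=zyg,
                    )
                )
    return out


def write_vcf(
    variants: Sequence[VariantCall],
    path: str | Path,
    contigs: Mapping[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write calls as a single-sample VCF 4.2.

    Merged records carry an INFO ``MERGED_FROM`` tag naming their parent
    calls.
    """
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line(
        '##INFO=<ID=MERGED_FROM,Number=.,Type=String,'
        'Description="Parent calls merged into this MNV">'
    )
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_sample(sample)
    gt_map = {"het": (0, 1), "hom": (1, 1), "hemi": (1,)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=VariantCall.key):
            rec = vf.new_record(
                contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.sources:
                rec.info["MERGED_FROM"] = [s.replace(":", "_") for s in v.sources]
            rec.samples[sample]["GT"] = gt_map[v.zygosity]
            rec.samples[sample].phased = v.phase_set is not None
            vf.write(rec)
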
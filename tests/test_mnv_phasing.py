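"""Phase calling, cis-pair merging, protein consequences and MNV rescue."""

import numpy as np
import pysam
import pytest

from exoboost import simulate
from exoboost.mnv_phasing import (
    PhaseEvidence,
    PhasingNotApplicableError,
    PhasingParams,
    ProteinConsequence,
    VariantCall,
    annotate_consequence,
    hgvs_c,
    merge_cis_substitutions,
    phase_pair,
    protein_consequence,
    read_vcf,
    rescue_mnvs,
    write_vcf,
)
from exoboost.regions import GenomicInterval


def _fragment(header, name, seq, start):
    """Single-end stand-in fragment (one read) for evidence tests."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.reference_id = 0
    a.reference_start = start
    a.cigarstring = f"{len(seq)}M"
    a.mapping_quality = 60
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


def _evidence_reads(counts, ref="GG", v1_alt="C", v2_alt="C", start=99):
    """Build fragments showing the requested (base1, base2) combinations.

    counts maps e.g. ("alt", "alt") -> n; reads cover positions 100, 101.
    """
    header = pysam.AlignmentHeader.from_references(["chr1"], [1000])
    base = {"ref": (ref[0], ref[1]), "alt": (v1_alt, v2_alt)}
    reads = []
    i = 0
    for (k1, k2), n in counts.items():
        b1 = base[k1][0] if k1 in base else k1
        b2 = base[k2][1] if k2 in base else k2
        for _ in range(n):
            seq = "A" + b1 + b2 + "A" * 7
            reads.append(_fragment(header, f"f{i}", seq, start))
            i += 1
    return reads


V1 = VariantCall("chr1", 101, "G", "C")
V2 = VariantCall("chr1", 102, "G", "C")


def test_phase_perfect_cis():
    reads = _evidence_reads({("alt", "alt"): 10, ("ref", "ref"): 10})
    call, ev = phase_pair(reads, V1, V2)
    assert call == "cis"
    assert (ev.cis_support, ev.trans_support, ev.ref_ref_support) == (10, 0, 10)
    assert ev.ambiguous == 0


def test_phase_perfect_trans():
    reads = _evidence_reads({("alt", "ref"): 5, ("ref", "alt"): 5})
    call, ev = phase_pair(reads, V1, V2)
    assert call == "trans"
    assert ev.trans_support == 10


def test_phase_below_consistency_is_unknown():
    """3 cis + 1 trans at min_consistency 0.9 -> 0.75 < 0.9 -> unknown."""
    reads = _evidence_reads({("alt", "alt"): 3, ("alt", "ref"): 1})
    call, ev = phase_pair(
        reads, V1, V2, PhasingParams(min_fragments=4, min_consistency=0.9)
    )
    assert call == "unknown"
    assert (ev.cis_support, ev.trans_support) == (3, 1)


def test_phase_too_few_fragments_is_unknown():
    reads = _evidence_reads({("alt", "alt"): 1})
    call, _ = phase_pair(reads, V1, V2, PhasingParams(min_fragments=2))
    assert call == "unknown"


def test_phase_symmetric_and_counts_conserved(rng):
    for _ in range(20):
        counts = {
            ("alt", "alt"): int(rng.integers(0, 6)),
            ("ref", "ref"): int(rng.integers(0, 6)),
            ("alt", "ref"): int(rng.integers(0, 6)),
            ("ref", "alt"): int(rng.integers(0, 6)),
            ("T", "alt"): int(rng.integers(0, 3)),  # third allele -> ambiguous
        }
        reads = _evidence_reads(counts)
        c12, e12 = phase_pair(reads, V1, V2)
        c21, e21 = phase_pair(reads, V2, V1)
        assert c12 == c21
        assert e12 == e21
        assert e12.total == sum(counts.values())
        assert e12.ambiguous == counts[("T", "alt")]


def test_phase_rejects_cross_contig_and_homozygous():
    reads = _evidence_reads({("alt", "alt"): 4})
    with pytest.raises(ValueError, match="contig"):
        phase_pair(reads, V1, VariantCall("chr2", 102, "G", "C"))
    with pytest.raises(PhasingNotApplicableError):
        phase_pair(reads, V1, VariantCall("chr1", 102, "G", "C", zygosity="hom"))


def test_low_quality_bases_count_ambiguous():
    header = pysam.AlignmentHeader.from_references(["chr1"], [1000])
    a = _fragment(header, "f0", "ACCAAAAAAA", 99)
    a.query_qualities = pysam.qualitystring_to_array("I!IIIIIIII")  # Q0 at site 1
    call, ev = phase_pair([a], V1, V2, PhasingParams(min_fragments=1))
    assert ev.ambiguous == 1
    assert ev.informative == 0
    assert call == "unknown"


# -- merging ------------------------------------------------------------


def test_merge_adjacent_pair_to_delins():
    m = merge_cis_substitutions(V1, V2, phase_call="cis")
    assert (m.pos, m.ref, m.alt) == (101, "GG", "CC")
    assert m.zygosity == "het"
    # order-insensitive
    m2 = merge_cis_substitutions(V2, V1, phase_call="cis")
    assert (m2.pos, m2.ref, m2.alt) == (101, "GG", "CC")


def test_merge_refuses_trans():
    got = merge_cis_substitutions(V1, V2, phase_call="trans")
    assert got == (V1, V2)


def test_merge_gap_limit_and_reference_infill():
    ref = {"chr1": "A" * 100 + "GATCG" + "A" * 100}
    a = VariantCall("chr1", 101, "G", "C")
    b = VariantCall("chr1", 105, "G", "T")  # gap of 3 (ATC between)
    assert merge_cis_substitutions(a, b, ref, max_gap=2) == (a, b)
    m = merge_cis_substitutions(a, b, ref, max_gap=3)
    assert (m.pos, m.ref, m.alt) == (101, "GATCG", "CATCT")


def test_merged_edit_equals_sequential_edits(rng):
    """Applying the delins reproduces applying both substitutions — always."""
    for _ in range(50):
        seq = simulate.make_reference(60, rng)
        p1 = int(rng.integers(10, 40))
        gap = int(rng.integers(0, 4))
        p2 = p1 + 1 + gap
        alt1 = "ACGT"[(("ACGT".index(seq[p1 - 1])) + 1) % 4]
        alt2 = "ACGT"[(("ACGT".index(seq[p2 - 1])) + 2) % 4]
        a = VariantCall("c", p1, seq[p1 - 1], alt1)
        b = VariantCall("c", p2, seq[p2 - 1], alt2)
        m = merge_cis_substitutions(a, b, {"c": seq}, max_gap=5)
        assert isinstance(m, VariantCall)
        seq_both = list(seq)
        seq_both[p1 - 1] = alt1
        seq_both[p2 - 1] = alt2
        seq_merged = seq[: m.pos - 1] + m.alt + seq[m.pos - 1 + len(m.ref):]
        assert seq_merged == "".join(seq_both)


# -- protein consequences -----------------------------------------------


def test_codon_647_trio(mnv_cis_fixture):
    """GGG codon: each single sub is missense, the merged delins is Pro."""
    model, ref, (v1, v2), _ = mnv_cis_fixture
    single1 = annotate_consequence(v1, model)
    single2 = annotate_consequence(v2, model)
    assert single1 == ("c.1939G>C", ProteinConsequence("missense", "p.(Gly647Arg)"))
    assert single2 == ("c.1940G>C", ProteinConsequence("missense", "p.(Gly647Ala)"))
    merged = merge_cis_substitutions(v1, v2, {"chr1": ref})
    c, p = annotate_consequence(merged, model)
    assert c == "c.1939_1940delinsCC"
    assert p == ProteinConsequence("missense", "p.(Gly647Pro)")


def _long_cds_model():
    """Transcript whose codon 3102 is CAG (Gln); CDS long enough for it."""
    ref = simulate.make_reference(11000, 31)
    model, ref = simulate.embed_transcript(
        ref, transcript_id="TXL", start=200, exon_lengths=[9309],
        strand="+", rng=31,
    )
    model, ref = simulate.set_codon(model, ref, 3102, "CAG")
    return model, ref


def test_nonsense_at_gln_3102():
    model, _ = _long_cds_model()
    v = VariantCall("cds", 9304, "C", "T")  # CAG -> TAG
    got = protein_consequence(v, model)
    assert got == ProteinConsequence("nonsense", "p.(Gln3102*)")


def test_synonymous_third_base_edit():
    model, _ = _long_cds_model()
    cds = model.cds_sequence
    # find a codon whose third-base change is synonymous (Gly GGx works)
    from Bio.Seq import Seq

    for i in range(1, model.cds_length // 3 - 1):
        codon = cds[3 * i : 3 * i + 3]
        for alt in "ACGT":
            if alt == codon[2]:
                continue
            new = codon[:2] + alt
            if str(Seq(codon).translate()) == str(Seq(new).translate()):
                v = VariantCall("cds", 3 * i + 3, codon[2], alt)
                assert protein_consequence(v, model) == ProteinConsequence(
                    "synonymous", "p.(=)"
                )
                return
    pytest.fail("no synonymous edit found in random CDS (should not happen)")


def test_frameshift_matches_translate_until_stop_oracle(rng):
    """fs*N equals the stop position found by direct translation."""
    from Bio.Seq import Seq

    checked = 0
    while checked < 20:
        model, _ = simulate.embed_transcript(
            simulate.make_reference(3000, int(rng.integers(2**31 - 1))),
            transcript_id="TXF", start=100, exon_lengths=[900],
            rng=int(rng.integers(2**31 - 1)),
        )
        cds = model.cds_sequence
        pos = int(rng.integers(10, 400))
        dlen = int(rng.integers(1, 5))
        if dlen % 3 == 0:
            continue
        ref_allele = cds[pos - 1 : pos - 1 + dlen + 1]
        v = VariantCall("cds", pos, ref_allele, ref_allele[0])  # deletion
        got = protein_consequence(v, model)
        # oracle: translate the edited CDS codon by codon until a stop
        edited = cds[: pos - 1] + ref_allele[0] + cds[pos - 1 + dlen + 1 :]
        p_ref = str(Seq(cds).translate())
        p_alt = str(Seq(edited[: len(edited) // 3 * 3]).translate())
        i = 0
        while i < min(len(p_ref), len(p_alt)) and p_ref[i] == p_alt[i]:
            i += 1
        if p_alt[i] == "*":
            assert got.kind == "nonsense"
        else:
            stop = p_alt.find("*", i)
            assert got.kind == "frameshift"
            if stop >= 0:
                assert got.hgvs_p.endswith(f"fs*{stop - i + 1})")
            else:
                assert got.hgvs_p.endswith("fs*?)")
        checked += 1


def test_frameshift_hgvs_shape():
    """A 4-nt deletion yields the Xaa#Yaafs*N rendering."""
    model, _ = _long_cds_model()
    cds = model.cds_sequence
    v = VariantCall("cds", 157, cds[156:161], cds[156])  # 4-nt deletion at c.157
    got = protein_consequence(v, model)
    assert got.kind in ("frameshift", "nonsense")
    if got.kind == "frameshift":
        assert "fs*" in got.hgvs_p
        assert got.hgvs_p.startswith("p.(")


def test_variant_outside_cds_is_no_protein():
    model, _ = _long_cds_model()
    v = VariantCall("cds", model.cds_length + 50, "A", "C")
    assert protein_consequence(v, model).kind == "no_protein"


def test_consequence_of_merge_equals_joint_application(mnv_cis_fixture):
    """consequence(merged) == consequence of applying both components."""
    model, ref, (v1, v2), _ = mnv_cis_fixture
    merged = merge_cis_substitutions(v1, v2, {"chr1": ref})
    _, p_merged = annotate_consequence(merged, model)
    # joint application by hand: edit the CDS with both substitutions
    from dataclasses import replace

    cds = list(model.cds_sequence)
    cds[1938], cds[1939] = "C", "C"
    joint = replace(model, sequence=model.sequence[: model.cds_start - 1]
                    + "".join(cds) + model.sequence[model.cds_end :])
    from Bio.Seq import Seq

    aa_ref = str(Seq(model.cds_sequence[1938:1941]).translate())
    aa_joint = str(Seq(joint.cds_sequence[1938:1941]).translate())
    assert (aa_ref, aa_joint) == ("G", "P")
    assert p_merged.hgvs_p == "p.(Gly647Pro)"


# -- rescue driver ------------------------------------------------------


def test_rescue_cis_fixture_merges(mnv_cis_fixture):
    model, ref, (v1, v2), sim = mnv_cis_fixture
    out, audit = rescue_mnvs(
        [v1, v2], sim.records, model, reference={"chr1": ref}
    )
    assert len(out) == 1
    assert (out[0].ref, out[0].alt) == ("GG", "CC")
    assert len(audit) == 1
    assert audit[0]["action"] == "merged"
    assert audit[0]["hgvs_p"] == "p.(Gly647Pro)"


def test_rescue_trans_fixture_preserves_pair(mnv_trans_fixture):
    model, ref, (v1, v2), sim = mnv_trans_fixture
    out, audit = rescue_mnvs(
        [v1, v2], sim.records, model, reference={"chr1": ref}
    )
    assert out == [v1, v2]
    assert audit[0]["phase_call"] == "trans"
    assert audit[0]["action"] == "kept"


def test_rescue_mixed_pairs_match_hand_adjudication():
    """5 candidate pairs with known cis/trans/low-depth truth."""
    ref = simulate.make_reference(12000, 77)
    cfg = simulate.SimulationConfig(seed=77, contig_length=12000,
                                    per_base_error=0.0)
    # pair layout: (pos1, pos2, phase, depth)
    layout = [
        (1000, 1001, "cis", 30.0),
        (3000, 3001, "trans", 30.0),
        (5000, 5002, "cis", 30.0),     # gap 1
        (7000, 7001, "cis", 0.0),      # no coverage -> unknown
        (9000, 9001, "trans", 30.0),
    ]
    variants = []
    spec = []
    targets = []
    for p1, p2, phase, depth in layout:
        for p in (p1, p2):
            ref_b = ref[p - 1]
            alt_b = "ACGT"[("ACGT".index(ref_b) + 1) % 4]
            variants.append(VariantCall("chr1", p, ref_b, alt_b))
        a1, a2 = variants[-2], variants[-1]
        if phase == "cis":
            spec += [(a1.pos, a1.ref, a1.alt, (1,)), (a2.pos, a2.ref, a2.alt, (1,))]
        else:
            spec += [(a1.pos, a1.ref, a1.alt, (0,)), (a2.pos, a2.ref, a2.alt, (1,))]
        if depth > 0:
            targets.append((GenomicInterval("chr1", p1 - 300, p2 + 300), depth))
    sim = simulate.simulate_reads(ref, spec, targets, cfg)
    out, audit = rescue_mnvs(variants, sim.records, reference={"chr1": ref})
    by_pos = {row["pos1"]: row for row in audit}
    assert by_pos[1000]["action"] == "merged"
    assert by_pos[3000]["action"] == "kept"
    assert by_pos[5000]["action"] == "merged"
    assert by_pos[7000]["phase_call"] == "unknown"
    assert by_pos[7000]["action"] == "kept"
    assert by_pos[9000]["action"] == "kept"
    # hand-adjudicated output: 2 merged + 3 intact pairs = 2 + 6 records
    assert len(out) == 8
    assert len(audit) == 5


def test_rescue_passes_through_non_candidates(mnv_cis_fixture):
    model, ref, (v1, v2), sim = mnv_cis_fixture
    hom = VariantCall("chr1", 100, "A" if ref[99] != "A" else "C", "G"
                      if ref[99] != "G" else "T", zygosity="hom")
    # normalize: make a valid hom far from the pair
    hom = VariantCall("chr1", 100, ref[99], "ACGT"[("ACGT".index(ref[99]) + 1) % 4],
                      zygosity="hom")
    out, _ = rescue_mnvs([hom, v1, v2], sim.records, model,
                         reference={"chr1": ref})
    assert hom in out
    assert len(out) == 2


# -- VCF round trip -----------------------------------------------------


def test_vcf_round_trip(tmp_path):
    variants = [
        VariantCall("chr1", 101, "G", "C", "het"),
        VariantCall("chr1", 500, "AT", "GG", "hom"),
        VariantCall("chr1", 900, "C", "T", "hemi"),
    ]
    path = tmp_path / "v.vcf"
    write_vcf(variants, path, {"chr1": 2000})
    back = read_vcf(path)
    assert [(v.pos, v.ref, v.alt, v.zygosity) for v in back] == [
        (101, "G", "C", "het"), (500, "AT", "GG", "hom"), (900, "C", "T", "hemi"),
    ]


def test_vcf_merged_record_carries_sources(tmp_path):
    m = merge_cis_substitutions(V1, V2)
    path = tmp_path / "m.vcf"
    write_vcf([m], path, {"chr1": 2000})
    text = path.read_text()
    assert "MERGED_FROM" in text
    assert "2439" not in text  # sanity: only our contigs/positions present


def test_hgvs_c_rendering():
    assert hgvs_c(VariantCall("c", 1939, "G", "C")) == "c.1939G>C"
    assert hgvs_c(VariantCall("c", 1939, "GG", "CC")) == "c.1939_1940delinsCC"
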
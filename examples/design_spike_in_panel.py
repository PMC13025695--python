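"""Design a spike-in capture panel from a simulated cohort.

Builds a 6-sample depth cohort with two systematically undercovered
segments, a ClinVar-style table with deep intronic / UTR / leading-exon
splice P/LP variants, then runs the full design: low-coverage detection
(< 35 reads in >= 2 samples), harvest, target assembly and 120-mer probe
tiling.
"""

import numpy as np

from exoboost import regions, simulate, target_design

rng = np.random.default_rng(42)

# a transcript whose structure offers every non-coding variant class
reference = simulate.make_reference(12_000, rng)
model, reference = simulate.embed_transcript(
    reference, transcript_id="TX000001", start=800,
    exon_lengths=[180, 300, 500, 400], intron_lengths=[800, 5000, 900],
    utr5=250, utr3=149, rng=rng,
)

# cohort depths: 80x baseline, two spots dropping to ~10x in 3 of 6 samples
exome = regions.merge_intervals(
    [regions.GenomicInterval(e.contig, e.start - 20, e.end + 20)
     for e in model.exons]
)
spots = [
    (regions.GenomicInterval("chr1", exome[0].start + 10, exome[0].start + 90), 10.0, 3),
    (regions.GenomicInterval("chr1", exome[-1].start + 50, exome[-1].start + 130), 12.0, 4),
]
profiles = simulate.make_depth_profiles(
    exome, 6, mean_depth=80.0, lowcov_spots=spots, rng=rng
)

params = target_design.DesignParams(cohort_size=6)
lowcov = target_design.low_coverage_bases(profiles, params)
print(f"low-coverage regions (padded, merged): {len(lowcov)}")
for iv in lowcov:
    print(f"  {iv.contig}:{iv.start}-{iv.end} ({iv.length} bases)")

clinvar = simulate.make_clinvar_fixture(
    [model], reference,
    {"deep_intronic": 3, "utr_exonic": 2, "noncoding_exon_splice": 1,
     "coding": 2, "canonical_splice": 1},
    gene_names=["GENE001"], n_non_plp_coding=2, rng=rng,
)
harvested = target_design.harvest_noncoding(clinvar, {"GENE001"})
print(f"\nClinVar records: {len(clinvar)}, harvested P/LP non-coding: "
      f"{len(harvested)}")
for r in harvested:
    print(f"  {r.gene_symbol} {r.contig}:{r.pos} {r.hgvs_c} "
          f"[{r.consequence_class}]")

targets = target_design.build_targets(lowcov, harvested, params)
probes = target_design.tile_probes(targets, params.probe_length,
                                   params.probe_stride)
report = target_design.design_report(["GENE001"], harvested, targets, probes)
print(f"\ndesign: {report.n_target_regions} target regions, "
      f"{report.n_probes} probes, {report.total_target_bases} target bases")
# The harvested count is the number of clinically asserted non-coding
# variants the spike-in panel rescues; each contributes a padded window
# that is tiled with capture probes alongside the low-coverage segments.
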
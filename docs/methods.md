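# Methods

## Coordinate conventions

BED records are 0-based half-open on disk and in `GenomicInterval`;
anything mirroring VCF or HGVS (variant positions, CDS positions, codon
indices) is 1-based inclusive. All conversions live in
`exoboost.regions`. Transcript arithmetic operates in spliced 5′→3′
space; minus-strand genomic input is flipped exactly once at entry
(`TranscriptModel.transcript_position`), so orientation handling has a
single home. Codon *i* spans CDS positions 3i−2..3i, giving
`codon_index = ceil(cds_pos / 3)` and `codon_offset = (cds_pos − 1) mod 3`.

Intronic positions are expressed HGVS-style as (nearest exon boundary
base, signed offset): positive downstream of a donor, negative upstream
of an acceptor, ties to the donor. 5′/3′ UTR positions render as
`c.-n` / `c.*n`.

## Spike-in design

A base enters the low-coverage set when its depth falls below
`min_depth` in at least `min_samples` of `cohort_size` reference
profiles. Defaults (35 reads, 2 of 12 samples, 50 M reads per sample)
encode the rule used to predict undercaptured segments from a public
reference cohort. Flagged runs are padded by `lowcov_pad` (25 nt) and
merged with `merge_gap` (50 nt).

The ClinVar-style harvest keeps a record when its gene is in the panel
set, at least one submitter asserted Pathogenic or Likely pathogenic
(case-insensitive; slash-combined assertions such as
"Pathogenic/Likely pathogenic" count once), and its consequence class is
one exome capture misses: `deep_intronic`, `utr_exonic`, or
`noncoding_exon_splice` (the +1/+2 donor of an exon lying wholly 5′ of
the CDS). "Deep" intronic means |offset| > 8 nt — past the ±8 splice
region that exome probe padding already reaches; the cutoff is this
package's own, chosen to separate spike-in work from what the backbone
capture provides.

Each harvested variant contributes a `variant_pad` = 60 nt window per
side; windows and low-coverage runs are unioned and merged, then tiled
with `probe_length` = 120 nt probes at `probe_stride` = 120 (1×)
starting at the target start with the final probe right-aligned; targets
shorter than one probe get a single centered probe. Padding, merge and
tiling values follow common hybridization-capture practice; vendors do
not publish theirs, so published panel totals (region and probe counts)
are treated as report shapes rather than recomputable quantities.

## Coverage QC

Depth is **per-read**: each alignment record contributes its aligned
blocks (CIGAR M/=/X; deletions, introns and clips skipped), so
overlapping mates of one fragment count twice. This matches
depth-file-based counting and is isolated behind the
`depth_from_alignments` surface; unmapped, secondary and supplementary
records are always excluded, duplicates by default. DPk is the percent
of target bases with depth ≥ k; reported percentages are rounded
half-even to 2 decimals. The coverage table emits one row per sample per
region set plus an arithmetic-mean "Average" row; DP20 and DP50 columns
are both present so nuclear (DP20) and mitochondrial (DP50) conventions
can be read off the same table.

Downsampling to a total read budget B operates on fragments: exactly B/2
fragments are retained by seeded uniform sampling without replacement,
keeping both mates together and preserving input order, so exactly B/2
read-1 and B/2 read-2 records survive. Budgets must be even.

## MNV phasing and rescue

The phasing unit is the fragment (read pair pooled by query name):
mates derive from one molecule and therefore one haplotype. For a het
pair, each fragment observing both sites is classified alt-alt,
ref-ref, or one-alt-one-ref; fragments touching the pair with a
missing, low-quality (< Q13), conflicting-mate or third-allele
observation count as ambiguous. Because the cis diplotype is
{alt-alt, ref-ref} and the trans diplotype is {alt-ref, ref-alt},
ref-ref fragments are cis-consistent evidence: the call is cis when
informative fragments reach `min_fragments` (2), at least one alt-alt
fragment exists, and (alt-alt + ref-ref)/informative ≥
`min_consistency` (0.9); trans symmetrically with
trans/informative. Scoring consistency over all informative fragments
rather than only alt-bearing ones is what makes the call robust at
modest depth, where a single sequencing error that converts one
fragment into apparent trans evidence would otherwise sink the ratio.
Results are invariant under argument order.

Cis substitution pairs within `max_gap` = 2 nt merge into one delins:
reference allele is the spanned reference substring, alternate is
alt₁ + intervening reference + alt₂. No 3′-shifting normalisation is
applied (none is needed for fixed-span delins). The rescue driver scans
sorted calls left to right, phases each candidate het-substitution
pair, merges cis pairs, passes everything else through, and logs one
audit row per candidate pair with all four evidence counts; pairs
without usable coverage are logged `unknown` and left unmerged. Runs of
three or more substitutions merge greedily pairwise (a merged delins is
no longer a merge candidate), a deliberate simplification.

Protein consequences apply the allele to the spliced CDS and compare
translations. Length-preserving edits yield synonymous (`p.(=)`),
missense, nonsense, or an in-frame delins when several residues change;
length changes divisible by 3 yield in-frame del/ins/delins renderings;
otherwise a frameshift `p.(Xaa#Yaafs*N)` where N is the 1-based position
of the new stop in the shifted frame counting the first changed residue
as 1, `fs*?` when no downstream stop exists. Three-letter amino-acid
codes with `*` for stops follow clinical reporting style. Frameshift
N values are validated against a translate-until-stop oracle on
synthetic transcripts.

## Synthetic data

Generators are byte-deterministic under a fixed seed. References are
uniform ACGT; transcripts are written into the reference as
UTR5 + (ATG, internal-stop-free codons, TAA) + UTR3 over an arbitrary
exon/intron layout on either strand. Reads are emitted directly as
aligned SAM pairs (mates on opposite strands, M-only CIGARs, constant
Q40 qualities) with per-base substitution errors at the configured rate
(default 1%); fragment counts per region class are Poisson with mean
depth·len/(2·read_length), so overlapping classes add — spike-in
boosting is modelled as an extra fragment process on top of the
backbone, the simplest mechanism reproducing the observed
spike-in-versus-backbone coverage contrast. Defaults are 150 nt reads
and 350 ± 50 nt fragments. The truth table records each fragment's
haplotype; downstream checks read truth only from it.

What the simulator does **not** model: alignment ambiguity and mapping
error, indel or structural alleles in reads, GC and capture-sequence
bias, duplicate fragments, base-quality variation, and real splice-site
sequence content. Passing tests therefore demonstrate the correctness
of the bookkeeping, the cohort rule, the phasing logic and the
consequence arithmetic — not robustness to alignment artefacts, which a
real pipeline must get from its aligner and caller upstream.

## Problem sizes and numerical choices

Tests and examples use contigs of 2–20 kb, cohorts of 3–12 samples,
depths of 20–120× and 100-replicate phasing experiments; these sizes
were chosen so the full suite reruns in a few minutes while still
exercising every rule at realistic depths. Degenerate inputs are
contracts, not silent: empty profiles raise on DP/mean queries, orphan
reads raise during downsampling, out-of-span positions raise in
transcript lookups, malformed BED lines raise with their line number.
Merging abutting intervals at `max_gap` = 0 is intentional (capture
targets treat adjacent segments as one region).

## Known limitations

- Only substitution pairs merge; indel-adjacent MNVs are out of scope.
- One transcript model is used per rescue run; multi-isoform annotation
  policy is out of scope.
- The harvest consumes a documented tab-delimited ClinVar subset, not
  the live database: reproducibility over freshness.
- Genome-wide haplotype assembly (MEC-style optimisation) is explicitly
  not attempted; the phaser is local by design.
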
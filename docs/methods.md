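# Methods

## Data model

The central container is a samples × variants grid of diploid calls
(`GenotypeMatrix`), numpy-backed, with per-call read depth and a four-way
zygosity class: **hom**, **het**, **ambiguous**, **missing**. Coordinates are
1-based inclusive throughout (VCF/GFF convention); chromosome names accept
both `Chr4` and `4`, with `Chr00`/`0` denoting the unanchored
pseudo-chromosome.

Zygosity is classified from allele read fractions: homozygous when either
allele holds ≥ 90% of reads, heterozygous when the alternate fraction lies in
[0.40, 0.60], otherwise ambiguous ("indistinguishable as either"). A call
with zero reads is missing, not an error. Fractions in (0.60, 0.90) or
(0.10, 0.40) therefore land in the ambiguous class; by default ambiguous
calls are treated as missing wherever allele copies are counted (PIC, MAF,
IBS, the diagnostic screen), because nothing principled can be said about
their genotype. This is switchable (`FilterConfig.ambiguous_as_missing`).

A *half-missing* call (tabular dialect `G/-`) keeps its observed allele and
is flagged; each downstream operation decides its treatment explicitly: it
contributes one allele copy to PIC/MAF counting, is excluded from IBS and
dosage, participates in the diagnostic screen through its observed allele,
and in match-rate comparison is concordant iff that allele is consistent
with the partner call.

## Filtering

Filters run in a fixed, logged order — mapping quality → read depth →
biallelic → minor allele frequency — so removal counts are reproducible.
The depth rule masks individual calls below the threshold to missing and
removes variants with no observed call left; because masking is idempotent,
so is the whole chain. "Unmapped reads" is a read-alignment-stage criterion
that cannot act on a VCF; it is carried as a zero-count placeholder in the
log for completeness. Site-level mapping quality is taken from INFO/MQ when
present (variants without MQ pass); the VCF reader also accepts per-call AD
to classify zygosity, or a ZY tag written by this package's own writer.

## Marker informativeness and subset selection

PIC uses the Botstein formula on allele frequencies counted from allele
copies (hom = 2, het = 1 + 1). The evenly spaced subset takes up to
`max_per_interval` (default 4) markers per 0.5-Mb interval, requiring mean
depth > 3 and PIC > 0, ranking genic ahead of intergenic, then PIC
descending, then position ascending. Genic location is a *preference*, not a
hard filter — an interval with only intergenic candidates still contributes,
which is why a realistic selection contains a minority of intergenic markers.
`max_per_interval = 4` reflects that a strict one-per-interval reading cannot
reach realistic genome-wide subset sizes; both knobs are configuration. All
tie-breaking is deterministic, so selection is invariant to input order.

Window densities tile each chromosome with non-overlapping 100-kb windows
(last window truncated); hotspot region sums are recomputed from raw variant
positions, never from the binned counts, so a region that cuts through a
window is counted exactly.

## Panel structure

IBS sharing per locus is 1, 0.5 or 0 for two, one or zero shared alleles;
with both alleles in {ref, alt} this equals 1 − |dosage difference|/2, and
the pairwise distance is 1 − mean sharing over co-called loci (a pair with
no co-called locus is an error naming the pair). Neighbor-joining uses the
Saitou–Nei Q-criterion (via scikit-bio) with negative branch estimates
clamped to zero; on additive matrices the tree reproduces every input
distance exactly, which the tests verify against randomly generated additive
trees. PCA runs on dosage (0/1/2) with per-variant mean imputation of
missing dosages, keeping the sample dimension fixed.

## Diagnostic screen

A variant passes when all usable target-group calls are homozygous for one
allele, all usable complement calls are homozygous for another, and the two
differ. Missing calls never disqualify; heterozygous calls count as
deviations unless `allow_het`; up to `max_discordant_per_group` deviating
samples are tolerated (default 0). A group left empty at a variant skips the
variant with a log entry. Group consensus ties break toward the
alphabetically later allele among equally common ones; with the default zero
tolerance a tie cannot pass anyway.

## CAPS conversion

Amplicons are taken either as SNP ± `flank_bp` or delimited by a primer pair
(forward match on the plus strand, reverse-complemented reverse match
downstream, each required to occur exactly once within the search radius);
lengths outside 50–2000 bp raise a warning. The restriction scanner matches
the IUPAC recognition motif on both strands with overlapping occurrences,
emitting one top-strand cut per site event: `s + cut_offset_top` for a
plus-strand site at `s`, and the mirrored `s + k − cut_offset_bottom` for a
minus-strand site — for palindromes the two coincide and deduplicate. Cut
offsets may lie outside the recognition span (Type IIS enzymes such as BsrI
and BbsI); cuts falling off the sequence are discarded rather than raised.
The packaged 22-enzyme table carries REBASE recognition strings and offsets
and is an ordinary input, so users can substitute their own panel. A CAPS
candidate requires the two alleles' *cut-position sets* to differ — two
different single-cut positions are accepted, since they give distinguishable
fragments. Fragment lengths are consecutive differences of
{0} ∪ cuts ∪ {length} and always sum exactly to the amplicon length (a
constructor invariant).

## Match-rate validation

Validation compares two call vectors per marker — sequencing calls versus
assay calls. A sample pair is excluded only when both calls are fully
missing. A pair where exactly one assay gave no call cannot exhibit a
mismatch and counts toward agreement; this is the convention under which the
packaged 24-line validation panel's published per-marker rates (denominators
of 24: 22/24 = 0.92, 23/24 = 0.96) are reproduced exactly. Half-missing
calls are concordant iff the observed allele appears in the partner call;
full calls must agree as allele multisets. Rates are rounded to two
decimals.

## Synthetic data

The generator emulates the study design it is tested against: 24 inbred
lines (9 target, 15 complement), 12 chromosomes of 1 Mb, 10 genes of 3 kb
with 3 exons per chromosome, 5,000 biallelic SNPs, 1% planted diagnostic
loci (target group fixed for one allele, complement for the other), read
depth ~20× drawn negative-binomially, and zero default het/missing/ambiguous
noise as appropriate for inbred material — noise rates are per-call knobs
for robustness experiments. Half of the diagnostic loci additionally get a
restriction motif written into the reference flank with the SNP at a
non-degenerate motif position, so that exactly one allele is cut; planting
is verified against the scanner at generation time and skipped (not
mis-recorded) when a neighboring variant or an accidental second site would
spoil allele-differentiality.

Two guarantees make truth-table recovery exact rather than probabilistic:
background loci that would co-segregate with the groups by chance are
redrawn, and the default depth floor equals the depth-filter threshold
(3 reads), so filtering cannot silently delete the discordant calls that
keep a near-fixed background locus non-diagnostic. Lowering the floor is
how the depth filter is exercised deliberately. Everything derives from one
seed; bundles are byte-identical across runs.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, alignment artifacts, allele-frequency spectra of real
populations, InDels, and read-level data. Passing recovery tests therefore
demonstrates the correctness of the screening and conversion logic, not
performance on real resequencing panels.

## Pipeline

`run_pipeline` chains load → filter → annotate → select → structure →
screen → CAPS → optional validation, writing fixed-column TSV reports plus a
newick tree. The diagnostic screen runs on the **full filtered matrix**, not
the evenly spaced subset: subsampling four markers per interval would
arbitrarily drop diagnostic loci, and the genome-wide screen is what the
truth-recovery invariant checks end to end. Default problem sizes (5,000
SNPs × 24 samples) run the whole pipeline in a few seconds on one CPU.

## Known limitations

* Primer design (melting temperature, GC clamps) is out of scope; primers
  are inputs, or a symmetric flank stands in for them.
* dCAPS (mismatch-primer) designs are not generated.
* The screen's group consensus assumes a biallelic world; a third allele in
  a group simply reads as discordance.
* Fragment sizes are reported from top-strand cut positions; sticky-end
  overhangs (up to a few bases) are not reflected in the lengths, matching
  the convention of standard in-silico digestion tools.
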
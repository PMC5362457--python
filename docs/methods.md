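# Methods

## Study design and data model

The unit of analysis is a patient *trio*: one non-tumor exome and two tumor
exomes from spatially distinct regions (center, periphery) of a single
lesion. All read-level processing (alignment, deduplication, pileup) is out
of scope; evidence arrives tabulated as per-site depth, variant-read count
and mapping quality per sample, plus per-bin coverage counts on a shared
exome tiling. Coordinates are 1-based inclusive internally (VCF convention);
BED/bedGraph output is 0-based half-open, converted only at the file
boundary. VAFs are always recomputed from counts.

## Somatic filtering

SNVs must satisfy, per tumor region: mapping quality ≥ 20, tumor VAF ≥ 5%,
depth ≥ 10 in both tumor and non-tumor, ≥ 2 tumor variant reads, ≤ 1 normal
variant read, no candidate indel within 5 bp (measured to the indel's
leftmost affected base, the VCF anchor), and no more than 2 SNVs in any
10-bp window. Indels must satisfy depth ≥ 20 in both samples, VAF ≥ 10%,
≥ 5 variant reads and zero normal variant reads. All comparisons are
inclusive exactly as stated; all failed rules are reported (no
short-circuiting), so rejects are auditable. Design choices where the rules
underdetermine behavior:

* the window rule removes **all** SNVs of an offending window — the unique
  order-independent choice;
* rules are evaluated per tumor region independently; clonality is decided
  later by cross-region interrogation, not by the filter;
* the window rule counts raw candidate SNVs of the same region (not only
  survivors of the other rules), keeping the rule a pure function of the
  candidate table.

Known polymorphisms are excluded by exact (chrom, pos, ref, alt) match
against a supplied list, and sites outside the exon/splice-site annotation
are flagged NON_EXONIC.

## Clonality classification

A mutation passing the filter in both regions is **common** without further
interrogation. A single-region pass is cross-interrogated in the other
region's raw evidence; *presence* there means ≥ 2 variant reads at depth
≥ 10 (the same evidence minimum the filter uses; configurable), which also
yields **common**. Absence at depth < 10 yields **unresolved** — absence
cannot be asserted without coverage. Absence with coverage makes the
mutation a private candidate scored against orthogonal AF measurements: it
is **confirmed** (private) when the harboring region exceeds the non-tumor
AF by ≥ 5% and the other region does not; **refuted** and relabelled common
when both regions exceed; and treated as an unsupported artefact
(unresolved) when not even the harboring region exceeds. Missing
measurements leave the candidate private with status *untested*. Note the
status vocabulary distinguishes an assay that was never run (*untested*)
from one that ran and failed to support the variant (*unsupported*).

Median-VAF conventions (not fixed by the workflow's description): private
mutations contribute the harboring region's VAF; common mutations contribute
the mean of the two tumor regions' VAFs. Counts and private fractions cover
non-synonymous mutations; spectra cover all SNVs.

## Mutation spectra

Substitutions are collapsed onto the pyrimidine strand into six paired
classes (C>T/G>A, C>A/G>T, C>G/G>C, T>C/A>G, T>A/A>T, T>G/A>C). A C>T/G>A
event is a CpG event when G is immediately 3′ of the mutated C (or C
immediately 5′ of the mutated G on the plus strand). Records without a
trinucleotide context are excluded from both numerator and denominator of
the CpG fraction and counted separately.

## Driver tiering

Non-synonymous mutations in knowledge-base genes are tiered with precedence
high_confidence > putative > unknown: an exact (gene, amino-acid-change)
match to a known mutation or a SIFT score < 0.05 (strict) is high
confidence; a parseable residue position within 5 residues (inclusive) of
any known mutation of the gene is putative; a bare gene match is unknown.
Proximity is measured in **residues**, since the underlying annotations are
residue-level. Splice-site or frameshift records without parseable positions
can only be promoted via exact match or the manual-review list, which
promotes listed (gene, aa_change) pairs to high_confidence with full
logging. Tiering is a pure function of (record, KB, promotions) and hence
order-invariant. The packaged KB fixtures are synthetic stand-ins for
non-redistributable COSMIC/SIFT extracts (see
`src/ith_exome/data/driver_kb/README.md`).

## Read-depth CNV model

Reference profiles (≥ 10; fewer is a hard error) are each scaled to a common
total count; the per-bin mean and SD across the panel absorb capture,
GC, library and inter-sample biases. Bins with zero panel SD or near-zero
mean are masked. A test sample is scaled the same way and additionally
recentred so its genome-wide **median ratio** to the model mean is 1, with a
second pass that re-estimates the scale from bins within 3 SD of neutral:
pure total-count correction is confounded by the aberrant fraction itself (a
tumor gaining tens of megabases drags every diploid bin below the panel
mean), and the median of a one-third-aberrant genome is still biased by
about 0.7 noise-SD. Both steps keep the profile invariant to uniform count
scaling. The approach assumes the majority of the exome is copy-neutral;
when more than half the genome is aberrant the majority state becomes the
baseline (an intrinsic limit of depth-only normalization).

Calling: maximal same-sign runs of ≥ 5 consecutive bins (`min_bins`,
suppressing isolated outliers) with |z| ≥ 2 against the panel model become
segments. A segment's expected deviation under a clonal copy state is
`100·t·(cn−2)/2` percent at tumor content `t` (germline calling uses t = 1);
the copy-state grid is cn ∈ {0..4}. The segment call is the unique clonal
state whose expectation lies within the concordance tolerance
`max(10, 2·100·SD/mean)` (strict inequality) of the observed mean deviation;
otherwise the call is *ambiguous*, with every feasible interpretation listed
— including subclonal-tumor and non-tumor readings at the implied cell
fraction `dev/(100·(cn−2)/2)`. With these definitions an observed +30% at
60% tumor content is an unambiguous heterozygous duplication while +20%
is ambiguous between a subclonal duplication and a duplication of the
admixed non-tumor tissue, as the worked examples require. A unique clonal
fit is not demoted by the always-present subclonal alternatives; ambiguity
requires zero or several clonal fits.

The 5-Mb tumbling-window median smoother is presentation-only; calling
operates on unsmoothed bins. Center/periphery comparison paints per-bin call
states from both segment sets and reports maximal discordant intervals,
flagging those involving an ambiguous call separately.

## Synthetic cohort generator

The generator defines the study conditions every test runs under:

* **Scale** — 4 trios + 10 reference exomes on 3 × 60 Mb chromosomes tiled
  into 100-kb bins (the bin width resolves tens-of-megabase events with
  hundreds of bins while keeping tests second-scale); per patient 24–41
  common non-synonymous and 12–14 silent mutations, 0–14 private mutations
  per sample, 2 indels, and 5 germline polymorphism decoys listed in the
  exclusion fixture.
* **Purity** — per-region tumor content defaults average ≈ 0.47 (range
  0.35–0.70) with the peripheral sample slightly purer, reproducing the
  slightly higher peripheral allele frequencies such designs show.
* **Spectrum** — default class weights (0.48, 0.12, 0.08, 0.18, 0.07, 0.07)
  put 48% of substitutions in C>T/G>A with 45% of those at CpG sites; the
  non-dominant weights are plausible values for a C>T-dominated carcinoma
  and are not separately constrained. Hypermutator mode (default: patient
  4's peripheral sample) draws that sample's private mutations from a
  C>A/G>T-dominated spectrum (weight 0.45) with an inflated count, emulating
  a mismatch-repair-deficient region.
* **Counts and noise** — per-site depth and per-bin coverage are negative
  binomial with variance m + d·m², d = 4 × 10⁻⁴ (d = 0 is the deterministic
  noise-free limit); at the default 109× target depth this gives ≈ 10%
  per-site depth CV, and ≈ 2% per-bin CV at the ≈ 10⁵ reads a 100-kb bin
  collects with 100-bp reads — a realistic residual for panel-normalized
  large bins. Variant reads are binomial at the expected VAF
  `purity·ccf·multiplicity/(purity·cn + (1−purity)·2)` plus Poisson spurious
  reads at a per-base error of 10⁻³ (of which a third support a given alt).
  A shared multiplicative log-normal bias field (σ = 0.3) links the panel
  and all samples, emulating capture bias. Orthogonal AF re-measurements add
  Gaussian noise (SD 0.02) truncated to [0, 1].
* **Placement** — planted sites keep ≥ 25 bp separation so the proximity
  rules are not tripped by construction; trinucleotide contexts are written
  at planting time rather than read from a reference sequence, since context
  (not sequence) is what downstream statistics consume. Consequence labels
  are assigned at planting (no codon model); indels carry no spectrum, as
  none is specified for this design.
* **Truth** — the serialized truth (JSON) carries every planted mutation
  with clonality and context, every CNV segment with region and copy number,
  and the purities, sufficient to score any stage without re-running the
  generator.

What the generator does **not** emulate: mappability artifacts, strand
bias, FFPE damage, germline structure beyond the listed polymorphisms,
subclonal CCF distributions (planted CCF is 1), or real exon geometry
(the exon annotation equals the bin tiling). Passing tests therefore
demonstrate correctness of the rules and estimators under the stated noise
model, not robustness to raw-data pathologies upstream of the tabulated
evidence.

## Numerical and reproducibility choices

Threshold comparisons at published boundaries (e.g. a 5% AF difference) use
an absolute epsilon of 10⁻¹² so float rounding cannot flip an inclusive
rule. Clinical descriptives use exact decimal arithmetic with half-up
rounding to one decimal (a true mean of 7.05 prints 7.1). All randomness
flows from one `numpy` Generator seeded per run; identical config + seed
reproduces byte-identical tabular outputs, and the config hash embedded in
every artifact header covers the scientific parameters only (not output
paths). Problem sizes in the test suite (2-chromosome genomes, 50-replicate
CNV recovery, 20-seed fraction recovery, 10⁴-event spectra) were chosen to
give tight statistical checks at seconds-to-minutes runtime.

## Known limitations

* Depth-only CNV calling cannot separate a majority-aberrant genome from a
  rescaled baseline, has no allele-fraction (BAF) channel, and reports
  amplitudes beyond cn = 4 as ambiguous against the nearest grid state.
* The clonality labels are rule-based presence/absence decisions, not
  cancer-cell-fraction inference; two-region sampling underestimates the
  true extent of heterogeneity by design.
* The driver KB ships as editable fixtures; tiers are only as good as the
  knowledge base supplied.
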
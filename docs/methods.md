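# Methods

## The analysis in one paragraph

A recombinant AAV (rAAV) prep is never pure vector genome: producer-cell
DNA, packaging-plasmid fragments, bacterial carryover and unassignable
("foreign") DNA are co-packaged or co-purified. Single-stranded virus
sequencing captures all of it — the library protocol denatures every
molecule, so ssDNA vector genomes and dsDNA contaminants enter the same
library. `ssvdecon` decomposes such a read set into a species percentage
profile by competitive alignment against a panel of candidate references,
and reads the ±DNase contrast as a localization assay: DNA inside capsids
is nuclease-protected, DNA outside is not.

## Reference panel and homology masking

Several panel members legitimately share sequence: the ~145 bp inverted
terminal repeats (ITRs) appear in both the vector genome and the vector
plasmid backbone, and gene-editing donors carry homology arms copied from
the producer genome. A read from such a segment would hit several
references equally well, so the segment is detected up front and
hard-masked (bases → N) in every record except one deterministic owner.

* Detection: shared 15-mer seeding between record pairs (both strands),
  ungapped extension along each seeded diagonal. A window is reported when
  it is ≥ 50 bp at ≥ 90% identity; the mismatch penalty of the extension
  (+1/−9) is chosen so a window is score-positive exactly when its identity
  exceeds 0.9. Overlapping windows on the same target merge.
* Ownership: a fixed priority order decides which copy stays unmasked —
  vector genome first, then plasmid backbone, helper, Rep-Cap, the lambda
  spike-in, baculovirus, *E. coli*, and the producer genome last. The
  rationale: %rAAV genome is the purity figure of merit, so shared
  ITR/cassette/arm sequence counts toward the vector genome, and a
  homology-arm read is evidence of vector, not of producer DNA. The choice
  is a convention, not an inference; with a different priority order the
  same reads would be credited differently.
* The masked panel is a fixed point: re-running detection on it finds
  nothing, because N matches nothing (not even another N).

Coordinates are 0-based half-open throughout; masks are serialized as a
BED-like TSV next to the panel FASTA.

## Read classification

The aligner is an internal k-mer seed-and-extend implementation (k = 21
exact seeds against the unmasked panel, grouped per diagonal; ungapped
extension scored match +1 / mismatch −4; an affine-gap local-alignment
fallback with gap open −6 / extend −1 — a length-L gap costs −6 − L — when
the ungapped window fails the identity ≥ 0.90 or length ≥ 50 thresholds).
Both read orientations are queried; the best hit per reference is kept.
An internal implementation was chosen over wrapping an external mapper so
that the whole pipeline is self-contained and checkable against a
brute-force Smith-Waterman oracle; on error-free reads the two agree on
≥ 99% of placements (co-optimal positions counted as agreement).

Pair assignment: the pair score per reference is the sum of the best
mate scores; the top species must beat the runner-up species by ≥ 5 score
points, otherwise the pair is *ambiguous*. Ambiguous pairs fold into the
*unmapped* bucket for the headline table (the published category set has
no "multi" bucket); their count is retained separately. QC-rejected pairs
(adapter-trimmed below 30 nt, or mean quality < Q20) are excluded from the
denominator entirely. Percentages are deduplicated read-count fractions,
not base-coverage fractions — the simpler reading, and the one consistent
with UMI molecule counting.

UMI deduplication: mapped pairs collapse when they share (UMI, species)
and their positions agree within 2 bp (alignment-end wobble from leading
sequencing errors); UMIs at Hamming distance 1 at the same position also
collapse (sequencing error in the UMI itself). Unmapped pairs collapse on
(UMI, first 30 nt). Grouping by UMI *before* clustering positions matters:
with tens of thousands of molecules on a 4.7 kb genome every position is
occupied, and chaining positions first would link the whole reference into
one cluster and collapse unrelated molecules that happen to share a UMI
(8 nt UMIs collide at rate 1/65,536, which is thousands of pairs at this
depth).

## Coverage and SNVs

Per-base coverage on the vector genome is normalized per 1,000: each
base's deduplicated read count divided by the summed coverage of the whole
genome, × 1000. The track always sums to 1000 (when any read maps) and is
invariant to depth, so samples of different sequencing depth are directly
comparable.

SNVs are aggregated with a combined-alternative rule: at each position
with depth ≥ 20 in a sample, the alt fraction is (depth − reference-base
count)/depth, i.e. all alternative alleles summed. A position is *present*
in a sample when that fraction is ≥ 0.01, and reported when present in at
least ⌈S/2⌉ of S samples, with the reported fraction the mean over the
samples where present. The depth and fraction thresholds are this
package's choices (calibrated to suppress calls from the 10⁻³ per-base
error process, which produces per-sample alt fractions an order of
magnitude below 0.01); "half of all samples" is read conservatively as
⌈S/2⌉.

ITR placement caveat: the two ITRs of one genome are reverse complements,
so an ITR read matches both ends co-optimally; ties are broken
deterministically toward the lower coordinate, which concentrates ITR
coverage at the left end. Coverage and SNV statistics inside ITRs should
be read with that in mind.

## DNase-differential localization

Removing extra-capsid DNA mechanically inflates every surviving species'
raw percentage, so raw percentages cannot be compared across the ±DNase
pair. Each contaminant's share is therefore normalized to the rAAV-genome
share of the same profile (the vector genome is fully protected and acts
as the yardstick); global renormalization then cancels exactly. The log2
change of that ratio across the pair is thresholded at ±1: a drop of at
least 2-fold calls the species *extra_capsid*, less than 2-fold in either
direction is *intra_capsid*, and undefined ratios (species below a 0.01%
floor in both profiles, or zero shares) are *indeterminate* — as is an
apparent ≥ 2-fold relative *enrichment*, which the protection model cannot
produce and which therefore signals noise. The 2-fold threshold separates
the two regimes visible in the published prep-2 numbers themselves: the
human genome drops 5.7-fold (log2 ≈ −2.51) while the helper plasmid drops
1.97-fold (log2 ≈ −0.98).

The lambda spike-in is the digestion control: lambda DNA is never
encapsidated, so the +DNase control run must retain at most 1% of the
−DNase molecule count.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions, and everything downstream is validated against its ground
truth.

* References: producer genome 200 kb segment, rAAV genome 4.7 kb (ITR +
  800 bp left arm + cassette + 800 bp right arm + reverse-complement ITR,
  arms copied verbatim from producer loci), 3 kb backbone carrying both
  ITRs, 10 kb helper, 7 kb Rep-Cap, 50 kb *E. coli* segment, 20 kb
  baculovirus, 48.5 kb lambda, 20 kb foreign; all but the copied segments
  i.i.d. uniform DNA. Byte-deterministic under the seed.
* Reads: a prep is a mixture over species with stated fractions; with
  DNase, species *s* keeps weight `f·(enc + (1−enc)·(1−efficiency))`,
  renormalized (the spike control instead thins binomially, since its
  molecule count is the measured quantity). Fragments are ~Normal(300, 60)
  truncated to [50, 500] (sonication), starts uniform, strand uniform
  (the library protocol denatures everything, so strand carries no
  information and no ssDNA-specific bias is modelled). Substitution errors
  are i.i.d. at 10⁻³; no indel errors. Qualities are flat Q30 — quality is
  only ever used as a filter, so a flat model keeps the filter testable.
  Fragments shorter than the read length read through into the adapter.
  5% of molecules emit a PCR duplicate (same fragment and UMI, fresh
  errors) to exercise deduplication. A sidecar truth table records every
  read's molecule, species and position; truth never enters the FASTQ.
* Compositions: the published prep decomposition tables are encoded in
  `ssvdecon.tables` and used as simulation inputs (each column rescaled to
  sum to 1, with the unmapped row played by the `foreign` species, which
  is excluded from every panel by construction).
* Phenotypes: %CFU per condition follows `intercept + slope·purity` with
  donor-level Gaussian noise (defaults 5.0 + 0.2·purity, sd 2 — chosen so
  the dirtiest and cleanest published preps span roughly a two-fold
  difference in clonogenicity); plate counts are Poisson at 300/100/25
  cells × duplicate plates, split over colony morphologies
  (erythroid : myeloid ≈ 60 : 40, 3% mixed CFU-GEMM). Ct values are
  Normal around planted log2 fold changes with the β-actin reference held
  invariant; viability trajectories drop after transduction with a
  contamination-dependent term and partially recover by day 5.

What the generator does *not* emulate — hence what passing tests do not
show about real data: ITR secondary structure and its coverage artifacts,
GC/coverage bias, indels and structural variants, chimeric reads, real
UMI error processes beyond single substitutions, partial/truncated vector
genomes, and empty capsids. Composition recovery on this generator
demonstrates that the classifier is unbiased under the stated error model,
not that real preps are free of harder artifacts.

## Phenotype statistics

* %CFU per plate is 100 × colonies / cells plated; a condition is the mean
  over plates.
* The erythroid/myeloid split counts BFU-E + CFU-E vs CFU-GM + CFU-G +
  CFU-M; mixed CFU-GEMM colonies belong to neither arm and are reported
  separately.
* The purity-clonogenicity regression is ordinary least squares with the
  two-sided t-test on the slope; it matches a normal-equations oracle to
  1e-10 relative.
* ΔΔCt: technical replicates are averaged first; ΔCt = Ct_gene − Ct_ACTB
  per condition, ΔΔCt relative to the mock condition, fold = 2^(−ΔΔCt).
* Group comparisons use Welch's t-test — the source analyses never name
  their test, and unequal variances are the safe default at n = 3 donors —
  with stars at p < 0.05 / 0.01 / 0.0005 / 0.0001. No multiple-testing
  correction is applied (comparisons are reported per-pair, matching the
  source presentation); treat the stars accordingly.
* Viability is summarized descriptively (mean ± sd per condition and day);
  no significance testing is attached to it.

## Numerical and design notes

* Alphabet is {A, C, G, T, N}; N never matches, including N-vs-N.
* Ties in competitive assignment break deterministically (score, then
  ref id, then position), so runs are reproducible to the byte.
* Degenerate inputs are contracts, not crashes: zero-coverage tracks warn
  and return zeros; profiling zero assignments, regressing on constant x,
  zero classified colonies, and a zero −DNase spike count raise
  `ValueError`.
* The Welch p-value agrees with the exact permutation p-value to ±0.02 in
  the moderate-effect regime; deep in the tail the permutation p is
  floored at 1/924 for 6+6 samples and the two legitimately diverge.
* Problem sizes used by the test suite and the acceptance script:
  composition recovery runs 50,000 read pairs per prep against full-size
  references; unit tests use compact references (12 kb producer segment)
  where composition bias from homology reassignment is expected and
  asserted as such; the masking fixed-point sweep uses 20 seeds with a
  50 kb producer segment.

## Known limitations

* The chromosome-level read-density view is reduced to density per
  reference segment (the producer genome is a single ≤ 1 Mb stand-in
  segment, not a full genome with chromosomes).
* Localization is a three-way verdict, not a continuous encapsidation
  estimate; titer changes between the ± reactions are not modelled.
* The secondary-panel triage of unmapped reads is a local stand-in for a
  public-database search; it annotates, and never moves reads between
  headline categories.
* Whether published decomposition percentages are read fractions or base
  fractions is not stated in the source; read fractions are assumed
  throughout.
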
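# Methods

This note documents the models, defaults and design choices behind
rilmap, in the order the pipeline runs them.

## Simulated study design

The simulator reproduces the design of a biparental RIL RAD-seq
experiment with full ground truth.

**Founders.** Two fully homozygous genomes share a random backbone and
differ only at a configured list of variants (SNPs, and 1–10 bp indels
at a default 8 % of variants, matching the SNP:indel ratio typical of
RAD marker sets). By default every variant is placed inside a 92-bp
RAD tag window of a planted EcoRI site (G/AATTC; sites spaced 1,500 bp)
so that each variant is discoverable by the genotyper, with one variant
per tag window and ≥ 92 bp between variants; a flag allows multi-variant
tags to exercise the marker-caller's rejection path. Variants are
rejected and re-drawn if they would create or destroy a recognition
site, so both founders digest into the same site set. With
`at_cut_sites=False` variants are placed uniformly and no sites are
planted — the fast path for genotype-level simulations.

**Pedigree.** The F1 is heterozygous genome-wide; each generation one
selfed offspring is kept (single seed descent) until F8 (7 meioses, so
expected residual heterozygosity (1/2)^7 ≈ 0.78 %, which is simulated,
not forced to zero, so the genotyper's H path is exercised). Meiosis
draws Poisson(L_cM/100) crossovers per chromosome with breakpoints
uniform in genetic coordinates and no interference — chosen
deliberately so the Haldane map function is *exact* for the simulated
process and closed-form oracles exist; recombination rate is uniform
along each chromosome.

**Library.** Reads are emitted from both flanks of every cut site
(standard RAD), as barcode (8 nt) + 92-bp tag = 100 bp; both flank tags
begin `AATTC`. Depth is drawn per (site, flank, haplotype) with
per-haplotype mean `mean_depth / n_haplotypes` (Poisson, or fixed for
deterministic tests); default mean depth 20× reflects routine RAD
practice. Substitution errors are applied per base at the configured
rate (default 0.1 %, bounded at 5 %); barcodes are error-free by
default since demultiplexing is by exact match, with an optional
barcode-error rate to exercise the unassigned-read sink. Qualities are
a fixed Q35 placeholder — quality modeling is out of scope.

**What the simulator does not emulate** (hence what passing tests do
not show about real data): PCR duplicates, depth over-dispersion beyond
Poisson, allele-specific amplification bias, restriction-site
polymorphism (allele dropout), paralogy beyond exact repeats, missing
data that is non-random in the genome, and segregation distortion.

## k-mer survey

Canonical k-mers (lexicographic min of forward and reverse-complement
encodings; k odd, ≤ 31, default 17) are counted in memory with a 2-bit
rolling encoding — the scale target is desk-size simulations, not
billions of k-mers. The peak depth is the modal histogram depth at
depth ≥ 4 (excluding the sequencing-error bump; ties break to the
smaller depth), genome size is volume/peak, and coverage is total
sequenced bases over genome size. Note the peak estimates *k-mer*
coverage, lower than base coverage by (L−k+1)/L for read length L —
with 100-bp reads and k=17 that factor is 0.84, which is why a 26.9×
dataset peaks near 22. Simulation tests therefore use 1-kb reads where
the two coverages nearly coincide. The volume share above a repeat
threshold (default 2·peak) is reported as a k-mer-volume statistic
only; no genome repeat-fraction formula is implied, since no exact
relation links the two without a mixture model.

## RAD genotyping

Demultiplexing is exact-prefix barcode matching (mismatching reads are
counted, not rescued), tags are the 92 bp after the barcode, and
clustering is by sequence identity — sequencing errors stay as separate
low-count tags and are removed by depth thresholds rather than merged.
Tags with more than 100 reads are treated as repetitive and dropped
(boundary: exactly 100 is kept). Marker calling compares the two
parents' tag sets: identical tags are monomorphic and removed; a SNP
marker is a unique cross-parent pair at Hamming distance exactly 1
(each tag at depth ≥ 3); an indel marker is a unique single-gap
alignment (gap 1–10 bp, zero mismatches, free terminal overhang).
A Hamming-1 pair is never also considered for a gapped alignment, and
any tag with two or more candidate partners is discarded — the
conservative choice against paralog collapse. Where a gap placement is
ambiguous inside a repeat run, it is placed at the end of the longest
common prefix (checking there is exhaustive: any valid placement left
of the prefix end implies validity at the prefix end), and the smallest
fitting gap length wins. RILs are scored A/B/H by which parental tags
reach depth ≥ 3, else missing. Defaults (pairing distance 1, depth 3)
are declared choices, configurable, not inferences from any particular
dataset.

## Linkage map

Heterozygous calls are treated as missing in two-point counts: the F8
analysis is effectively two-class and a residual heterozygote's
recombinant status is ambiguous. Pairs need ≥ 10 informative RILs.
`R̂ = k/n` is clamped to ≤ 0.5 before the Haldane–Waddington inversion
`r = R/(2(1−R))` (the selfing-RIL∞ limit; the exact-F8 correction
differs negligibly at these generation numbers and is a documented
approximation). LOD uses `n·log10 2` when k = 0, the exact closed form
of the likelihood ratio at R̂ = 0.

Grouping is single-linkage over edges with LOD above a threshold,
starting at 6. The threshold then moves stepwise (0.5 LOD) *toward*
the target group count (the chromosome number): down, admitting only
edges that join a small group (< 5 % of markers) to another group, to
a floor of 3; or up, when a sampling-tail pair has falsely merged two
chromosomes at the starting stringency — with ~10^5 unlinked pairs a
binomial tail of ~10^-7 per pair is occasionally realized. The
(threshold, count) trace is returned; failing to reach the target is
reported, not fatal.

Ordering minimizes COUNT = Σ adjacent-pair `k` (pairs with no
informative RILs contribute 0, i.e. missing cells are imputed
non-recombinant). Groups of ≤ 7 markers are solved exactly by
permutation enumeration (halved by reverse symmetry); larger groups use
randomized greedy insertion followed by window ripple of sizes 2 and 3
until no improvement, best of 10 seeded restarts. Orders are
orientation-normalized so the lexicographically smaller terminal marker
comes first. Consecutive markers with zero observed recombinants (on
at least one informative RIL) merge into a locus named for its first
member. Adjacent-locus distances use the corrected r between locus
representative (first-member) markers through the Kosambi function by
default — the de-facto standard for legume RIL maps — with Haldane
selectable; an unlinked adjacency (r = 0.5) is capped at 50 cM and
flagged rather than breaking the group. Groups are named SLG-1, SLG-2,
… by descending genetic length. Gaps are adjacent-locus intervals above
20 cM. Summaries carry exact column sums; densities are reported at
one decimal.

## Anchoring and traits

A marker anchors where its reference-parent tag matches exactly, full
length, on either strand, at exactly one site of exactly one scaffold —
a strict reading of "unique 100 % match" that is deterministic and
needs no aligner; multi-site matches even within one scaffold are
rejected as ambiguous. Anchor coordinates are 1-based on the scaffold
forward strand at the variant offset. A scaffold whose markers land in
two or more groups is a conflict, reported and excluded from per-group
counts.

A binary trait is treated as one extra two-class marker (R/S mapped to
the donor/other parent's allele; F8 phenotypes are assumed to report
homozygous classes — dominance is a documented limitation). The trait
joins the group of its best-LOD marker and sits at the locus of its
best-supported zero-recombinant marker set when one exists, else at
the best-LOD locus; marker distances are map-position differences
within that group. "Linked" means within a 5 cM window (configurable);
"co-segregating" means zero observed recombinants. Candidate scaffolds
are the anchored scaffolds of co-segregating markers, with an empty
annotation slot (gene prediction is out of scope). Panel validation
reports the genotype–phenotype concordance fraction, excluding and
counting samples with missing genotypes.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds (one per configured
stage in the pipeline driver, derived from the single run seed); the
same configuration and seed give byte-identical FASTQ and CSV outputs.
Tabular interchange is headered CSV with stable column order; the run
manifest is JSON. Degenerate inputs are explicit errors (infeasible
variant density, duplicate barcodes, empty histograms above the error
bump) rather than silent truncation.

## Problem sizes used by the test suite and acceptance script

Chosen as the smallest sizes at which the statistical checks have
adequate power: parameter recovery uses 5 chromosomes × 100 markers ×
94 RILs at the genotype level; the end-to-end RAD run uses 2 × 150 kb
chromosomes, 40 variants, 94 RILs at fixed 6× depth (error-free);
ordering-oracle checks use up to 7 markers over ~1,000 random
instances; heterozygosity checks use 50 independent single-variant
chromosomes × 200 RILs so binomial bounds apply exactly.
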
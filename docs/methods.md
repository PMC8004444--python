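# Methods

## Problem and scope

kaspforge converts a multi-sample SNP genotype panel (VCF or tabular), a
reference genome (FASTA) and a gene annotation (GFF3) into KASP-assay-ready
SNP markers. KASP (kompetitive allele-specific PCR) genotyping interrogates
one SNP with two allele-specific forward primers — each ending on the SNP
base and carrying a distinct universal tail read out as FAM or HEX — plus
one common reverse primer. A SNP makes a good KASP marker when it is highly
polymorphic across the germplasm of interest and when its primer footprint
amplifies a single, sequence-stable genomic locus. The package screens for
exactly those properties and then designs the primer triplets.

Read alignment and variant calling are out of scope: the pipeline starts
from called genotypes. GO enrichment, wet-lab validation and downstream
breeding applications are likewise out of scope; reports carry gene ids so
users can run enrichment elsewhere.

## Polymorphism model

Polymorphism is scored per locus with the polymorphism information content

    PIC = 1 − Σ_j p_j²,

where `p_j` is the frequency of the j-th *pattern* among genotyped samples.
A pattern is an allelic state: a single base for homozygous/haploid calls,
or a sorted pair such as `A/G` for heterozygous diploid calls. Panels of
inbred lines are effectively haploid, so patterns are usually plain bases;
the pattern formulation keeps the statistic well defined when residual
heterozygosity occurs. A heterozygous call is kept as its own pattern by
default (`het_policy="pattern"`), or can be treated as missing
(`het_policy="missing"`) to mimic strict-inbred handling.

PIC is computed over non-missing calls only; missingness is handled by two
separate count filters (below). PIC is 0 for a monomorphic site and reaches
1 − 1/k at equal frequencies of k patterns: 0.50 for bi-allelic sites, 0.75
for four alleles. Loci with more than four patterns are tolerated but
flagged.

Substitutions are classified directionally (ref→alt, so `T>C` and `C>T`
tally separately) into transitions (A↔G, C↔T) and transversions. The Ts/Tv
ratio is computed over bi-allelic single-base loci only.

## The screen

A locus reaches the **standard** tier when all of the following hold, tested
in a fixed order (the first failure is what the rejection tally records:
pattern-count → PIC → genotyped-count → flank → uniqueness → conservation):

1. exactly two observed patterns, both single bases;
2. PIC ≥ `min_pic` (default 0.4);
3. at least `min_genotyped` genotyped samples (default 100);
4. both `flank_len` (default 20 bp) flanks extract cleanly — no chromosome
   edge, no ambiguity base;
5. the upstream flank maps to exactly one genomic window (both strands,
   gap-free) allowing up to `max_mismatch_standard` mismatches (default 1);
6. no other panel SNP inside the upstream-flank interval has
   PIC ≥ `conservation_pic_standard` (default 0.2) — low-PIC secondary SNPs
   are tolerated.

Candidates that additionally stay unique at `max_mismatch_core` (default 2)
and conserved below `conservation_pic_core` (default 0.1) form the nested
**core** tier, so core ⊆ standard on every input.

Uniqueness is checked on the upstream flank only (the sequence the
allele-specific primer body is built from); downstream-flank uniqueness is
an optional switch, off by default. The flank's own origin counts as one
hit, so "unique" means exactly one genome-wide match. The conservation
screen uses the panel's own discovered SNP list as the variant universe —
no external variant database is assumed.

A separate locus pre-filter drops loci with more than `max_missing_samples`
missing calls (default 20) before screening. With the defaults this makes
the genotyped-count check redundant (≤ 20 missing of 368 implies ≥ 348
genotyped); both knobs are kept because they are independent dials on panels
of other sizes, and the test fixtures exercise the genotyped-count check by
running the screen directly.
The two-decimal missing-rate conversions for a 368-sample panel are
20/368 = 5.43% and 100/368 = 27.17%.

### Mismatch-tolerant uniqueness search

Flank uniqueness uses a pigeonhole seed search rather than an external
aligner: the query is split into `max_mismatch + 1` contiguous near-equal
seeds; any window within the mismatch budget must contain at least one seed
exactly, so exact seed hits (string scan) generate candidate windows which
are verified by Hamming distance with early exit. Both strands are searched
by also scanning the reverse-complemented query; a query and its reverse
complement therefore give identical counts by construction. Gapped
alignment is deliberately not supported — a primer that only matches a
second locus via an indel is not at risk of clean competitive mispriming at
these lengths, and the gap-free definition admits an exact brute-force
oracle (the test suite compares against a position-by-position Hamming scan
over every window and requires zero discrepancies at budgets 0/1/2).

## Primer design

The allele-specific forward primers are constructed, not searched: body =
upstream flank + allele base, so the 3′ terminus sits on the SNP; the FAM
and HEX universal tails (standard published pair, overridable) are prepended
verbatim. Dye assignment is normalised alphabetically — FAM gets the
alphabetically first allele — so swapping allele labels changes nothing.

The common reverse primer is picked by exhaustive scan of all (start,
length) windows within `reverse_search_window` (150 bp) strictly downstream
of the SNP, under explicit constraints: length 18–25 bp, Tm 57–63 °C,
GC 30–65%, 3′ homopolymer run ≤ 3, no panel SNP with PIC ≥ 0.2 in the
window footprint. Among admissible windows the one with Tm closest to the
range midpoint wins; ties break to the shorter amplicon, then the lower
start. Design is a pure function of (genome, candidate, constraints); reruns
are byte-identical. Thermodynamic dimer/hairpin screening is not performed
(future work).

Melting temperatures use the nearest-neighbor model with the unified
published parameter table (Biopython's `Tm_NN` default) at fixed
conditions: Na⁺ 50 mM, single-strand concentration 250 nM, entropic salt
correction. Any single pinned Tm convention serves the constraint check; the
tests verify the wrapper against an independent re-implementation of the
same thermodynamic sum to within 0.5 °C.

## Annotation and reporting

"Genic" means the marker position falls within a gene's full GFF3 span;
exon/intron subclassification is out of scope. When several genes overlap a
position the assignment is deterministic: smallest start, then
lexicographically smallest id. Densities are counted in fixed windows
(default 1 Mb; windows are `[k·w+1, (k+1)·w]` in 1-based coordinates, last
window truncated) with denominators always taken from the supplied FASTA.
All report ratios derive from integer counts; presentation values use
decimal half-up rounding (percentages to two decimals), and the PIC
histogram is fixed at right-closed bins of width 0.05, so reports regenerate
bit-identically.

## Synthetic fixtures

The generator produces FASTA + GFF3 + VCF + a truth JSON with no downloads.
Defaults encode the study conditions the screen is calibrated for:

- 368 samples, fully homozygous calls (inbred lines); a `het_fraction` knob
  injects heterozygous patterns for het-policy testing;
- SNP density 1.4/kb (280 loci on the default 2 × 100 kb genome);
- allele-count spectrum 92.42 / 6.47 / 1.12 % for 2/3/4 patterns;
- bi-allelic minor-pattern frequency law q = 0.5·u^4.79 with u uniform; the
  exponent is the analytic solution of P(PIC ≤ 0.1) = 62.61 % and
  P(PIC ≥ 0.4) = 11.51 % and implies a mean PIC of ≈ 0.13, reproducing the
  low-skewed polymorphism spectrum of inbred transcriptome panels;
- transition:transversion target 0.91 with the directional spectrum fixed
  at the observed maize kernel RNA-Seq proportions (T>C the most frequent
  transition, T>G the most frequent transversion). Directional labels are
  drawn first and positions are then sampled from reference positions whose
  base matches the label, so the expectation equals the target exactly;
- i.i.d. per-call missing rate 2 %, comfortably inside what the pre-filter
  tolerates at 368 samples;
- a genic fraction of 0.86 of background loci placed inside gene spans.

Pattern counts are assigned by largest-remainder composition of the target
frequencies and permuted across samples with the seeded generator, rather
than sampled multinomially. This is the module's central design decision:
the recorded true frequencies and true PIC are exactly those of the
generated calls *before* the missing mask, so estimator error measured
against the truth isolates the effect of missingness instead of conflating
it with sampling noise the generator itself injected.

Planted markers are constructed per prescription: repeat copies (identical
for uniqueness failures; differing at exactly two bases inside the flank
for core-only uniqueness failures), flank SNPs with PIC placed inside
[0.2, 0.4) or [0.1, 0.2) for the two conservation tiers, chromosome-edge and
N-containing flanks, exact low-PIC and low-genotyped compositions. After
assembling the genome the generator re-verifies every uniqueness
prescription with the package's own search and re-draws the local sequence
on the rare accidental near-duplicate, so the planted truth table holds for
arbitrary seeds, and the full screen recovers it exactly.

What the generator does **not** emulate: linkage disequilibrium and
population structure (frequencies are prescribed, not evolved), genotyping
error, locus-level missingness correlated with polymorphism, realistic
repeat landscapes (85 % of a real maize genome is repetitive; the synthetic
background is i.i.d. with a handful of planted families), and read-level
artefacts (no FASTQ). Passing tests therefore demonstrate correctness of
the screening logic and arithmetic under known truth, not marker success
rates on real germplasm.

## Problem sizes used by the test suite

The suite runs at desk scale by choice: parameter-recovery panels use 368
samples × 3,000 loci on a 4 × 540 kb genome (the 1.4/kb default density);
the uniqueness oracle comparison uses 500 random 20-mers against a 100 kb
genome at mismatch budgets 0/1/2; the planted-truth screen uses 53
prescribed markers (plus 10 neighbor loci) and no background. The whole
suite completes in well under a minute on one CPU.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive everywhere in the public model (VCF
  convention); BED outputs convert to 0-based half-open at the boundary.
- Chromosome name matching across VCF/FASTA/GFF3 is exact; readers accept a
  rename map, and a mismatch raises immediately with the available names,
  because silent `chr1`/`Chr1` mismatches are the dominant field failure.
- All-missing loci carry an undefined (None) PIC and are excluded by the
  screen's pattern-count criterion; PIC of an empty frequency map raises.
- Ts/Tv returns +inf when transversions are absent, and raises only when no
  bi-allelic locus exists at all.
- Indels, multi-base and symbolic alleles are rejected at read time (KASP
  targets single-base substitutions); skips are tallied in a read report.
- When a bi-allelic locus's two observed patterns do not include the
  reference base, the directional label uses the first declared alt that is
  observed — an arbitrary but deterministic convention for a vanishingly
  rare case.
- Candidate ordering is (chromosome in FASTA order, position); all writers
  use fixed column orders and fixed float formatting so identical inputs
  give byte-identical files.

## Known limitations

- Uniqueness is Hamming-only (no gaps) and capped at 2 mismatches.
- No primer thermodynamics beyond Tm/GC (no dimers, hairpins, or multiplex
  compatibility).
- The conservation screen covers the extracted flank and the chosen reverse
  window, not every conceivable primer placement.
- PIC treats patterns as unordered categories; no Hardy–Weinberg, LD or
  population-structure statistics are computed.
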
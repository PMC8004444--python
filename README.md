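# kaspforge

Screen multi-sample SNP genotype panels into **KASP-assay-ready markers**:
per-locus polymorphism scoring, flank-uniqueness and primer-conservation
screening, allele-specific primer design, gene assignment and density
reporting — plus a ground-truth synthetic fixture generator so the whole
pipeline is testable without downloading anything.

## Who this is for

Geneticists and molecular breeders who have a called SNP panel (hundreds of
lines, typically inbred), a reference genome and a gene annotation, and who
need a few thousand *reliable* assays for genotyping many samples at few
loci — fine mapping, marker-assisted selection, seed quality control. KASP
(kompetitive allele-specific PCR) is the target chemistry: two tailed
allele-specific forward primers whose 3′ base sits on the SNP (read out as
FAM/HEX fluorescence) plus one common reverse primer.

## The statistic and the screen

Marker usefulness is scored with the polymorphism information content

```
PIC_i = 1 − Σ_j p_ij²
```

where `p_ij` is the frequency of the j-th allelic pattern at marker *i*
among genotyped samples (max 0.50 for bi-allelic sites, 0.75 for four
alleles). A locus becomes a **standard**-tier marker when it is bi-allelic,
PIC ≥ 0.4, genotyped in ≥ 100 samples, its 20-bp upstream flank maps to
exactly one genomic window allowing ≤ 1 mismatch (both strands, gap-free,
pigeonhole seed search), and no other panel SNP with PIC ≥ 0.2 sits in the
primer region. Markers that stay unique at ≤ 2 mismatches with flank SNPs
below PIC 0.1 form the nested **core** tier. Every threshold is a config
knob; see `docs/methods.md` for the full model and design rationale.

## Worked example

Generate a seeded synthetic fixture (2 × 100 kb genome, 40 genes, 200
background SNPs across 368 inbred samples), screen it, and design primers:

```
$ kaspforge fixtures --seed 7 --n-loci 200 --out fx
wrote genome.fa, genes.gff3, panel.vcf, truth.json to fx

$ kaspforge screen --vcf fx/panel.vcf --fasta fx/genome.fa \
      --gff fx/genes.gff3 --window 10000 --out outdir
21 standard-tier candidates (21 core) from 200 loci -> outdir

$ kaspforge design --candidates outdir/candidates.tsv --fasta fx/genome.fa \
      --vcf fx/panel.vcf --out primers.csv
designed 21/21 primer sets -> primers.csv
```

`outdir/candidates.tsv` holds one row per marker:

```
chrom  pos    ref  alt  pic       n_genotyped  tier  gene_id   upstream_flank        downstream_flank
chr1   16289  C    A    0.499614  360          core  gene0004  CCTCAACTATCCATACGCCT  TCGCGTCGCTTATGAAGAAT
```

PIC 0.499614 is just under the bi-allelic maximum of 0.5 (the two alleles
are nearly equally frequent in the 360 genotyped samples), and the marker
falls inside `gene0004`, so it is a genic marker. The rejection tally in
`outdir/rejections.json` explains the other 179 loci by the first failed
criterion:

```
{"n_candidates": 21, "n_core": 21,
 "rejection_tally": {"pattern_count": 16, "pic": 162, "conservation": 1}}
```

— most synthetic loci fail on polymorphism, as expected from the low-skewed
PIC spectrum the generator emulates. `primers.csv` is the order sheet:

```
marker_id   fam_primer                                   common_reverse         reverse_tm  amplicon_len
chr1:16289  GAAGGTGACCAAGTTCATGCT…CCTCAACTATCCATACGCCTA  CAATCGCCATTGGCGAACAGA  60.01       65
```

The FAM and HEX primers differ only at their 3′ base (the two alleles); the
common reverse primer was chosen from the downstream window with Tm closest
to 60 °C. The same operations are available as library functions
(`kaspforge.screen`, `kaspforge.design_kasp`, …) on in-memory objects.

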
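# dmbtkit

Analysis toolkit for dissecting a balancing-selection footprint at a
tandem-repeat locus, built around the human *DMBT1* gene. *DMBT1* encodes
the salivary pattern-recognition glycoprotein DMBT1 (gp340 / salivary
agglutinin), whose bacteria-binding SRCR domains sit in a tandem array of
7–21 repeats per allele. The 5′ end of the gene carries a classic
balancing-selection signature: two deeply diverged SNP haplotype clades at
intermediate frequency, one linked to short SRCR repeat alleles and one to
long ones, with repeat copy number propagating through transcript length to
salivary protein isoform size.

The package is aimed at population geneticists and statistical geneticists
who want to run — or stress-test on fully synthetic data — the chain of
analyses that connects those observations:

1. **`selscan`** — Tajima's D from phased haplotypes, a 10 kb
   non-overlapping genome scan, z-normalization of a focal window against
   the genome-wide distribution, haplotype clade partitioning and tag-SNP
   selection. For `n` haplotypes with `S` segregating sites,

   D = (π̂ − S/a₁) / √(e₁S + e₂S(S−1)),  a₁ = Σᵢ₌₁ⁿ⁻¹ 1/i,

   with π̂ the mean pairwise diversity and e₁, e₂ the usual variance
   constants; the focal z-score is (D − μ_genome)/σ_genome over windows
   with at least three variable sites.
2. **`cnvphase`** — paralogue-ratio-test calibration to integer diploid
   repeat totals, and two routes from diploid totals to per-haplotype
   repeat alleles: pedigree constraint propagation with exhaustive
   refinement (CEPH-style three-generation families) and an EM algorithm
   over population allele frequencies using parent-offspring trios.
3. **`assoc`** — Wilcoxon rank-sum comparison (tie-corrected, continuity
   correction) of repeat alleles between the two tag-SNP clades; OLS of
   protein isoform size on diploid copy number with an optional secretor
   (FUT2) covariate plus Kendall's τ; ANOVA and linear-trend tests of
   expression against genotype dosage.
4. **`txrepeats`** — complete/partial repeat-unit counting in long-read
   transcript exon chains against a genomic repeat annotation, with
   full-length classification and comparison to the genomic allele.
5. **`synthdata`** — a seeded generator for every input the pipeline
   consumes: neutral coalescent windows, a structurally generated
   two-clade region, clade-linked multiallelic CNV spectra dropped through
   trios and pedigrees, isoform panels, and truncatable transcript reads.

`docs/methods.md` documents the models, defaults and design choices.

## Worked example

Generate a synthetic cohort and scan the mock region (coordinates mirror
GRCh38 chr10):

```bash
$ dmbtkit simulate --outdir demo --seed 7
wrote synthetic inputs to demo

$ dmbtkit scan --vcf demo/region.vcf | head -3
chrom   start      end        n_hap  S   pi      theta_w  D       z       ...
chr10   122550000  122560000  100    7   3.070   1.352    2.978   1.091
chr10   122560000  122570000  100    24  7.580   4.636    1.884   -0.219

$ dmbtkit clades --vcf demo/region.vcf --out clades.tsv
# between divergence 21.96, within 1.15, 20 concordant sites
# tag SNP at chr10:122556033 (concordance 1.000)
```

The two windows overlapping the planted two-clade region show strongly
positive D (here the z column is normalized against this tiny
two-window "genome" only; a real scan supplies genome-wide windows). The
clade step recovers the planted bipartition exactly — 20 concordant sites
are the 20 planted fixed inter-clade differences — and picks a perfectly
concordant tag SNP.

Phase the simulated families' diploid repeat totals onto haplotypes and
count repeat units in the simulated long reads:

```bash
$ dmbtkit phase-cnv --ped demo/pedigree.ped --cn demo/cn_observations.tsv \
    --tag-phase demo/tag_phase.tsv --transmissions demo/transmissions.tsv
$ dmbtkit tx-count --units demo/repeat_units.bed \
    --transcripts demo/transcripts.gff3 --genomic-allele 11
# full-length 699/1000, histogram {11: 699}, mode 11, genomic allele 11 concordant=True
```

With a 30% truncation rate, 699/1000 reads keep both mappable ends, every
full-length read counts exactly the 11 repeat units of the simulated
allele, and the transcript mode matches the genomic allele.

Regress isoform size on copy number for the built-in eight-donor saliva
panel (band sizes 287–389 kDa, upper-band encoding):

```bash
$ dmbtkit isoform-model --encoding upper
{"n": 8, "r_squared": 0.7497, "overall_p": 0.00544,
 "slopes": {"srcr_diploid_cn": 5.92}, "kendall_tau": 0.840, ...}
```

Diploid SRCR copy number explains 75% of the variance in salivary protein
isoform size at ~5.9 kDa per repeat unit — the molecular link between the
repeat polymorphism under selection and the protein phenotype.

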
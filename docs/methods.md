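# Methods

`dmbtkit` implements the population-genetic and statistical machinery used to
show that a balancing-selection footprint at the 5′ end of *DMBT1* is carried
by two divergent SNP haplotype clades linked to short versus long SRCR
tandem-repeat copy-number alleles, that diploid SRCR copy number drives
salivary protein isoform size, and that transcript repeat counts track the
genomic allele. Everything below is the package's own account of the models
it implements and the choices made where the design was open.

## Summary statistics and the scan (`selscan`)

For a window of phased biallelic haplotypes (H haplotypes, S segregating
sites) the package computes the mean pairwise diversity

π̂ = Σ_sites 2 j (n − j) / (n (n − 1)),  j = derived-allele count,

Watterson's estimator θ_W = S/a₁ with a₁ = Σ_{i<n} 1/i, and Tajima's
D = (π̂ − θ_W) / √(e₁S + e₂S(S−1)) with the standard constants
(a₂, b₁, b₂, c₁, c₂, e₁, e₂). D is undefined (NaN, flagged) when S = 0.
The implementation is cross-checked in the test suite against an
exact-arithmetic oracle (fraction-based constants, brute-force π̂) and
against `tskit`'s `Tajimas_D` on `msprime` genealogies during development.

The genome scan tiles contigs with non-overlapping 10 kb windows, 0-based
half-open internally; a 1-based VCF position p falls in window
⌊(p−1)/10000⌋. A focal window is z-normalized against the genome-wide
distribution of window D values. Choices the underlying quantification
leaves open, declared here:

* the null moments use windows with defined D **and** at least
  `min_variable_sites` (default 3) segregating sites — the same exclusion
  rule applied to sparse focal windows — so that noisy small-S windows do
  not contaminate the null;
* the standard deviation is the sample form (n − 1 denominator);
* the focal-region and focal-window coordinates default to the GRCh38
  *DMBT1* values (`FOCAL_REGION`, `FOCAL_WINDOW`) and are configurable.
  Reproducing the published CEU region value (D = 2.67) needs external
  cohort genotypes and is deliberately not part of the hermetic suite.

Clade partitioning is complete-linkage agglomerative clustering on pairwise
Hamming distance, cut at two groups, labels normalized so the lowest-index
haplotype sits in clade 0. The published analysis identified the two clades
by inspection; clustering is this package's formalization, and on two-clade
data with within-clade diversity well below the inter-clade divergence it
coincides with the ratio-maximizing bipartition (checked by enumeration for
small H). The tag SNP is the site maximizing clade concordance (fraction of
haplotypes matching their clade's majority allele), ties to the leftmost
position; concordance ≤ 0.5 is flagged unreliable.

## Synthetic data (`synthdata`)

The generator's defaults are the study conditions of the analysis; they are
not tuned per test.

**Neutral windows.** A bespoke Kingman coalescent with infinite-sites
mutations: with j lineages the waiting time is Exponential(j(j−1)/2) in
units of 2N generations, each branch receives Poisson(θ/2 × length)
mutations, and sites get distinct uniform positions in the window. This
keeps the genome-wide null hermetic (no external simulator needed) while
satisfying E[S] = θa₁ and E[D] ≈ 0.

**Balanced region.** The haplotype-structure pattern, not a selection
trajectory, is what the scan detects, so the region is generated
structurally: round(f·n) haplotypes form the "short" clade; d fixed
inter-clade differences are planted (default d = 20 over the 16.5 kb mock
region — the inter-clade divergence is not quantified by the source data,
so the default is the value at which the region robustly clears the
neutral 99th percentile while staying compatible with a ~16 kb footprint);
each clade then receives its own coalescent variation. `theta_within` is
the regional scaled mutation rate; a clade maintained at frequency f is an
allelic class of effective size f·N, so its coalescent runs at f·θ_within.

**CNV through families.** Founder haplotypes draw (clade, tag allele,
repeat allele) with the short clade on the C allele; defaults put the short
clade's mode at 8 repeats and the long clade's at 13 (with secondary mass
at 9/11 and 11/14), inside the 7–21 repeat range. Families are
parent-offspring trios and CEPH-like three-generation pedigrees (4
grandparents, 2 parents, 8 children — CEPH sibships are of this order).
Children inherit one uniformly chosen haplotype per parent; the chosen slot
is recorded in a transmissions table, the observable counterpart of
region-scale SNP phase (in real pedigrees, phased haplotypes identify which
parental haplotype a child received; a single tag SNP does not). Diploid
totals are reported with probability `cn_measurement_error` of a ±1 error
(PRT miscalls are near-integer).

**Isoforms and transcripts.** Protein size is
intercept + slope·CN + secretor_effect·1[Se+] + N(0, σ) on the kDa scale,
with defaults (228 + 6·CN + 10·Se, σ = 5) chosen so that simulated sizes
span the observed 287–389 kDa band range over diploid copy numbers 14–29.
Secretor status is recessive in a null allele at frequency 0.45 (the
common European range). Transcript reads tile a 5′ flank, the first k
annotated repeat units, and a 3′ flank; truncation removes a uniform random
prefix or suffix in transcript coordinates and clears the corresponding
mappable-end flag.

What the generator does **not** emulate: recombination, demography, linkage
decay around the region, sequencing error, allele-frequency drift between
cohorts, and genotyping failure. Passing tests therefore demonstrate
correctness of the machinery on idealized inputs with the right first-order
statistical structure, not performance on real cohort data.

## Copy-number calling and phasing (`cnvphase`)

**Integer calling.** Per assay, a least-squares line CN = a + b·ratio is
fitted to reference samples of known copy number (b ≤ 0 is a calibration
error); assay estimates are averaged before rounding (the assays are
treated as replicate estimates of the same SRCR total); half-integers round
away from zero; calls further than 0.35 from an integer are quality-flagged.

**Pedigree phasing.** Each individual's candidate set holds every ordered
(paternal, maternal) allele pair summing to its observed total within the
declared range. Transmission constraints — a child's haplotype allele must
sit on a compatible haplotype of the corresponding parent — are propagated
to a fixpoint (arc consistency), where "compatible" is sharpened by the
transmissions table when present and by the tag-SNP phase of
tag-heterozygous parents otherwise. Families of at most 14 members are then
refined by depth-first exhaustive enumeration of joint assignments, so the
reported candidate sets are exactly those that survive in some globally
consistent assignment. Empty sets mark the family inconsistent with the
first offending individual named; no exception is raised. Founders whose
two haplotypes carry the same tag allele have observationally exchangeable
slots; when their allele multiset is uniquely resolved the pair is reported
in sorted order and counts as resolved.

Residual ambiguity is real, not algorithmic: in a family where every
member is tag-homozygous, all allele assignments can shift coherently by
±t while preserving every diploid total, and no observable breaks the tie
(population allele frequencies would, but the pedigree method deliberately
uses none). With the default conditions this affects under 1% of simulated
three-generation families; phasing accuracy, measured as individuals whose
(tag allele, repeat allele) multiset is uniquely and correctly recovered,
is ≈ 99.3% in the long run.

**Trio EM.** Founder alleles are i.i.d. from an unknown frequency vector p
under random mating; parents transmit either allele with probability 1/2; a
trio configuration (father pair, mother pair, transmitted pair) must
reproduce all three observed totals. The E-step computes per-trio
posteriors over configurations, the M-step re-estimates p from expected
founder-allele counts (four per trio); the log-likelihood is asserted
non-decreasing at every iteration, and convergence is declared at a gain
below 1e-8. The uniform vector is a saddle at which every configuration has
identical weight (the transmission factor exactly cancels the genotype
multiplicity), so the ascent runs from 8 seeded Dirichlet(1) starts and
keeps the best final log-likelihood; this is deterministic given the seed
and reliably reaches the optimum found by dense grid search on small
fixtures. Inconsistent trios are flagged and excluded from the likelihood.
Per-trio MAP configurations are reported with posteriors; ties break to the
lexicographically smallest configuration and are flagged.

## Association models (`assoc`)

**Clade association.** Wilcoxon rank-sum with mid-ranks, tie-corrected
variance and 0.5 continuity correction, two-sided (sidedness is a declared
choice). An exact enumeration mode exists for total n ≤ 20. Population
spectra are compared on founder haplotypes only, avoiding double counting
through transmission. The normal approximation agrees with
`scipy.stats.mannwhitneyu` (asymptotic, continuity-corrected) to within
numerical precision on tied and untied data.

**Isoform regression.** OLS of protein size on diploid SRCR copy number,
optionally with a secretor indicator; r², overall F-test p, per-coefficient
t-test p, and Kendall's τ (with p) of size against copy number are
reported. The response encoding for band sizes is configurable: band mean
(default declared convention), upper band, lower band, class size-rank, or
a measured continuous size column. On the built-in eight-donor panel the
upper-band encoding reproduces the published copy-number-only fit
(r² = 0.75, p = 0.005) and the band-mean encoding the published Kendall
p = 0.004; the published with-secretor pair (r² = 0.85, secretor p = 0.07)
is not reproduced by any encoding of the recoverable records (the secretor
covariate does improve the fit, r² = 0.82, nesting guaranteed).

**Secretor inference.** Homozygous null at the FUT2 variant → Se−,
otherwise Se+, missing → unknown; the variant is configurable (default
null allele: the common European nonsense allele's A).

**Expression trend.** One-way ANOVA across genotype-dosage classes plus a
two-tailed F-test of the linear dosage slope in an OLS of normalized
expression on dosage; both p values and the slope sign are reported.

## Transcript repeat counting (`txrepeats`)

A repeat unit is complete in a read when exons cover ≥ `coverage_frac`
(default 0.95) of its length, partial when covered below threshold but
above zero. The 0.95 default operationalizes "visually complete" in an
annotation-graphic sense while tolerating a few clipped bases at unit
edges. Full-length status comes from caller-provided 5′/3′ mappable flags
(adapter/primer detection belongs to the upstream read-processing tools).
Counting is strand-agnostic; interval splitting cannot change counts; the
complete count is non-increasing in `coverage_frac`. Summaries histogram
complete-unit counts over full-length reads; the mode (ties to the larger
count) is compared against a supplied genomic allele.

## Numerical and reproducibility notes

* All simulation randomness flows from `numpy.random.Generator`s; every
  entry point takes a seed or generator, and ensembles (e.g. the 1000
  neutral windows of the calibration) draw from a single stream in
  documented order, so identical seeds give bit-identical outputs.
* Problem sizes in the test suite and acceptance script — 1000 neutral
  windows (n = 20, θ = 5), 200 balanced-region replicates (n = 100, f = 0.5,
  d = 20, θ_within = 2), 500 trios for the EM recovery, 100 three-generation
  pedigrees, 200 cohort simulations of 65 trios (260 founder haplotypes) —
  are the package's calibration conditions and complete in well under a
  minute together.
* Degenerate inputs have defined behaviour throughout: S = 0 windows carry
  NaN D and are excluded from z-scores rather than scored; a zero-spread
  genome null raises; clade partitioning of identical haplotypes raises;
  totals incompatible with the allele range yield empty candidate sets that
  mark the family, not an exception.

## Known limitations

* The pedigree phasing uses no allele-frequency information, by design;
  the all-tag-homozygous shift ambiguity above is the price.
* The trio EM assumes random mating and exact integer totals; measurement
  error is handled upstream (quality flags, ±1 relaxation is not applied
  inside the EM).
* The coalescent has no recombination, so simulated regions are single
  genealogies; windowed D values across a real chromosome are correlated
  in ways the synthetic null ignores.
* The isoform model treats band size as a linear readout of copy number;
  glycosylation differences beyond the single secretor indicator are not
  modelled.
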
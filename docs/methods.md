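# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and
the numerical choices that were genuinely open.

## The diversity estimator

All diversity statistics start from an *all-sites* matrix: every
genomic position, invariant or not, with a haploid allele call and a
read depth per sample.  Window diversity is the ratio-of-sums
estimator

π(window) = Σs Ds / Σs Cs,

where at site s, Cs = ns(ns−1)/2 counts unordered pairs of genotyped
samples and Ds counts the discordant ones.  Missing calls (including
calls masked by the depth filter: depth < 0.5× or > 2× the sample's
mean coverage) drop out of numerator and denominator together, which
keeps the estimator unbiased under arbitrary missingness; the test
suite demonstrates this against a missingness-blind estimator, which
is biased low by roughly the square of the genotyping rate.
Multiallelic sites contribute pairwise discordance over all alleles.
Windows tile each chromosome from position 0 (default 1,000 bp, the
trailing partial window keeps its true span); a window with Cs = 0
everywhere is undefined and excluded from percentile ranking.  Outlier
thresholds are linear-interpolation empirical percentiles (95th/99th)
of the defined windows, with a strictly-greater rule so that an
all-equal table yields no flags.  Windows overlapping the mask BED of
horizontally transferred segments are annotated separately: in this
system host reads mis-map onto HGT segments and inflate apparent
diversity, so those windows are artifacts, not balancing selection.

## Coding diversity and selection efficacy

Per-gene π_N and π_S use unweighted Nei–Gojobori (1986) counting:
each codon's nonsynonymous/synonymous site content is the synonymous
fraction of its nine single-base neighbours (changes to stops count
as nonsynonymous), and pairwise differences are averaged over all
minimal mutational pathways that avoid stop codons (if every pathway
hits a stop, all changes count as nonsynonymous).  Site counts are
averaged over sequences; codons containing ambiguity and columns
masked by the divergence rule are excluded from every count.  Genes
with π_S = 0 have an undefined ratio and are excluded from gene-set
medians (their count is reported); no pseudocounts are used.  The
gene-set contrast (conserved/BUSCO-like vs background) is a
Kruskal–Wallis test with tie correction and the χ² approximation.

The ingroup–outgroup alignment mask follows a 0.5% divergence rule.
Two modes are provided because the rule is ambiguous at face value:
the default masks 100-bp sliding windows (step 50) whose gap-excluded
difference fraction strictly exceeds 0.005 — note that *any* single
difference in a 100-bp window exceeds 0.5%, so under this mode all
retained columns are identical between the references and
MKT divergence counts are zero by construction.  That reproduces a
real pathology of low-diversity/high-divergence datasets (α cannot be
estimated reliably; the suite shows bootstrap spreads of α above 0.5
with ≤10 polymorphic sites).  The alternative mode
(`divergence_mask_mode: gene`) excludes whole genes whose overall
divergence exceeds the threshold, leaving sub-threshold divergence in
place so the MKT and asymptotic MKT (exponential fit
α(x) = a + b·e^(−cx), starting values a = last bin, b = −0.5, c = 1,
c ∈ [0, 50], linear-extrapolation fallback flagged) are exercised end
to end.

## Ploidy evidence

Two independent evidence sources are combined conservatively.  The
allele-balance histogram bins the minor-allele read fraction at
biallelic sites with depth ≥ 10 (bin width 0.02).  The k-mer spectrum
uses canonical k-mers (k = 21 by default) with moving-average
smoothing (window 3), an error floor at multiplicities < 3, a peak
height floor of 5% of the tallest peak, a small prominence floor (2%)
to suppress shoulder noise, and a plateau bound so a flat spectrum has
no modes.  A sample is haploid iff the heterozygous band
(minor fraction 0.35–0.65) holds < 5% of the mass *and* no spectrum
mode sits near half the main mode; diploid iff the band holds ≥ 20%
or a half-coverage mode exists; everything else — including fewer
than 100 informative sites (the low-polymorphism regime, where
haploidy cannot be separated from, e.g., mixed infection) and outright
conflict between the two evidence sources — is ambiguous.  All
thresholds are explicit parameters; they formalise criteria that are
inherently visual.

## Structure, relatedness, and isolation by distance

PCA operates on the biallelic genotype matrix (multiallelic SNPs are
kept for π but excluded here), with per-SNP mean imputation of
missing calls and optional √(p(1−p)) scaling.  Clustering is k-means
(best of 10 restarts, seeded) on the PCs jointly explaining ≥ 80%
variance.  Relatedness is the allele-sharing coefficient
β = (M − M̄)/(1 − M̄) on the matching fraction M over co-genotyped
SNPs, so the mean off-diagonal β is zero by construction; the exact
estimator behind a published relatedness matrix is rarely stated, so
β was chosen as a simple, documented matching-based coefficient.

Geodesic distances are WGS84 Vincenty inverse solutions (validated
against an independent geodesy oracle to 10 m); pairs spanning
Eurasia–North America are routed through a Bering Strait waypoint
(65.8°N, 169.6°W — a documented choice, as dispersal between the
continents plausibly followed that route) as the sum of the two legs.

The IBD test regresses the leading principal components of the
relatedness matrix (cumulative variance ≥ 0.9) on dbMEM spatial
eigenvectors: the distance matrix is truncated at the longest
minimum-spanning-tree edge t (longer distances replaced by 4t),
Gower-double-centered as −½d², and eigen-decomposed.  Of the
positive-eigenvalue axes, only those with positive spatial
autocorrelation (Moran's I above its null expectation −1/(n−1),
computed against the within-t connectivity) are retained, following
the convention of the standard dbMEM implementations.  This retention
rule is load-bearing at n = 10: keeping all positive-eigenvalue axes
(five here) makes the permutation null so permissive that the test
has almost no power, while the two broad-scale axes carry the entire
geographic signal; calibration is unaffected (measured type-I error
≈ 0.05).  Significance is the one-sided permutation probability of R²
under random row permutation of the response (P ≥ 1/(1+n_perm); 1,000
permutations by default, seeded and reproducible).

## Clock calibration and the per-generation rate

Third codon positions are 4-fold degenerate columns only when every
sequence agrees on a 4-fold family with no gaps — an approximately
neutral marker set (all third-position changes in these families are
synonymous, so the generator's selection thinning never touches
them).  Pairwise distances on the concatenated 4-fold sites use the
JC69 correction (divergence here is far from saturation; the
correction is configurable).  A full Bayesian tree is deliberately
out of scope: the module either accepts an externally calibrated
clock rate or computes the distance-based strict-clock surrogate
r = d̄/(2T) from the mean between-clade distance and the split time;
both paths share the conversion code.  Genes overlapping the HGT mask
BED are excluded before distance computation — contaminated windows
otherwise inflate d̄ by tens of percent.

Conversion to a per-generation rate uses a 365-day year and months of
year/12: generations per year = 365 × 24 × (12 − m)/12 / g for
generation time g hours and m dormant months; μ = r / generations.
With g = 63 h this gives 139.05 generations in a fully active year,
92.70 with four dormant months, and 69.52 with six.  The 365-day
convention reproduces the canonical conversions to three significant
figures; 365.25 does not.  The calibration prior on the deepest split
is a shifted log-normal (M = 1, S = 0.775, offset 0.45 Myr): median
offset + e^M = 3.17 Myr and 5th/95th percentiles 1.21 and 10.2 Myr.
Those tail quantiles use z = ±1.645; the interval is sometimes
loosely called a 95% CI, which would instead imply z = ±1.96 — the
quantile function is general and the package reports the 5th/95th
convention that matches the printed bounds.

## The synthetic generator

The generator emulates the *statistical* structure of the study
design, not its sequences:

* **Genealogy**: a Kingman coalescent within each lineage
  (effective size θ/2r in years, conditioned to coalesce before the
  lineage joins its sister) with lineage roots joined at exactly
  T2 = 0.5 Myr (East Asia + North America) and T1 = 1.61 Myr
  (Western Eurasia vs the rest).  The forced join makes the
  between-clade expectation exactly 2rT, which is what the clock
  recovery test needs; it is not an ancestral-population coalescent.
* **Mutations**: Poisson at r = 1.04×10⁻⁹ /site/year on branches,
  infinite-sites (recurrent hits rejected), single-nucleotide only.
  Selection is reduced to an acceptance probability for
  nonsynonymous candidates, classified against the *reference* codon
  (not the evolving background): f = 0.1 in the conserved gene set,
  f = 0.5 in the background.  Synonymous and intergenic changes are
  always accepted.
* **Scale**: 12 × 20 kb chromosomes and 120 single-exon genes of 333
  codons (≈50% coding, matching the gene density of a compact
  microsporidian genome) keep a full dataset under a second of
  compute; the full ~2.3 Mb scale is one config value away.
  Within-lineage diversity θ = 10⁻⁴ per site sits far below the
  between-lineage divergence (≈3×10⁻³), reproducing the qualitative
  ordering of the real data; no published within-lineage effective
  size exists, so θ is a realism choice, not an estimate.
* **Geography and depths**: the default 5/2/3 design uses the actual
  sampling coordinates and mean coverages of the ten study isolates;
  other designs scatter samples around lineage centroids (σ = 2°).
* **Read evidence**: depth ~ Poisson(mean coverage); alternate-read
  support ~ Binomial(depth, ε = 0.01) for haploids and
  Binomial(depth, 0.5) at heterozygous sites of diploid controls,
  whose second haplotype comes from across the deepest split.  The
  k-mer spectrum is emulated *parametrically* as a Poisson mixture
  with a fixed heterozygous-k-mer weight (0.4) at half coverage —
  enough to produce the characteristic two-mode diploid spectrum at
  20× coverage.  At this coverage the two Poisson modes only resolve
  for weights between ≈0.3 and ≈0.5, so the weight is an emulation
  knob, not a quantity derived from the simulated heterozygosity;
  real spectra near that boundary would look unimodal.
* **HGT contamination**: inside three 1 kb windows (chromosomes 2, 5
  and 8), each sample is contaminated with probability 0.5 and
  receives random "host" alleles at 5% of sites, inflating window π
  far above the genomic background.
* **Not emulated**: recombination, migration after the splits,
  indels, alignment error, reference bias, and base-composition
  structure.  Passing tests therefore validate the estimators and
  their interplay under the assumed sampling design — they say
  nothing about mapping artefacts or model misspecification in real
  sequencing data.

Everything is deterministic given the master seed (sub-streams are
spawned per stage), and the full default dataset generates in well
under a second.

## Numerical conventions and degenerate inputs

Internal coordinates are 0-based half-open; VCF and GFF3 keep their
1-based conventions at the file boundary.  Indel records are dropped
on read; multiallelic SNPs are retained in the site matrix but
excluded from the genotype matrix.  A genotype masked by the depth
filter becomes missing, never deleted, preserving denominators.  The
GFF3 phase column is ignored; CDS length divisibility by 3 is
enforced instead, and a CDS outside its chromosome is an error, never
trimmed.  Diversity tables report undefined windows as NaN rather
than dropping rows.  JC69 is undefined (flagged) at p ≥ 0.75.
Kruskal–Wallis on identical groups returns H = 0, P = 1 without
calling the χ² machinery on a degenerate statistic.  k-means and all
permutation tests take explicit seeds; reported P-values are exact
permutation probabilities with the +1 correction.

## Problem sizes used by the test suite

The acceptance-level tests run 20 replicate datasets at the default
12 × 20 kb scale for the selection, clock and IBD checks, 500 null
replicates (199 permutations each) for type-I calibration, a
40-sample panel at 20× for ploidy, and 1,000 random small matrices
for the exact π oracle.  Clock-rate recovery is asserted on the mean
over the 20 replicates (single-replicate scatter is ≈±15%, dominated
by Poisson mutation noise on the shared stem branches).  The whole
suite completes in well under two minutes on one CPU.
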
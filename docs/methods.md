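# Methods

## The ROH45 statistic and ROH calling

A run of homozygosity is a maximal stretch of contiguous homozygous,
non-missing SNP calls of one animal on one chromosome. A run qualifies at
calling length L when it contains at least L SNPs; this is equivalent to
the union of every length-L sliding window that contains no heterozygote
and no missing call. The per-SNP indicator ("ROH45" at L=45) marks every
SNP inside a qualifying run — including those beyond the first L — so
animals whose runs start or stop a few SNPs apart still agree at shared
interior SNPs. Its population frequency is the central statistic of the
pipeline.

Choices that the run definition leaves open:

* **Missing calls break a run** by default (they are treated like a
  heterozygote for run termination but excluded from the denominator of
  overall homozygosity). `missing_in_roh="skip"` lets a run continue
  across missing calls without counting them toward L. Breaking is the
  conservative, deterministic default.
* **No heterozygote allowance** inside a run. Allowing heterozygotes is
  known to blur run boundaries, which would directly corrupt a statistic
  defined by run membership.
* **Segment length** is the bp distance between the run's terminal SNPs
  (closed interval), not midpoints to flanking markers.
* **Proportion of genome in ROH** divides summed segment Mb by the
  SNP-covered span (per chromosome, last minus first marker bp). Under
  this denominator a fully homozygous genome scores exactly 1, and the
  quantity is computable from the data alone; fixed assembly lengths can
  be passed instead.

Nesting is structural: status at L=95 implies status at L=70 implies
status at L=45, so the three genome proportions are always ordered.

## Population structure

The genomic relationship matrix follows Yang et al.: off-diagonals are
standardized cross-products (x_j−2p)(x_k−2p)/(2p(1−p)) averaged over SNPs,
the diagonal is 1 plus the average per-SNP inbreeding term
[x²−(1+2p)x+2p²]/(2p(1−p)), whose expectation under Hardy–Weinberg is 0 —
hence a mean diagonal of 1 in an outbred sample. Allele frequencies come
from the combined (merged) sample, since the point of the PCA is to place
all populations in one space. SNPs fixed in the combined sample are
excluded; missing calls drop a SNP from the affected pairs with per-pair
N adjustment. The GRM is not guaranteed positive semi-definite, so PCA
variance fractions λ_i/Σλ keep negative eigenvalues in the total.

F_ST between two populations is the Weir–Cockerham variance-components
estimator θ = a/(a+b+c) for diploid samples (r = 2), including the
observed-heterozygosity term, computed per SNP from genotype counts and
averaged over a sliding window of 8 consecutive SNPs within chromosome
(step 1; a window mean is reported at the window's start/end bp to avoid
convention ambiguity). The estimator is unbiased around zero and may go
negative; SNPs monomorphic in both samples are undefined and excluded
from window means.

## Permutation calibration and region rules

For a two-population contrast the observed per-SNP statistic is the
absolute difference in ROH45 frequency; the chi-square (1 df, no
continuity correction) on the 2×2 population × in-ROH table is reported
alongside. Group labels are shuffled preserving group sizes (default
B = 1,000); the default empirical p pools all B×M null differences with an
add-one correction, p = (1+#{null ≥ obs})/(1+BM), so p is never 0 and is
bounded below by 1/(BM+1). Alternatives `per-snp` (each SNP against its
own B null values) and `max` (genome-wide maximum null) are available.

A region is declared for a maximal run of consecutive SNPs with p < 0.001
containing at least 45 SNPs and spanning more than 4 Mb; runs never cross
chromosomes. Common high-autozygosity regions flag SNPs at or above each
population's 97.5th-percentile ROH45 frequency (ties included), intersect
the flags across populations, and apply the same contiguity rule. The
region peak is the SNP of maximum |statistic|; when a plateau ties at the
maximum (which is certain when one planted carrier set spans the region)
the central tied SNP is reported rather than an arbitrary end.

The pooled null is well-behaved for the bounded frequency-difference
statistic. For the temporal slope (below) it is not: SNPs whose in-ROH
status rests on a handful of animals produce permuted slopes of |β| > 1,
and a few such SNPs dominate the pooled tail. The pooled default is kept
for comparability, but trend region calling in the analysis drivers uses
the per-SNP null with B ≥ 1,999 (smallest attainable p = 1/2000 < 0.001),
which conditions on each SNP's own carrier count.

## Temporal trend model

Per SNP, ROH45 status is fit by maximum-likelihood logistic regression on
birth year, P(status=1) = exp(α+βYB)/(1+exp(α+βYB)); β is the per-year
change in log-odds of locus autozygosity. Years with fewer than 40
genotyped animals are dropped before fitting. The year covariate is
centered at its mean for numerical stability and the intercept is
back-transformed to the original origin, so fits are invariant to year
recentering. Fitting is IRLS vectorized across SNPs (shared covariate,
per-SNP weights), capped at 25 iterations with step-size convergence at
1e-8 and divergence detection at |coefficient| > 50 on the centered
scale. All-constant status, separation or divergence flags the SNP
non-converged with p = 1 rather than raising, so one degenerate SNP
cannot break a genome scan. Wald p-values use the normal reference.

## Association model

Stage one adjusts lactation records per population and trait by OLS on
herd-year-season, parity and calving month (categorical) plus age at
first calving (linear, centered); a cow's yield deviation is the mean of
her adjusted records, standardized to mean 0, variance 1 within
population (the standardization SD is retained in the output so effects
can be placed back on the record scale). Singleton fixed-effect cells are
absorbed (residual 0) and rank deficiencies are handled by least squares.
A consequence worth knowing: residualizing on many small HYS cells
absorbs a fraction ≈ p/n of any genetic signal (p parameters, n records),
the usual attenuation of two-stage yield-deviation pipelines. The
synthetic demo uses few herds precisely so this attenuation is small.

Each deviation is weighted by the Garrick reliability weight
w(l) = (1−h²)/(h² + (1+r²(l−1))/l − h²) with parity count l, heritability
h² = 0.25 and repeatability r² = 0.43; w(1) = 1−h², w is increasing in l
for r² > h², and w → (1−h²)/r² as l → ∞.

Stage two fits, per SNP, y = μ + pop + SNP·g + u + e/w with u ~ N(0, Aσ²ᵤ)
on the pedigree numerator relationship matrix (tabular method) and the
variance ratio fixed at λ = σ²ₑ/σ²ᵤ = (1−h²)/h² = 3 rather than
re-estimated by REML — the scan is then deterministic and each fit is one
linear solve. Solutions come from Henderson's mixed-model equations
(numerically identical to dense GLS on V = A/λ + diag(1/w), verified to
1e-8 in the tests); σ²ₑ is profiled from the weighted residual sum of
squares on n − rank(X) degrees of freedom and the Wald test uses the t
reference, which keeps the null type-I rate at nominal level in
simulation. SNPs monomorphic among phenotyped animals are reported as
missing. Benjamini–Hochberg q-values are computed per trait over the
scanned subset (the region modules supply the SNP subset; the scan never
runs genome-wide by design).

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with exact truth:

* **Markers**: 29 autosomes by default, uniform spacing with ±30% jitter,
  defaults (1,000 SNPs per 76-Mb chromosome) giving 45 SNPs ≈ 3.4 Mb,
  matching the physical scale the 45-SNP rule is meant to capture.
* **Genotypes**: ancestral frequencies ~ Uniform(0.05, 0.95); population
  frequencies from the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with
  F the target F_ST; two haplotypes per animal at linkage equilibrium.
* **Planted ROH**: inside a declared region an animal becomes a carrier
  with a per-population probability, and both its haplotypes are replaced
  by one haplotype drawn once for that region — a true IBD segment. Trend
  regions move the carrier probability with birth year through a logistic
  link, so the temporal model is correctly specified and its slope equals
  the planted value. Background LD is deliberately absent: a spontaneous
  run of 45 homozygotes at intermediate frequencies is essentially
  impossible, so planted regions are the only source of long ROH and the
  truth table is exact.
* **Phenotypes**: 1–4 lactations per cow; record = μ + HYS + parity +
  month + age·b + QTL + u + pe + e with Var(u)+V_qtl = h², Var(u)+Var(pe)+
  V_qtl = repeatability, Var(e) = 1 − repeatability on the record scale
  (QTL variance 2p(1−p)a² is deducted from the polygenic part so total
  narrow-sense h² stays at the configured 0.25). The three traits share
  the animal-level effects and differ in residuals.
* **Pedigree**: four discrete generations with heavily reused sires
  (AI-like); optionally anchored to the genotyped animals as the final
  generation.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate: background linkage disequilibrium and its ROH
length distribution, recombination-map heterogeneity, genotyping error,
family co-segregation of marker genotypes with the pedigree, and
selection. Conclusions about those features require real data.

Two interactions discovered with this design are worth flagging. First,
because one carrier set spans a whole planted region, per-SNP statistics
are perfectly correlated within a region; block-level (not per-SNP)
fluctuation is the right unit when judging type-I behaviour. Second, the
Hardy–Weinberg QC filter is partially confounded with strong
autozygosity: at carrier rates above ~0.2 and n ≥ 250 per population a
sizeable share of planted-region SNPs genuinely fails the HWE test and is
removed, so planted regions in end-to-end runs are made wider than the
45-SNP rule strictly needs. The same tension exists in real pipelines —
HWE filtering can thin exactly the regions an autozygosity scan is
looking for.

## Problem sizes

The test suite and acceptance script run cohorts of 500–1,000 animals and
2,000–5,000 SNPs with 200–2,000 permutations, and 5,000–10,000 mixed-model
fits for null calibration; these sizes give stable Monte-Carlo estimates
for every property checked while keeping a full run in the minutes range
on a single CPU. All randomness flows from one seed through independent
substreams per stage, so reruns are bit-identical.

## I/O conventions

PLINK ped/map and bed/bim/fam are read and written natively; calls are
A2-allele dosages 0/1/2 with −1 as the missing sentinel; coordinates are
1-based bp and intervals closed on both ends. Since .map files carry no
allele labels, the counted allele on ped input is the lexicographically
greater observed allele, and a SNP with a single observed allele reads as
all-zero dosage — round-trips through bed/bim/fam are exact, those through
ped/map are exact for polymorphic markers. Non-autosomal markers
(chromosomes outside 1–29) are dropped on read with a logged count. The
PLINK family id doubles as the population label; birth year and herd are
carried in a sidecar sample table where needed.
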
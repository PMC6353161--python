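# Methods

This note documents the statistical machinery implemented in `divscan`, the
choices made where a convention had to be fixed, and what the synthetic data
do and do not establish.

## Data model and input conventions

Genotypes are diploid allele-B dosages in {0, 1, 2} with an explicit missing
code, tied to a marker map (1-based bp positions, sorted by chromosome then
position; numeric chromosome labels order before alphabetic ones) and a
sample table carrying breed labels.  Text PLINK PED/MAP is the interchange
dialect; the PED family-ID column doubles as the breed label unless an
explicit sample→breed TSV is given.  Because a MAP file carries no allele
roles, the counted allele defaults to the lexicographically larger allele
observed at each SNP; a SNP at which only one allele is ever observed is
then coded as dosage 2 of that allele.  Callers that need exact round-trips
(e.g. the test suite) pass explicit per-SNP allele roles to `read_plink`.
Cross-dataset merging of differently coded files is out of scope.

## Quality control

Filters run in a fixed order with per-SNP reason codes:

1. **Per-sample call rate** — keep samples with call rate strictly > 0.97.
2. **Sex-chromosome removal** — labels {X, Y, 32, 33} by default
   (configurable).
3. **Marker filters** — drop SNPs with whole-population missingness ≥ 0.20,
   then whole-population MAF < 0.05, then exact Hardy–Weinberg p < 1e−6 in
   *any single breed*.  MAF/missingness are population-wide; HWE is
   per-breed, since artefactual genotype clusters show up as HWE failures
   within breeds while real between-breed differentiation does not.

The HWE test is the exact conditional test: conditioning on the observed
allele counts, all heterozygote counts of matching parity are enumerated;
the p-value is the summed probability of tables no more probable than the
one observed (plain, not mid-p; the chi-square approximation is avoided
because breed samples can be small).  Probabilities are computed with
log-gamma terms and renormalized, which is exact to floating precision
(verified against integer enumeration for all tables up to n = 50).

The per-breed panel summary partitions SNPs by breed MAF into monomorphic
(MAF = 0), low-frequency (0 < MAF < 0.01) and polymorphic (MAF ≥ 0.01 —
the boundary value counts as polymorphic), so the three counts always sum
to the panel total.  Observed heterozygosity is the mean per-SNP
heterozygote fraction and expected heterozygosity the mean 2p(1−p), both
averaged over polymorphic-in-breed SNPs by default (a switch widens this to
all SNPs, and another applies the 2n/(2n−1) small-sample correction);
whether to average over all or only polymorphic SNPs is a reporting
convention, not a statistical necessity, so both are exposed and the choice
is recorded in the summary metadata.

## Pairwise F_ST

The two-population Weir–Cockerham (1984) variance components a, b, c are
computed per SNP from per-breed sample sizes, allele frequencies and
observed heterozygote proportions (sample sizes are per-SNP, so missing
genotypes are handled exactly).  θ̂ = a/(a+b+c); SNPs with a+b+c = 0
(monomorphic across the pair) are undefined and excluded from all
summaries, with the exclusion mask retained.  Two multi-locus summaries are
reported: the mean of per-SNP θ̂ with its sample (n−1) standard deviation —
these are the moments the scan standardizes by — and the weighted estimate
Σa/Σ(a+b+c).  Negative per-SNP θ̂ are kept: they are legitimate draws from
the estimator's sampling distribution, and truncating them would shift the
mean and shrink the standard deviation, biasing every downstream z-score.
These conventions (estimator choice, negative-value policy, n−1 sd) are
deliberate and recorded here because the scan statistic is defined relative
to them.

## The d_i scan

Per pair, z = (θ̂ − mean)/sd using the pair's genome-wide moments; per
focal breed, d_i is the sum of z over the other breeds.  A SNP undefined in
*any* contributing pair is excluded from that profile (and counted).
Windows are 10 consecutive profile SNPs, step one SNP, never crossing a
chromosome boundary (a chromosome with fewer than 10 profile SNPs yields no
windows); the window value is the arithmetic mean and its center the
midpoint of the first/last SNP positions.  The threshold is per profile:
the ⌈0.001·N⌉-th largest window value (an order statistic — reproducible,
no interpolation; ties are included).  Selected windows whose SNP spans
overlap or share an endpoint on a chromosome merge into regions whose
start/stop are the outermost contributing SNP positions; the reported size
is stop − start, the only convention under which region size equals the
coordinate difference.  For gene annotation only, regions are padded by
25 kb per side (floored at 1 bp, capped at the chromosome length if known)
and genes overlap by ≥ 1 bp on closed intervals, strand ignored.  BED input
is converted from 0-based half-open to 1-based closed internally; GFF3 is
taken as-is.

Type-level comparisons average (not sum) the z tracks of all cross-type
breed pairs, which keeps one- and two-breed types on a common scale;
within-type pairs do not contribute.  Both the per-profile thresholding and
the mean-of-cross-pairs aggregation are documented choices where sum/joint
alternatives exist; both are trivially switchable at the call sites.

## LD and haplotype blocks

Haplotype frequencies come from EM over unphased genotypes (at two loci the
double heterozygote is the only ambiguity; multi-locus blocks enumerate
phase resolutions up to 12 markers, truncating wider spans with a warning;
individuals missing any genotype in the span are dropped).  Convergence is
a maximum frequency change < 1e−10 or 1,000 iterations; the log-likelihood
is non-decreasing by construction and asserted in tests.  D = f(AB) −
pA·pB, D′ = |D|/D_max with the margin-constrained bound, r² =
D²/(pA qA pB qB); monomorphic margins are flagged undefined rather than
raised.

D′ confidence bounds profile the genotype likelihood on a D′ grid (step
0.001) over [0,1] with margins fixed at sample estimates and the sign of D
fixed at its ML estimate; the normalized likelihood is treated as a mass
and the 5th/95th percentile grid points reported (90% interval).  Pair
classes: strong LD iff ci_low ≥ 0.70 and ci_high ≥ 0.98; strong
recombination iff ci_high < 0.90; otherwise uninformative.  A block is a
maximal span whose outer pair is strong LD with ≥ 95% of informative inner
pairs strong LD and at least 3 informative pairs (a single-rule
simplification of the original block-size-dependent minima); overlapping
candidates resolve greedily, longest bp span first, leftmost on ties.
Pairs farther apart than 500 kb are never evaluated, and markers below 5%
within-sample MAF are skipped (switchable).

## Population structure

PCA mean-imputes missing dosages per SNP, centers columns (unit-variance
scaling is off by default and toggleable) and uses the SVD; each
component's sign is fixed by making its largest-magnitude loading positive.
Neighbor joining uses the standard Q-criterion with a deterministic
tie-break (lexicographically smallest pair of cluster names, a cluster
named by its smallest leaf label); negative branch-length estimates are
floored at zero and counted.  The cladogram is built from the *weighted*
F_ST matrix.  Note the first NJ agglomeration is governed by the
Q-criterion, not by the smallest distance entry: on realistic multi-breed
matrices the minimum-distance pair need not join first, though a tight pair
(e.g. two closely related draft breeds) still emerges as sisters.

## Synthetic data

The generator emulates a six-breed array panel under the Balding–Nichols
model: ancestral frequency p ~ Uniform(0.05, 0.95) per SNP, breed frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F) with per-breed drift F, genotypes
Binomial(2, p_breed).  Expected pairwise weighted F_ST is approximately
(F_i + F_j)/2, so the preset drift vector (0.16, 0.10, 0.12, 0.10, 0.012,
0.016) spans a background of roughly 0.01–0.15 with the two draft-like
breeds closest — chosen once to mirror the magnitude ordering of a
real multi-breed horse panel.  The preset uses sample sizes
(124, 56, 116, 99, 107, 69), 10,000 SNPs on 5 chromosomes at ~43 kb mean
spacing, 0.2% missingness, three implanted 12-SNP selection targets
(focal frequency ≈ 0.97, non-focal pinned low) and four LD-block spans
driven by shared haplotype templates with a 1% per-allele noise rate (the
noise keeps block likelihoods non-degenerate).  All randomness flows from
the single config seed through one generator; identical configs produce
byte-identical PED/MAP files.

What the simulations do **not** capture: recombination-driven LD decay
(LD exists only where injected), ascertainment bias of array SNP panels,
genotyping error structure, relatedness within herds, and linked selection
around the implanted targets.  Passing recovery tests therefore establish
the estimators' correctness and the scan's sensitivity under the stated
model, not performance guarantees on real array data.

## Problem sizes and numerics

The test and acceptance workloads use 2,000–10,000 SNPs and 30–100 diploids
per breed — sizes at which every quantity checked (weighted-F_ST recovery
to ±0.02, ≥95% implant recovery over 40 replicates, block frequencies to
±0.03) is stable while the full suite stays fast.  Quantile selection uses
a 1e−9 backoff inside the ceiling to avoid floating-point misordering at
exact integer multiples.  Zero-variance F_ST tracks refuse standardization;
empty window profiles and all-undefined tracks raise; profiles with fewer
than 1,000 windows warn that the 99.9th percentile is degenerate.

## Known limitations

Binary PLINK (BED/BIM/FAM) is not read; VCF ingestion, hierarchical
F-statistics, haplotype-based selection statistics (EHH family), GO/pathway
enrichment and tree bootstrap support are out of scope.  The Gabriel
informative-pair rule is the simplified single-threshold variant noted
above.  Multi-locus EM enumerates 2^(het−1) phase configurations and is
exponential in principle; the 12-marker cap keeps it bounded.
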
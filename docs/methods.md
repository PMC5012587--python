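# Methods

## Overview

`dfcomp` analyses gene-level RNA-seq count matrices from panels of
deficiency heterozygotes (*Df/+*): genotypes hemizygous for a contiguous
block of genes, assayed in two sexes and (optionally) two genetic
backgrounds with biological replicates. The pipeline estimates per-gene
dosage responses against a pooled two-copy reference, stratifies them by
chromatin domain, profiles breakpoint-proximal effects, and traces the
propagation of dose perturbations through a gene-interaction network. A
synthetic panel generator with a complete truth table makes every stage
testable by parameter recovery; its defaults define the study conditions
used throughout the validation suite.

## Normalization and QC

**FPKM.** `count / (length_kb x mapped_millions)`. The per-library
denominator can include spike-in reads (so spike-derived detection limits
share the gene scale) or be overridden; the `CompensationModel` uses TMM
effective library sizes as denominators so that the loss of the deleted
segment's read mass does not inflate the FPKM of the remaining genes.

**TMM.** Between-sample scaling by the trimmed mean of M values: reference
library = the one whose 75th-percentile relative abundance is closest to the
panel mean; per-gene `M = log2(count_j / count_ref)` and
`A = 0.5 log2(count_j x count_ref)` on doubly-expressed genes; 30% two-sided
trim on M and 5% on A (rank-based); inverse-variance (delta-method) weights;
factor `= 2^(weighted trimmed mean of M)`, normalized to geometric mean 1.
M is computed on raw counts, so the factor absorbs relative depth as well as
composition; the effective library size `geomean(lib) x factor` equals the
usual lib-normalized convention's `lib x factor` exactly (a constant shift
in M and A changes no ranks and no weights).

**Expression cutoff.** The 95th percentile (linear-interpolation quantile)
of pooled intergenic-probe FPKM per genetic background; genes whose
reference median FPKM is at or below it are treated as unexpressed. A
`median_above` variant (median of the values above the quantile) is
available as a config switch.

**Gene filter.** Genes with fewer than 1 read in strictly more than 50% of
samples are dropped; a gene at exactly 50% is retained.

**Replicate QC.** Pearson r of `log2(FPKM + 1)` between replicates of each
(genotype, sex, background) group; groups whose best pair falls below
r = 0.9 are excluded, and groups with more than two passing replicates are
reduced to the best-correlated pair. The transform is a package choice (the
field uses several); the operation is idempotent.

**Spike-in ratiometrics.** Libraries receive alternating spike mixes (odd
replicates mix A, even mix B); subpools are designed at 1:1, 1:1.5 and
1.5:1 A:B ratios with balanced mix totals, so observed spike-share log2
ratios recover the designed ratios directly. A regression of
(observed − expected) on log2 abundance reports the compression slope
(≈ 0 for a well-behaved library pair).

## The compensation estimator

For each stratum (sex x background) every genotype is summarized per gene by
the median log2 FPKM over its replicates. The **reference** for a gene is
the median of these genotype summaries over genotypes that carry the gene at
two copies. Two deliberate refinements:

1. *Matched transforms.* The reference is a median over genotype-level
   medians rather than over pooled samples. With overdispersed counts the
   expected log of a noisy count lies below the log of the expected count;
   using the same replicate-median transform on the one-copy and reference
   sides cancels this bias (pooling samples would mix a mean-of-logs with a
   distribution median and bias R by roughly −0.02 to −0.04 log2 at
   dispersion 0.05 with duplicates).
2. *Network reference guard.* When an interaction network is supplied,
   genotypes whose deletion lies within 3 network hops of the gene are
   excluded from its reference pool: such genotypes can carry propagated
   secondary effects of their own deletion on the gene, which would
   systematically depress the reference. Disable with
   `CompensationModel(network_reference_guard=False)` to obtain a reference
   pooled over all two-copy genotypes.

Records are `R = one-copy genotype median − reference` and `C = 2^(R+1)`;
broken genes (partial deletion overlap) are excluded from compensation and
handled by the breakpoint analyses; genes below the cutoff or without any
two-copy reference genotype are flagged and excluded from summaries. Genes
uncovered by several deletions contribute one record per (gene, genotype)
and are deliberately counted once per deletion in pooled summaries.

Summaries per stratum: mean fold `2^(mean R + 1)` (log-scale averaging;
the arithmetic mean of per-record C is reported alongside), Pearson's second
skewness coefficient `3(mean − median)/sd`, plain kurtosis (fourth
standardized moment, normal = 3), two-sided Mann-Whitney U of one- vs
two-copy relative values, and the Kolmogorov-Smirnov D between the one-copy
distribution and the two-copy distribution shifted by −1 log2.

## Moderated differential expression

Each genotype's replicates are compared against all other genotypes of the
same sex and background (wild-type-only reference available as an option).
The precision-weighted moderated pipeline: log2-CPM with TMM effective
library sizes and a 0.5 pseudo-count; gene-wise OLS on the two-group design;
a lowess trend (span 0.5, 3 robustness iterations) of sqrt(residual SD) on
average log2 count; per-observation weights `1/trend(fitted log-count)^4`;
weighted least squares; empirical-Bayes shrinkage of gene variances toward a
scaled-F prior estimated by matching moments of log sample variances
(trigamma inversion by Newton iteration); moderated t on residual + prior
degrees of freedom; Benjamini-Hochberg correction within each
(genotype, sex, background) family. Genes with zero residual variance are
flagged and excluded from moderation. Step-up BH is order-preserving, with
NaNs propagated outside the ranking.

## Chromatin and breakpoints

Genes map to domains (sources: DamID chromatin states, Hi-C states, LADs)
by the midpoint rule (`any_overlap` available). Per state and stratum a
two-sided Mann-Whitney test compares in-state one-copy R against the
complement; for sparse sources (LADs) genes outside every domain remain in
the complement but are not tested as a state. Domains "broken" by a
deletion breakpoint contribute their un-deleted remnant's two-copy genes to
a flanking-expression test against the global two-copy distribution.
Breakpoint-centered profiles rank genes by distance on each side of every
breakpoint (one-copy side negative, two-copy side positive, broken genes
skipped), record the bp distance to the nearest gene edge with a ≤100 bp
proximal flag (gene boundary as a TSS proxy), and feed a sliding 30-gene
unscaled MAD track (windows in gene-rank order, step 1).

## Network propagation

Shells are computed by single-pass multi-source BFS from each genotype's
one-copy genes: shell k = genes first reached at depth k, with the set of
equidistant nearest sources retained. Pairing for the per-degree
correlation: one pair per (shell gene, nearest source), weight 1/m for m
equidistant sources; weighted Pearson r and weighted OLS slope per degree.
When recovery against known true source effects is wanted, the true values
replace the measured source log2FC (regression on a noisy regressor
attenuates the slope by var(x)/(var(x)+var(error)); with the true regressor
the slope estimates the per-edge decay unbiasedly) and pairs aggregate to
one per shell gene with the mean nearest-source value. Cross-background
overlap calls a gene concordant when |fold| > 1.5 with matching sign in
both backgrounds; significant-change counts report per-genotype totals
split by copy class plus the union of two-copy genes significant in at
least one genotype.

## EEE mixture clustering

Per-gene mean one-copy R in each background (females by default) is
clustered with a 2-component bivariate Gaussian mixture under the
equal-covariance ("EEE") constraint, fitted by EM: k-means initialization,
exact E-step via log-sum-exp, pooled M-step covariance, stopping when the
log-likelihood gain falls below 1e-8 (cap 500 iterations; non-convergence
keeps the best state with a flag); singular covariances are
ridge-regularized with a warning. The component with larger mean R is
reported as "better compensated". On well-separated instances the fit
matches a tied-covariance oracle's log-likelihood to numerical tolerance.

## Synthetic panel generator

The generator emulates a DrosDel-style screen and is the ground-truth bed
for all validation. Defaults (the study conditions):

| parameter | default | note |
|---|---|---|
| genes / arm length | 2500 / 25 Mb | non-overlapping tiled genes, lognormal lengths |
| deletions | 40, 0.2–1 Mb | uniform placement, overlaps allowed, each covers ≥1 gene |
| sexes x backgrounds x replicates | 2 x 2 x 2 | plus a wild-type genotype per stratum |
| library size | 10 M fragments | realistic bulk depth for a ~2500-gene share |
| dispersion | 0.05 | NB variance mu + 0.05 mu²; 0 ⇒ noise-free rounded means |
| compensation mixture c_g | 60% Beta(2,2)→[0.05,0.6], 20% c=0, 10% c=1, 5% anti U[−0.5,0), 5% over U(1,1.5] | skewed, heavy-tailed spectrum |
| female repressive boost | +0.5 on c | one-copy genes in LamB/Rep domains, females only |
| propagation | alpha 0.5, depth 3, jitter sd 0.1 | single-pass BFS, shell k shifts by alpha^k x mean nearest-source log2FC |
| network | preferential attachment m=1 over a 5x genome | see below |
| spike-ins | 3 subpools x 8, 2^15 conc range | 3% of each library |

One-copy genes express at `2^(c_g−1)` of their two-copy expectation; broken
genes at half (only the intact homolog). Sex-biased genes (20%, half male-
half female-biased, ±1 log2 in males) support the sex-bias enrichment test;
hybrid backgrounds add a per-gene N(0, 0.1) log2 shift. Intergenic probes
(150, ~0.2% of mean gene expression) provide the cutoff substrate. With a
fixed seed all outputs are byte-identical.

**Network choice.** The interaction network spans a genome five times the
profiled arm (arm genes placed at random among the nodes), with a sparse
tree-like power-law backbone (preferential attachment, m = 1). Rationale:
deletion panels delete a fraction of the genome while the network is
genome-wide, so most shell genes of any genotype are off-arm; a dense
small-world backbone confined to the arm would put most of the arm within
three hops of every deletion, so propagated effects would systematically
depress every gene's two-copy reference — a property real screens do not
have to this degree. With the default backbone a genotype perturbs roughly
tens of profiled genes per hemizygous gene block.

**What the generator does not emulate:** read-level sampling and alignment
artifacts, isoform structure, polyA selection artifacts, GC/length biases
beyond the FPKM length term, correlated biological replicate structure, and
directed or signed regulatory logic. Passing recovery tests therefore
demonstrates the statistical machinery, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

Zero-FPKM observations enter logs floored at 2^-10; quantiles are linear
interpolation (type 7); TMM returns factor 1 when every M is within 1e-6 of
zero; EM covariance ridging uses 1e-8 x (trace + 1); the trigamma inverse
uses Newton iteration with asymptotic guards; fewer records than a MAD
window yields one truncated, flagged window; breakpoints at chromosome
edges give one-sided profiles; empty domain files round-trip as header-only
tables.

## Validation studies and problem sizes

The validation suite (and `scripts/acceptance.py`) uses: the full default
panel (2500 genes, 40 deletions, 328 libraries) for compensation recovery,
domain/breakpoint contrasts and propagation slopes; 500 simulated null
panels of 120 records for test-calibration uniformity; five null DE
simulations of 2000 genes x 18 libraries for type-I calibration; 10
two-component mixtures of 300 points for clustering benchmarks; and ≥20
random small instances per statistical primitive for brute-force oracle
equivalence. These sizes keep a full run in a few minutes on one CPU while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

The moderated DE "rest of stratum" reference mixes many genotypes, so a
gene perturbed in many genotypes (e.g. a hub's neighbour) has a slightly
contaminated baseline; per-degree propagation slopes estimated from two
measured quantities are attenuated by regressor noise (the recovery path
uses true source effects; a deconvolution estimator is not provided); the
EEE mixture assumes exactly two clusters; the breakpoint proximal flag uses
annotated gene boundaries, not TSSs; tissue-specificity indices (tau, TSPS)
are computed from user-provided profiles — the generator does not simulate
tissues.
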
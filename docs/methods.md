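# Methods

`refmatch` studies one question: how well does the population-genetic
distance between a target sample and a phased reference panel predict the
accuracy of reference-based genotype imputation? It answers it with a
masking benchmark on synthetic structured populations: good-quality (GQ)
SNPs are hidden, re-imputed with a haplotype-copying model, and the
posterior distributions are scored against the hidden truth; distances and
accuracies are then correlated across a full factorial of targets,
references, imputer configurations and missingness levels.

## Distance estimators

All four measures are two-population estimators aggregated **ratio-of-
averages** style: per-marker numerators and denominators are summed over
markers first and divided once. Averaging per-marker ratios instead is
noisier and biased for small panels; the ratio of sums is what the package
reports everywhere.

With counted-allele frequencies `p1, p2`, sample sizes `n1, n2` diploid
individuals and allele counts `a_i` out of `m_i = 2 n_i`:

* **G_ST** (Nei, two-population per-marker form):
  `N = (p1 - p2)^2`, `D = 2 p_avg (1 - p_avg)`, `p_avg = (p1 + p2)/2`.
  This printed form is **twice** the classical Nei value (its maximum is
  2.0 at fixed opposite alleles) and carries no finite-sample correction.
  All G_ST thresholds quoted by this package (0.01 "excellent", 0.04
  "satisfactory") live on this scale.
* **F_ST^R** (Reich/Hudson-type, unbiased):
  `N = (a1/m1 - a2/m2)^2 - h1/m1 - h2/m2`, `D = N + h1 + h2`,
  `h_i = a_i (m_i - a_i) / (m_i (m_i - 1))`. A delete-one-block jackknife
  over 20 contiguous, equally sized marker blocks supplies the standard
  error (`SE^2 = (B-1)/B * sum_b (theta_(b) - mean)^2`); a single block
  degenerates to SE 0. The block count, not the block size, is fixed, so
  blocks scale with the marker set.
* **F_ST^WC** (Weir-Cockerham, unweighted `p_bar = (p1+p2)/2`):
  `s^2 = (n1 (p1-p_bar)^2 + n2 (p2-p_bar)^2) / n_bar`,
  `h_bar = (2 n1 p1 q1 + 2 n2 p2 q2) / (2 n_bar)`,
  `N = s^2 - [p_bar q_bar - s^2/2 - h_bar/4] / (2 n_bar - 1)`,
  `D = p_bar q_bar + s^2/2`.
* **F_ST^mWC** (modified WC): `N = (p1 - p2)^2`;
  `D = first_term + (2/(n1+n2)) [n1 p1 q1 + n2 p2 q2]`. Two conventions
  for the first denominator term are shipped: `as_printed` uses
  `(p1 - p2)` (the default; recorded in the estimate's metadata) and
  `squared` uses `(p1 - p2)^2`. Only the squared convention is symmetric
  in the two populations and invariant to relabelling the counted allele;
  the two are rank-equivalent in practice, and `pairwise_matrix` computes
  each unordered pair once and mirrors it, so distance matrices are
  symmetric under either convention.

Markers whose denominator is zero for a measure contribute (0, 0) to both
sums, so every measure is evaluated on the same marker set. The counted
allele is `alleleA` (file REF / first-listed allele) everywhere, removing
any sign ambiguity in `p1 - p2` across populations.

**Finite-sample floor of the printed G_ST.** Because the printed G_ST
subtracts no sampling variance, two independent samples of the *same*
population realize `G_ST ~ (1/m1 + 1/m2)/2` in expectation — about 0.010
for 40 diploid targets (80 alleles) against 120 reference haplotypes. The
corrected estimators (`fst_r`, `fst_wc`) center on 0 at the null instead.
Realized distances in the shipped study therefore start near 0.01, and
"maximally matched" means the floor, not 0.

## Quality control

GQ SNPs are selected with mean call rate >= 0.95 across populations, mean
minor-allele frequency >= 0.1 and stratified exact Hardy-Weinberg p >=
0.01 (all thresholds configurable; 0.01 reads the conventional `10^-2`).
The stratified HWE test conditions on the allele count within each
population (Levene-Haldane conditional distribution of the heterozygote
count), takes the *total* heterozygote count across populations as the
statistic, convolves the per-population conditionals for the null, and
sums the probabilities of all outcomes no more probable than the observed
one (probability-ordering two-sided rule; mid-p is not used). With one
population this is exactly the classical exact HWE test, which is how the
implementation is validated (brute-force enumeration over allele
placements). A Fisher combination of per-population exact p-values is
available as an alternative for users who prefer independent strata
evidence; the convolution test is the default because it is a genuine
stratified exact test with a single null distribution.

Strand handling before any cross-panel computation: markers are matched by
id; allele pairs equal after an optional strand complement are kept (with
the reference relabelled), swapped pairs additionally flip the reference's
haplotype codes, A/T and C/G pairs are removed as strand-ambiguous, and
anything else is removed as unmatched.

## Masking

Whole SNPs are masked across all individuals of the target — the unit of
masking is the SNP, not the genotype — using one seeded permutation of the
GQ set; the mask at fraction `f` is the first `round(f * n)` elements, so
masks are nested by construction. Analyses comparing missingness levels
use only the smallest fraction's markers, the set masked in every
scenario.

## The imputer

A diploid Li-Stephens-style haplotype-copying HMM: the hidden state is an
ordered pair of reference haplotypes, each chromosome switching
independently to a uniformly drawn template with per-interval probability
`rho` (default 0.05), emissions at typed markers allowing independent
per-allele error `epsilon` (default 0.01), emission 1 at missing markers.
Transitions factorize, so forward-backward costs O(markers * H^2); the
masked-marker genotype posterior sums pair posteriors times
`P(dose | template alleles, epsilon)`. Reference panels larger than `H`
(default 40) haplotypes are subsampled per individual by a global
allele-sharing score against the typed genotypes, ties to the lower index.

There is no genetic map: `rho` is constant per interval, matching the
synthetic data, and a documented limitation for map-aware use. An
EM-style routine can refine `epsilon` from the expected mismatch rate
between observed doses and leave-one-marker-out posterior template doses
(`estimate_params`; `rho` is held fixed). The imputer is a scientific
stand-in for production software (MaCH, minimac, IMPUTE2): it reproduces
their posterior-probability contract so that scoring and the factorial
design can be exercised end to end, and the benchmark's "software" axis is
realized as distinct parameterizations of this model (or externally
produced Oxford GEN / MaCH mlprob files read through `genodata`).

## Accuracy scores

Genotype level, against hidden truth `g`:

* Hellinger score `= 1 - sqrt(1 - sqrt(P_g))` — one minus the Hellinger
  distance between the point mass at `g` and the posterior; strictly
  increasing in `P_g`, equal to 1 iff the posterior is degenerate at `g`.
  The 0.45 cut-off marks well-imputed genotypes and inverts to
  `P_g >= (1 - 0.55^2)^2 ~ 0.4865`, which is why it nearly coincides with
  best-guess correctness.
* SEN score `= 1 - |g - dose|/2`, `dose = P1 + 2 P2`; maximal iff the
  posterior expectation equals the true dose; the 0.95 cut-off equals a
  dose error of 0.1.
* best-guess correctness: argmax of the triple, ties broken toward the
  smaller dose (deterministic).

SNP level, truth-free:

* MaCH-style Rsq: population (1/n) variance of the dosages over the
  Hardy-Weinberg binomial variance `2 p (1-p)` with `p` the mean dosage
  over 2; monomorphic SNPs report 0 and are flagged.
* IMPUTE-style info: `1 - sum(f_i - e_i^2) / (2 N theta (1-theta))` with
  `e = P1 + 2 P2`, `f = P1 + 4 P2`, `theta = sum(e)/(2N)`; 1 when `theta`
  is 0 or 1. Reported **unclamped** — worse-than-null posteriors can go
  negative — because the 0.8 summary threshold is unaffected and clamping
  would hide pathology.

Summaries report the percentages over the 0.45 / 0.95 / 0.8 cut-offs,
the Rsq/info means, and everything stratified by MAF class (low: MAF <=
0.05 in the target's own data). For the low-frequency analysis the
SNP-level mean Rsq is the default accuracy measure: genotype-level
percentages at rare variants are dominated by easy major-homozygote calls
and can *rise* as SNPs get rarer, whereas the dosage-variance ratio
exposes how poorly the minor allele is recovered.

## Synthetic data

Two generators, two jobs:

* **Independent-SNP mode** — ancestral frequencies Uniform(0.1, 0.9),
  per-population Balding-Nichols drift
  (`Beta(p(1-F)/F, (1-p)(1-F)/F)`; identity at F = 0), genotypes
  Binomial(2, p). No LD, closed-form expectations: the oracle for the
  estimators. For the printed two-population G_ST the Balding-Nichols
  expectation is `2F/(2-F)`.
* **Founder-mosaic mode** — a shared pool of 16 founder haplotypes drawn
  site-wise from the ancestral frequencies; every population's haplotypes
  are founder mosaics with per-interval switch probability 0.003
  (segments of a few hundred markers, the haplotype sharing imputation
  needs). Divergence `d` maps to founder-usage weights drawn from a
  symmetric Dirichlet with total concentration `(1-d)/d` (exactly uniform
  at d = 0): a divergent population shifts its allele frequencies *and*
  loses founders from its effective pool, so a distant reference panel is
  a genuinely poorer template library. A "complex" population mode
  doubles the founder count and switch rate, depressing LD — the analog
  of a high-haplotype-diversity reference whose imputation difficulty is
  under-predicted by allele-frequency distance. An optional
  founder-drift channel (site flips at rate `drift_flip_scale * d`,
  default off) is available for private-drift experiments.

  Target panels also emulate platform-quality variation: 75 % of markers
  (shared across target populations, as on a shared genotyping array)
  receive per-marker missing-call rates drawn Uniform(0.06, 0.5). These
  markers fail the call-rate filter, so the GQ (maskable) set is a
  minority (~25 % of markers) and the typed scaffold left for the
  imputer is dense and rich in common SNPs — the configuration the
  masking benchmark presumes, where GQ SNPs are a small, stringently
  filtered subset of a much larger typed marker set. Without this, a
  uniform-MAF simulation passes nearly every SNP and "mask all GQ SNPs"
  would leave no usable scaffold.

  Because no closed form links the Dirichlet concentration to realized
  G_ST, `calibrate_divergence` bisects `d` until the realized pairwise
  G_ST (median over 3 seeds, computed on mean-MAF >= 0.1 markers) is
  within 10 % of a requested value.

What the generator does **not** emulate: recombination hot/cold spots and
genetic maps, mutation, gene conversion, admixture gradients, genotyping
error correlated with genotype, and realistic site-frequency spectra.
Passing benchmarks here show the pipeline's internal consistency and the
qualitative distance-accuracy law under controlled structure; they do not
certify accuracy levels on any particular real cohort.

## The shipped study (`refmatch.study`)

12 target populations of 40 diploid individuals at divergence 0.02 each —
internally unstructured, mutually distinct, like a set of closely related
regional samples — and 4 reference panels of 120 phased haplotypes at
divergence (0.0, 0.06, 0.13, 0.45), the last in complex mode; 2,000 SNPs.
Realized printed-scale G_ST spans roughly 0.01 (the sampling floor) to
0.15. The headline quantities are: the Pearson correlation between G_ST
and the percentage of masked genotypes at Hellinger >= 0.45 over the 48
combinations; best-guess concordance for a maximally matched pair; and
the Hellinger yield for a pair calibrated to G_ST just below 0.04. The
correlation's zero test is the plain two-sided t-test
`t = r sqrt((n-2)/(1-r^2))` (no Fisher stabilization), matching standard
practice for reported r values. Outlying combinations (studentized
residual > 3) are flagged and reported alongside, never removed.

Problem sizes for the repeated-seed analyses (missingness robustness, MAF
stratification) use a reduced grid — 4 targets, 600 SNPs, 3 seeds, nested
50 %/100 % masks — which keeps every property of interest expressed while
the full 12 x 4 grid is reserved for the headline correlation.

## Numerical choices and degenerate inputs

* Forward-backward works on per-marker normalized mass (scaling, not
  logs); posterior triples are renormalized and agree with exhaustive
  path enumeration to 1e-9 on small instances.
* Posterior text I/O keeps 6 significant digits; triples whose sum falls
  in [0.99, 1.01] are renormalized on read, anything further off is an
  error, as is any negative probability.
* Argmax ties break toward the smaller dose; subsampling ties toward the
  lower haplotype index; both for determinism.
* Empty marker sets, empty score sets and a reference below 2 haplotypes
  are errors; markers with fewer than 2 alleles in a population are
  skipped (with a warning) by the corrected F_ST estimators; monomorphic
  markers yield HWE p = 1 and Rsq = 0.
* All randomness flows from explicit integer seeds through per-population
  spawned generators; identical config + seed is bit-reproducible.

## Known limitations

* The imputer has no genetic map, no pre-phasing step and no chunking;
  it is not a performance substitute for production imputation software.
* The printed G_ST floor means very small true distances (< ~0.01) are
  not resolvable at the study's sample sizes; conclusions near the
  "excellent" threshold are about the floor region, not about G_ST 0.001.
* The as-printed mWC convention is asymmetric in the population pair and
  not allele-swap invariant; use the `squared` convention when those
  properties matter.
* Low-frequency-variant results ride on few minor-allele carriers per
  SNP and are the noisiest part of the benchmark.
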
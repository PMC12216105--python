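# Methods

`demoml` infers the parameters of two-population demographic histories from
genomic polymorphism data by simulation-based supervised learning: simulate
many datasets under a parameterized coalescent model, reduce each dataset to
a fixed vector of summary statistics, and train one regressor per parameter
on the (statistics, parameter) pairs. Classical approximate Bayesian
computation (ABC) over the same reference table serves as the baseline, and
permutation importance plus Shapley values explain what the fitted models
use.

## Demographic models

Both models start from an ancestral population of constant diploid effective
size `N_anc` that splits into two descendant populations `Split_time`
generations before the present.

**Isolation with migration (IM).** The descendants keep constant sizes
`N_current_1`, `N_current_2` and exchange migrants at a constant symmetric
rate `Migration_rate` (fraction of a population replaced per generation)
from the split until the present. Five parameters, with uniform priors
`Split_time ~ U[1, 5000]` generations, sizes `~ U[100, 10000]` diploids, and
`Migration_rate ~ U[0, 0.001]`.

**Secondary contact with varying sizes (SC).** Each descendant changes size
exponentially with per-generation rate `Growth_rate_i` (positive =
forward-time growth), and migration is restricted to the most recent
fraction `Migration_duration` of the post-split period (0 = strict
isolation, 1 = continuous migration, window anchored at the present). Eight
parameters; priors `Split_time ~ U[100, 5000]`, sizes `~ U[1000, 5000]`,
`Migration_rate ~ U[0, 0.005]`, `Growth_rate_i ~ U[-0.001, 0.002]`,
`Migration_duration ~ U[0, 1]`.

Backward-time size trajectories follow the standard coalescent convention
`N_i(t) = N_current_i * exp(-g_i * t)`, applied over the whole post-split
period (the alternative — growth starting at some onset time after the
split — would need an extra parameter the model does not have). SC prior
draws whose trajectory would put a population below one diploid anywhere
before the split are rejected and redrawn during sampling; with the default
priors this affects a small fraction of draws and the count is reported.

Simulation uses msprime's coalescent with recombination; mutations are
placed under a binary model on a continuous genome, so every variant is
biallelic with known ancestral state. Sites that are non-segregating or
non-biallelic after simulation are dropped. The study design is 20
independent neutral loci of 2 Mb, 10 diploids per population, recombination
1.0e-8 and mutation 1.25e-8 per bp per generation (human-like rates); all
of it is configurable through `SampleDesign`.

## Summary statistics

Eleven classes are computed per locus. Within-population classes are
evaluated on each population sample and on the pooled sample; "segregating"
always refers to the sample in hand. Coordinates are 0-based, half-open.

1. **S** — proportion of segregating sites (per bp).
2. **D** — Tajima's D with the standard 1989 constants.
3. **PI** — mean and sd over segregating sites of the per-site expected
   heterozygosity `n/(n-1) * (1 - p^2 - q^2)`.
4. **WinH** — mean and sd over non-overlapping 50 kb windows of the
   haplotypic heterozygosity `1 - sum_h f_h^2`.
5. **SFS** — percentage of SNPs at derived count i, and the sd of gaps
   between consecutive SNPs (physical distance) at derived count i.
6. **LD** — mean and sd of `r^2` (phased two-locus haplotype frequencies)
   for SNP pairs in 19 geometric distance bins whose geometric means run
   from 282 bp to 1.4 Mb; per-bin pair counts capped at 10,000 by seeded
   subsampling.
7. **IBS** — nine deciles of the pooled length distribution of maximal
   identical-by-state segments for subsets of m haplotypes (m = powers of
   two up to the scope size: 2,4,8,16 within populations, plus 32 for the
   pooled sample at the default design); 20 seeded random subsets per m,
   exhaustive when there are at most 20 subsets; flanking segments to the
   locus ends included. Subset draws are made on lexicographically sorted
   haplotypes, so the statistics are invariant to the input row order.
8. **AFIBS** — for each SNP at derived count i, the segment around the SNP
   over which all i derived-allele carriers are identical, extended to the
   nearest disagreeing site on each side (exclusive) and truncated at the
   locus ends; per-frequency mean and sd.
9. **Fst** — Hudson's estimator, one minus the ratio of summed
   within-population to summed between-population mean pairwise differences.
10. **Dxy** — raw between-population divergence per bp.
11. **JSFS** — percentage of SNPs at joint derived counts (i, j) over the
    full (n1+1) x (n2+1) grid.

Per-locus values are aggregated across loci with the mean, median and
sample variance (n-1 denominator). For the default design this enumerates
exactly 3024 named features; the composition (frequency ranges per scope,
IBS m-values, JSFS grid) is configurable via `StatConfig`.

Frequency-range conventions: per-population SFS and AFIBS cover i = 1..n
(a site fixed derived within one population still segregates in the pooled
sample), the pooled scope covers i = 1..n-1; SFS percentages are normalized
by the number of sites inside the scope's range so they sum to 100. S, D,
PI and LD use only sites truly polymorphic within the scope.

Masking and imputation: statistics undefined on a locus (no qualifying
site, fewer than two values for a dispersion) are masked and ignored by the
cross-locus aggregation; features masked on every locus are imputed with 0
(which is the training mean after standardization under rare missingness),
and per-feature missing counts are kept alongside the vector.

## Regression methods

One single-output model per demographic parameter, all trained on the same
standardized features (training mean/sd, population-sd convention;
zero-variance columns map to zero) with squared-error loss:

- **RF** — random forest, 300 trees of depth 20 (within the tuned 200-300 /
  15-20 ranges), `max_features = p/3` (the classic regression-forest mtry).
- **XGB** — gradient boosting, 100 trees of depth 7 (xgboost, hist method).
- **MLP** — fully connected ReLU network with hidden widths
  (512, 256, 128, 64, 32, 16), Adam (lr 1e-3, batch 200), target
  standardized internally for conditioning. Training runs an explicit epoch
  loop with early stopping monitored on the *external* validation split
  (patience 20, at most 500 epochs), so validation rows never enter the
  gradient. The best-validation weights are restored.

MLP predictions outside the prior interval are clipped to the violated
bound; tree ensembles cannot extrapolate beyond their training targets and
are returned unchanged. All seeds are explicit; tree methods are bit
reproducible, the MLP is reproducible given its seed.

## ABC baselines

Distances are Euclidean on features scaled by their median absolute
deviation over the reference table (zero-MAD statistics are dropped from
the distance); the tolerance is the accepted proportion, with ties broken
by row index. **loclinear** first retains up to 300 statistics with the
highest absolute correlation with the target parameter, then adjusts the
accepted draws by an Epanechnikov-kernel-weighted linear regression,
`theta* = theta - b (s - s_obs)`; a singular system falls back to a scaled
ridge (and to least squares if still singular) with a warning. **neuralnet**
replaces the linear fit with a single-hidden-layer (three tanh neurons)
network fitted by weighted least squares through L-BFGS with two random
restarts — written in-repo because scikit-learn's MLP accepts no sample
weights — and shifts draws by the fitted conditional-mean difference;
non-convergence returns the raw draws with a warning flag. The 300-statistic
budget is applied at every tolerance. Point estimates are the mean or median
of the (adjusted) accepted draws.

## Evaluation

Per parameter and method: RMSE; MAE with its standard error (sd of absolute
errors / sqrt(n)); and NMAE = MAE / (prior high − prior low), which makes
errors comparable across parameters. The error-heterogeneity analysis fits
a random forest of |standardized error| = |y_hat − y| / (prior range) on the
true parameter values, ranks parameters by permutation importance, and
averages |standardized error| over a 20 x 20 binning of the two most
explanatory parameters (empty cells masked). Signed errors are kept for
plotting; absolute errors drive the ranking.

## Interpretation

**Permutation feature importance** is the degradation of held-out R^2 under
within-column shuffles (5 repeats, seeded), via scikit-learn's machinery
applied to the full prediction pipeline (standardizer and clipping
included). Class-level importance sums member features per statistic class
with negative values floored at 0, normalized to fractions of the total.

**Shapley values.** XGB models use xgboost's built-in exact TreeSHAP
(`pred_contribs`). Random forests use an exact path-dependent TreeSHAP
implemented in this package (float64; validated against brute-force
coalition enumeration, with local accuracy holding to ~1e-9 even for
targets of order 1e3 — xgboost's float32 contributions satisfy the identity
only to relative ~1e-6). The MLP uses a seeded permutation-sampling
estimator with a 100-row background set, whose per-permutation telescoping
makes the values sum to prediction minus the sampled-background mean. The
reports expose mean-|phi| rankings, beeswarm data and per-feature
dependence pairs.

## Problem sizes used by the tests and the acceptance script

Full-scale replication (10,000 simulations of 20 x 2 Mb loci) is a cluster
computation; the shipped checks run a scaled-down isolation-with-migration
benchmark chosen to keep a complete desk run in minutes: 1500 simulations
(1000 train / 250 validation / 250 test) of 5 loci x 500 kb with 4 diploids
per population (1287 features). At this scale all three methods recover
every parameter far better than the analytic midpoint-predictor baseline
(NMAE 0.25), and the learned methods beat rejection ABC for the current
population size; the *ordering among* the three methods (MLP ahead of
XGB ahead of RF) emerges at full scale and is not asserted at this scale. Analytic identities (Watterson's segregating-site expectation,
the midpoint-NMAE value, Shapley local accuracy, brute-force oracle
equivalence of all eleven statistic classes) are checked exactly or within
three standard errors.

## What the generator does and does not emulate

The synthetic data generator *is* the study's data-generating process:
neutral, uniform mutation and recombination rates, phased haplotypes, known
ancestral states, no missing data, no sequencing error. Passing tests
therefore demonstrate correctness of the statistics and learning machinery
under the model, not robustness to selection, rate heterogeneity,
phasing/polarization error or missingness — all outside scope.

## Known limitations

- The default feature-list composition is one consistent reading of the
  per-class definitions that reproduces the 3024-feature total; alternative
  compositions are expressible through `StatConfig`.
- The ABC neural-network adjustment applies the conditional-mean shift
  without the heteroscedastic variance correction some implementations add.
- The Python TreeSHAP is exact but not optimized for thousand-leaf forests;
  explaining many instances of a full-size RF is slow (XGB's native path is
  fast).
- Model selection (IM vs SC), asymmetric migration, more than two
  populations, and CPU-time benchmarking are out of scope.
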
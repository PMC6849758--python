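# Methods

This note documents the models, defaults and numerical choices behind
`climvuln`, and what the synthetic-data tests do and do not demonstrate
about real data.

## The framework

A population's climate-change risk is assessed from three components.

**Exposure** ranks projected change 1–4. Inputs per population: current
and future (2070-style) maximum temperature (°C), summer rainfall (mm),
and ENM suitability (relative occurrence probability, 0–100), plus the
binary suitable/unsuitable state of the area under each time slice.
Dissimilarity bins: temperature increase low < 6, medium 6–8, high > 8 °C;
rainfall decrease low < 25, medium 25–50, high > 50 %; ENM change
small/large at |25| %. Rules, highest level first:

- 4: became unsuitable AND (temperature high OR rainfall high)
- 3: became unsuitable OR temperature high OR rainfall high
- 2: remains suitable AND ENM change > 25 % AND (temperature OR rainfall
  medium)
- 1: remains suitable AND ENM change < 25 % AND both dissimilarities low

These formulas are not exhaustive. When no rule matches exactly, the
engine assigns level 1 if the area remains suitable with a small ENM
change, else level 2 if it remains suitable, else level 1, and sets a
`rule_mismatch` flag with the assignment path. In the bundled case study
exactly one population (Bizkaia: both dissimilarities medium, ENM change
+5.3 %) needs the fallback; the flagged assignment (level 1) matches its
published rank. Percent changes are rounded to one decimal,
half-away-from-zero, matching the published tables; one published cell
(Granada's % suitability change, −52.5) is inconsistent with its own
printed inputs ((37−80)/80 = −53.8) and the recomputed value is used
wherever arithmetic is verified.

**Sensitivity** combines an adaptive and a neutral code. Adaptive, from
the per-population frequencies of the candidate climate-adaptive alleles:
`++` mean < 0.5 and > 1/3 of loci below 0.25; `+` mean < 0.5 otherwise;
`0` mean ≥ 0.5 with ≥ 1 locus below 0.25; `−` otherwise (the boundary
mean = 0.5 with no low-frequency locus is `−`). Neutral, from
heterozygosity: `−` > 0.9, `0` 0.75–0.9, `+` < 0.75. The published record
does not state the combination rule; the seven published
(adaptive; neutral) → overall mappings are all reproduced by an additive
score (`++`=2, `+`=1, `0`=0, `−`=−1; overall `+` if the sum ≥ 1, `0` at 0,
`−` below), which is the rule implemented, with the mapping kept as a
regression fixture.

**Risk** integrates (exposure, overall sensitivity, range-shift flag),
first match wins: High = exposure 3–4, sensitivity `+`, range `−`;
Medium–high = exposure 3–4 and (sensitivity `+` or range `−`);
Medium = exposure 2 and (sensitivity `0/+` or range `−`), or exposure 3
with sensitivity `−/0` and range `+`; Low = exposure 1 with
(sensitivity `−` or range `+`), or exposure 2, sensitivity `−`, range `+`.
Four of the 24 input combinations — (1, 0, −), (1, +, −), (4, −, +),
(4, 0, +) — are covered by no published rule; the engine returns
`Unclassified` with a diagnostic rather than guessing. On the classified
part of the lattice, risk is monotone in each component (property-tested).

## Synthetic data: what it emulates

`SimConfig` defaults encode the study conditions: 10 populations
(8 in the "main" region, 2 on a northern island across a sea channel),
9 diploid individuals each, 6000 neutral + 8 adaptive biallelic SNPs,
within-region F_ST 0.056, region-level F 0.08, ~8 % missing genotypes
(genotyping rate ≈ 0.92), one injected close-relative pair (an individual
copied with 5 % of genotypes re-sampled, PI_HAT ≈ 0.95).

Neutral allele frequencies follow a hierarchical Balding–Nichols model:
ancestral p ~ U(0.05, 0.95); region frequency ~ Beta(p(1−F_r)/F_r, ·);
population frequency ~ Beta around the region value with F = target F_ST.
Adaptive loci take the same population-level draw and add a logistic
shift, logit(p_pop) + β·z, where z is the covariate (maximum temperature
or summer rainfall, alternating) standardized across populations and
β = ±`env_effect` (default 2.0 per environmental s.d.). Setting
`env_effect = 0` therefore reduces adaptive loci exactly to the neutral
model — the null-reduction property the calibration tests rely on.

The landscape is a raster stack on a seeded grid (default 40×40 in the
pipeline examples; any ≥ 8×8): temperature with a latitudinal gradient,
altitude lapse and smoothed noise; rainfall with the opposite gradient;
altitude from Gaussian massifs; slope as its gradient; a 3-class land
cover; a Gaussian-niche suitability surface s(tmax, rain) ∈ [0, 1]
(optimum 26 °C / 120 mm) applied identically to both time slices, so
suitable→unsuitable transitions arise mechanistically from the future
delta (default +6.5 °C, rainfall ×0.6). Binary suitability for synthetic
populations uses a fixed s ≥ 0.25 cut. All stage randomness flows from
child seeds of `SimConfig.seed`.

What the generator deliberately does **not** emulate: linkage
disequilibrium, coalescent demography, isolation by distance in the
neutral loci (populations are exchangeable islands — the stepwise MRDM
correctly finds *no* landscape signal on synthetic neutral data), read
depths, and genotyping error beyond uniform missingness. Passing tests
therefore demonstrate estimator correctness and calibration under the
stated model, not robustness to LD or spatially autocorrelated drift.

## Estimator notes

**PI_HAT** is the method-of-moments P(IBD=1)/2 + P(IBD=2) from genome-wide
IBS counts and their expectations given whole-dataset allele frequencies;
plink's finite-sample corrections are omitted (negligible at thousands of
loci). **HWE** is the exact two-sided test: enumeration of heterozygote
counts conditional on allele counts, p = sum of configurations no more
probable than observed; monomorphic samples return 1.

**QC order** (the published filter list is unordered; this order is the
conventional one and is part of this package's contract): individual
missingness → locus missingness → MAF (computed across all retained
individuals) → relatives (the pair member with more missing data is
dropped; ties by sample-id order) → HWE (p < .01 in ≥ 3 populations).
A fixture test demonstrates the order is load-bearing. Populations with
≥ 7 individuals after QC are nominated for population-level statistics.

**Weir–Cockerham θ** uses the 1984 a/b/c components per locus and
ratio-of-sums aggregation; loci monomorphic overall or typed in < 2
populations are excluded from both sums. **AMOVA** decomposes squared
allele-count distances between individuals (missing pairs rescaled to the
full locus count) into among/within-group sums of squares; Φ_ST from the
usual moment estimators, p by permuting individuals among groups, and an
R²-style effect size SS_among/SS_total is reported (package-specific; not
claimed equivalent to other software's R²).

**Outlier scan.** The neutral envelope simulates Balding–Nichols loci at
the observed sample configuration, with F calibrated by bisection (common
random numbers per evaluation; tolerance 0.005 on the multi-locus mean θ,
max 50 steps). Conditional quantiles use a sliding expected-heterozygosity
window: half-width 0.025, widened to the nearest ≥ 200 simulated points
(which is also the nearest-bin rule when an observed locus falls outside
the simulated support; such loci are flagged). A locus is a directional
outlier when its θ exceeds the conditional q_{1−α} (default α = 0.01).
Only the upper tail is scanned. With α ≥ 1 every informative locus flags.

**Logistic environmental regression** is a binomial GLM of per-individual
dosage (successes out of 2) on the standardized covariate; Wald p, with a
likelihood-ratio fallback when separation is detected (non-convergence,
non-finite s.e., or |slope| > 15).

**GEA.** The association scan regresses mean-imputed dosage on a covariate
plus K latent factors. Because the covariate is constant within
populations, the regression is computed on population mean dosages
(sample-size-weighted WLS — the identical point estimate to the
individual-level fit) so the standard error reflects true
between-population replication including drift. Latent factors are the
top-K left singular vectors of the population frequency matrix
residualized against the covariate (one alternating-least-squares pass),
which prevents the factors from absorbing the tested effect; K must be
≤ G−3 for G populations. Per-locus residual variance is moderated toward
a p(1−p)-proportional prior (exact under Balding–Nichols + binomial
sampling) with prior df 20, the prior scale bias-corrected by the χ²
median. Five runs by default: run 1 uses unperturbed factors (so a single
run is deterministic), later runs re-orthonormalize factors under a small
seeded perturbation; z-scores are combined by the median, rescaled by
λ = median(z²)/0.456, converted to p against χ²₁ and BH-adjusted at
FDR 0.05. On neutral synthetic data the within-region λ sits in
[0.8, 1.3]. At the full (two-region) scale λ is ≈ 2 by construction:
drift between two regions along a region-separated covariate is a single
random draw that no per-locus error model can average away — this is the
expansion-cline/allele-surfing confound, and exactly why scans are run at
two scales with the within-region scale authoritative for candidate
nomination.

**Candidate intersection** requires, per locus, all three evidence types
with same-covariate agreement between the GEA flag (within-region scale
by default) and a significant (p < .05) logistic regression; the reported
covariate is the flagged one with the smallest q. The warm-adaptive allele
is the one whose frequency rises with temperature (positive slope on the
dosage allele); the dry-adaptive allele rises as rainfall falls (negative
slope). Orientation with a zero slope is flagged ambiguous.

**Connectivity.** Cost surfaces map suitability s to 1 + 99(1−s)
(continuous rasters may instead use piecewise-linear breakpoints,
categorical ones explicit dictionaries; land costs must lie in [1, 100]);
sea cells override to 200 (alternative 120). The lattice graph uses
8 neighbours, edge resistance = arithmetic mean of the two cell costs
(harmonic-mean variant behind a flag), diagonals scaled by √2; a
4-neighbour mode exists for closed-form oracles. Effective resistance and
per-pair currents come from sparse LU solves of the component-grounded
Laplacian (direct solver; agreement with a dense pseudo-inverse oracle to
1e−9); pairs in different components are ∞ and flagged. Cumulative current
assigns each cell half the sum of |branch currents| incident to it,
summed over all population pairs. The range-shift flag is this package's
explicit operationalization of "becomes isolated": score = mean cumulative
current within `buffer_radius` (default 3) cells of the population; flag
`−` when future/present score < τ (default 0.5), or when every remaining
corridor (future effective resistance within `corridor_factor`, default
2.0, of the present median) ends in a future-unsuitable population. Raw
scores are always reported alongside the flag.

**MRDM** vectorizes strict lower triangles; overall significance uses R²
(equivalently F) against simultaneous row/column permutations of the
response matrix, p = (exceedances + 1)/(n_perm + 1); per-predictor
p-values use the pseudo-t under the same permutations (marginal
single-predictor fits can be obtained by fitting each predictor alone).
The stepwise procedure fits geography first, mirrors the stage-1 lower-
triangle residuals into a symmetric zero-diagonal matrix, fits all
non-empty landscape subsets against it, and selects the highest-R² model
whose predictors are all significant at .05; finding none is a result,
not an error. The collinearity screen drops predictors with lower-triangle
R² > .70 against geography or an already-retained predictor, in input
order.

## Test and acceptance problem sizes

Simulation-based checks are sized to run on a laptop-class budget while
keeping the conditions of interest: outlier-scan type-I pools 20
replicates of 2000 loci (10 populations × 10); GEA calibration and power
use 10–12 replicates of 1000 loci; the end-to-end intersection check uses
6 + 6 replicates of 2000 loci; MRDM type-I uses 200 null replicates of
9 populations at 1000 permutations; the circuit oracle uses a 400-node
random grid. Power floors (≥ 50 % planted-locus recovery for the GEA,
≥ 40 % for the full intersection, ≤ 1 false candidate per 2000 neutral
loci) and the planted-correlation floors were frozen from pilot runs
before the assertions were written.

## Known limitations

- The exposure and risk rule sets are faithful to the published tables,
  including their gaps (four unclassifiable combinations, one fallback-
  classified case-study row); they are not a complete decision theory.
- Binary suitability for the case study is an input (the published
  threshold value is not recoverable); `max_sss_threshold` implements the
  sensitivity+specificity-maximizing rule for users with raster data.
- The GEA replaces an MCMC latent-factor model with a deterministic
  WLS core plus seeded run perturbation; it preserves the pipeline shape
  (K factors, 5 runs, median z, λ, FDR 0.05) but is not numerically
  interchangeable with the MCMC implementation.
- The outlier envelope is Balding–Nichols, not a coalescent island model;
  both condition θ on heterozygosity, but tail shapes differ under strong
  mutation/migration regimes.
- AMOVA is genotype-distance based and two-level; region strata are
  handled by re-running with region labels rather than a nested
  three-level decomposition.
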
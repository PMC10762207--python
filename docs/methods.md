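# Methods

This note documents the models implemented by `domcascade`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
world does and does not establish.

## Formula assignment

**Ionisation model.** All ions are treated as singly charged deprotonated
molecules [M−H]⁻, so the neutral mass is `m/z + 1.007276467 Da`. The proton
mass includes the electron-mass correction: at a 0.2 ppm tolerance the
electron mass (~3 ppm at 180 Da) is decisive, so using the hydrogen atomic
mass instead would misassign essentially every peak.

**Constant table.** One monoisotopic mass table
(`chem_core.MONOISOTOPIC_MASS`) underlies every mass computation: ¹²C = 12
exactly; H, N, O, S, P at ≥ 9 decimal places.

**Enumeration.** Candidates are all CHNOSP formulas within the element
bounds (C 0–100, H 2–200, O 0–70, N 0–3, S 0–2, P 0–2) whose exact mass lies
within ± 0.2 ppm of the neutral mass. Internally a cached heavy-atom grid
(C, N, O, S, P) is pruned by mass and hydrogen is solved per query — at
≤ 0.2 ppm on ≤ 1000 Da the residual window is far narrower than one
hydrogen, so at most one H count can match per heavy-atom combination. The
result contract is exhaustiveness, verified in the tests against an
independent brute-force loop oracle.

**Chemical filters.** Default: double-bond equivalents
`DBE = 1 + C − H/2 + N/2 + P/2` must be a non-negative integer. Optional
H/C and O/C plausibility caps are off by default. Online assignment tools
additionally use homologous-series and isotopologue logic; those are out of
scope here and replaced by a documented deterministic tie-break: smallest
|ppm error|, then fewest heteroatoms (N+S+P), then lexicographic canonical
string.

**Detection limit and replicates.** The method detection limit retains
peaks with `intensity ≥ 2 × noise`, where noise is by default the median
intensity of the lowest-intensity decile (the estimator is pluggable; the
literature definition it stands in for is not reproducible from published
descriptions). The MDL is applied to each exported replicate mass list
*before* the duplicate-retention step: noise peaks anchor the noise estimate
and must be removed before they can spuriously match between replicates.
Only signals detected in both duplicates (greedy nearest match within
0.5 ppm, each peak used once) are retained, merged at the intensity-weighted
mean m/z with the mean intensity. Assigned-peak intensities are normalised
to sum to 1 per sample.

## Descriptors and compound classes

`AI_mod = (1 + C − 0.5·O − S − 0.5·(N+P+H)) / (C − 0.5·O − S − N − P)` (the
modified aromaticity index, treating half the oxygen as carbonyl); defined
as 0 when the denominator ≤ 0 or the quotient is negative, and clamped to
≤ 1, so saturated molecules never read as condensed aromatics.

Published van-Krevelen classification schemes differ in their exact cut
points and the scheme used for the field data this package emulates is not
printed anywhere; class shares are therefore approximate by nature. The
shipped default table (first match wins) is:

| order | class | rule |
|---|---|---|
| 1 | condensed-aromatic-like | AI_mod ≥ 0.67 |
| 2 | tannin-like | AI_mod < 0.67, O/C > 0.67, H/C < 1.5 |
| 3 | carbohydrate-like | O/C > 0.67, H/C ≥ 1.5 |
| 4 | amino-sugar-like | 0.55 < O/C ≤ 0.67, H/C ≥ 1.5, N ≥ 1 |
| 5 | protein-like | 0.3 < O/C ≤ 0.55, H/C ≥ 1.5, N ≥ 1 |
| 6 | lipid-like | O/C ≤ 0.3, H/C ≥ 1.5 |
| 7 | unsaturated-hydrocarbon-like | O/C ≤ 0.1, 0.7 ≤ H/C < 1.5 |
| 8 | lignin-like | 0.1 < O/C ≤ 0.67, 0.7 ≤ H/C < 1.5, AI_mod < 0.67 |
| 9 | other | catch-all |

The entire table is user-overridable (YAML/JSON rule lists), which is the
real contract: reproducing any particular study's class shares requires that
study's table.

## Universal-pool statistics

A formula is universal when detected (intensity > 0) in at least a fraction
`threshold` of samples; the default 1.0 is the strict in-all-samples
definition, and the parameter exists only for sensitivity analyses.
Per-sample universal fractions are reported both by richness (% of detected
formulas) and by intensity (% of total normalised signal). Intensities are
*never* renormalised after subsetting, so the intensity share of any
compound group is a fraction of the sample's total assigned signal — which
is also why universal and non-universal intensity shares are exactly
complementary. Class profiles are computed with count weighting (shares of
formula counts, summing to 100%) and intensity weighting (shares of signal),
because both conventions are common and they answer different questions.

Weighted mass uses neutral masses (the neutral-mass equivalent of the ion
m/z scale); the statistic is scale-invariant in the intensities and bounded
by the member masses.

## Rarefied similarity

Units are repeatedly subsampled without replacement to a fixed depth
(default 6000 formulas, 1000 iterations) and the percentage of drawn
formulas found in the reference set is averaged. Draws are presence-based
and uniform, not intensity-weighted, matching rarefaction practice in
diversity studies. Units smaller than the depth are excluded with a logged
record, not up-sampled. The reference set is not rarefied by default (a
flag enables symmetric rarefaction). The expected value of the statistic is
the hypergeometric expectation `100·k/n`, which the tests use as an
independent oracle. Randomness: one master seed; per-unit substreams are
derived by CRC-32 hashing of the unit id, so results are independent of
processing order. `rarefaction_profile` provides the sd-vs-depth diagnostic
for judging sampling adequacy; the decision tolerance is the user's.

## Trend models

`fit_trend` fits an additive GLM of a per-sample response on the focal
gradient factor plus nuisance factors (catchment, the other gradient,
sample type). A focal × gradient interaction can be fitted first and is
dropped when a likelihood-ratio test gives p > 0.05. Families:

- `binomial` — proportions of counts, with over-dispersion handled by
  quasi-likelihood Pearson dispersion scaling. (An observation-level random
  effect is the mixed-model alternative; quasi-likelihood was chosen because
  it is deterministic and dependency-light, and the dispersion estimate is
  exposed so the two can be compared.)
- `gaussian-logit` / `gaussian-log` — continuous proportions / positive
  responses, transformed to normalise residuals and back-transformed for
  reporting.
- `gaussian` — identity.

Marginal means average link-scale predictions with equal weights over all
combinations of observed non-focal levels (the conventional estimated
marginal means definition), then back-transform; confidence intervals are
delta-method t intervals (normal when the model is saturated). Contrasts
against the baseline level (first level, e.g. 5 cm or shoulder) are adjusted
with the multivariate-t reference distribution of the whole contrast set
(Tukey-style max-|T|, computed by QMC rectangle probabilities with a fixed
internal seed); a singular contrast covariance falls back to Holm with the
adjustment recorded in the result. Adjusted p-values are floored at the
unadjusted ones.

## Predictor reduction, selection, and variance partitioning

- `reduce_collinear`: while any pair of predictors has Pearson |r| > 0.80,
  remove the variable involved in an offending pair with the largest mean
  |r| against all remaining variables; exact ties keep the earlier-listed
  column. Deterministic given input order.
- `forward_select`: stepwise selection for multivariate responses. Adding a
  candidate is tested with a partial pseudo-F under Freedman–Lane
  permutation of reduced-model residuals (n_perm ≥ 99, seeded); candidates
  enter at p ≤ 0.10 (best F first) and included predictors are dropped again
  when their marginal p rises above 0.10. Directionality and permutation
  count are configurable since published analyses rarely state theirs.
- `pcnm`: truncated-distance principal coordinates. The default truncation
  is the longest minimum-spanning-tree edge (keeping all sites connected);
  larger distances are replaced by 4× the truncation; the matrix is Gower
  double-centred and eigendecomposed, keeping eigenvalues > 1e-10, unit-norm
  vectors, first nonzero loading positive. The construction reproduces the
  standard R implementation's eigenvalues and eigenvectors exactly (checked
  in the tests against frozen values). Note the leading eigenvector on a
  regular transect is a full sine wave, not a monotone trend.
- `rda_adj_r2`: multivariate least squares on centred matrices;
  `adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1)` (Ezekiel). Negative adjusted
  values are legal and reported raw. Rank-deficient inputs error with the
  aliased column names.
- `variance_partition` (2–3 matrices): adjusted R² of every nonempty union,
  Venn components by Möbius inversion, so raw components sum exactly to the
  full-model adjusted R²; a truncated view clamps negatives to 0 for
  display. Unions are made full-rank by dropping aliased columns, which is
  what makes duplicated or nested matrices behave sensibly.
- `hierarchical_partition`: Shapley-style averaging of each predictor's
  incremental adjusted R² over all subsets; contributions sum to the
  full-model adjusted R². Exact enumeration is capped at 15 predictors
  (2¹⁵ subsets) — larger analyses must group variables first, as is standard
  practice with hundreds of environmental predictors.

All predictors are standardised to zero mean and unit variance before
selection and partitioning.

## Synthetic world

The generator encodes the degradation cascade as one ordinal stage axis
applied to both gradients: soil depth index and hillslope position index
each map to a stage in [0, 1]; stream samples sit at the cascade end-member
(stage 1 on both axes). Defaults describe a plausible field survey and were
fixed before any acceptance measurement:

- design: 4 catchments × 4 positions × 4 depths (5/15/30/60 cm) + 1 stream
  = 68 samples;
- library: 3000 formulas, lignin-dominated mixture (55% lignin-like, 10%
  tannin-like, 7% each condensed-aromatic/carbohydrate/unsaturated-
  hydrocarbon-like, 5% lipid/protein-like, 4% amino-sugar-like), masses
  log-normal around 400 Da within 150–1000 Da, all within the assignment
  element bounds and chemical filters, classes verified by the classifier;
- universal core: 400 formulas, 79% lignin-like (mirroring the strongly
  lignin-dominated universal pools of field DOM);
- gradient effects: non-universal members of tannin-, condensed-aromatic-,
  carbohydrate- and unsaturated-hydrocarbon-like classes are removed with
  probability `0.6 × stage`, tilted toward low-mass members (mass-bias 1.0)
  within the carbohydrate/unsaturated-hydrocarbon classes so their weighted
  mass rises along the cascade (emulating the ~10–20% field shifts);
- universal intensity share: 50% baseline + 10 percentage points per
  gradient-axis extreme, with per-sample Gaussian noise (sd 2 pp) standing
  in for measurement and compositional noise;
- intensities: lognormal(0, 1) (the standard heavy-tailed choice for MS
  signal; no empirical intensity distribution is published); non-universal
  detection probability 0.6; duplicate peak lists with 0.05 ppm Gaussian
  jitter (the calibration-error scale of modern instruments) and 10% noise
  peaks at 6–15% of the faintest real peak, i.e. below the detection limit.

**What a green test establishes — and what it does not.** The synthetic
world has exactly planted effects, independent lognormal intensities, a
clean universal core, and noise structures chosen to be separable by the
stated estimators. Recovery of the planted universal-intensity slope
(± 2 pp) and detection of the carbohydrate mass shift (p < 0.05 in ≥ 90% of
seeds) establish that the statistical pipeline is unbiased and adequately
powered *for this world*. Real FT-ICR-MS data add ionisation suppression,
correlated intensities, calibration drift, isotopologues and adducts — none
of which are simulated — so green tests validate the computation, not the
field inference.

## Numerical choices and edge cases

- Canonical formula strings (C,H,N,O,S,P order, count-1 elision) are the
  join keys everywhere; no mass-tolerance joining after assignment.
- Per-sample normalised intensities sum to 1 ± 1e−9 (validated at dataset
  assembly); subsetting never renormalises.
- A sample detecting zero formulas, or a compound group with zero intensity,
  yields missing values, not errors.
- All Monte-Carlo operations (rarefaction, permutation tests) are exactly
  reproducible from their seeds; the Tukey QMC rectangle probability uses a
  fixed internal seed.
- When the MDL threshold removes every peak (all intensities equal with
  factor ≥ 1 is the canonical case), an empty list is returned with a
  warning.
- `fit_trend` on a saturated design (zero residual df) reports dispersion
  from a unit-scale covariance and normal rather than t quantiles.

## Known limitations

- No isotopologue verification, adduct chemistry beyond [M−H]⁻, internal
  recalibration, or multiply charged ions.
- The compound-class table approximates unpublished boundary schemes; class
  shares on real data depend on the user's table.
- Hierarchical partitioning is exact-enumeration only (≤ 15 predictors).
- The trend model's quasi-likelihood dispersion is a deliberate substitute
  for observation-level random effects; estimates agree closely for
  moderate over-dispersion but are not identical.
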
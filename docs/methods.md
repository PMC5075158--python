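# Methods

This note documents the models, algorithms and design choices behind
`hadsim`: what the synthetic cohorts are, how each missing-item method is
defined, how bias and imprecision are measured, and where the package's
conclusions should and should not be trusted.

## 1. The synthetic cohort model

The original item-level data (cancer patients and survivors) are not
public, so simulated cohorts are drawn from a generative model calibrated
to published descriptive statistics.

**Latent structure.** Each subject has two latent traits
(T_anx, T_dep) ~ bivariate standard normal with correlation ρ. Item *i*
of subscale *s* has latent response

    y*_i = λ_s · T_s + √(1 − λ_s²) · ε_i,   ε_i ~ N(0, 1) iid,

so y*_i is standard normal marginally and two items of the same subscale
correlate λ_s². The observed category (0–3) is the number of thresholds
(t_i1 < t_i2 < t_i3) that y*_i exceeds. Thresholds are parameterized as
t_ij = (j + ½ − μ_i)/σ: the item is a rounded-and-clipped N(μ_i, σ) on
the 0–3 value scale, with an item-specific location μ_i and one global
scale σ. This is the simplest structure that can match item means,
subscale SDs, three Cronbach's alphas and three score–QoL correlations
simultaneously.

**Quality of life** is a single continuous score

    QoL = w_a · T_anx + w_d · T_dep + σ_q · z,   z ~ N(0, 1),

standardized to unit variance (only its correlations with the HADS scores
matter). Internal FACT-G-style item structure is deliberately not
modelled.

**Covariates.** Age ~ N(63, 11.8²) truncated to [19, 87]; male with
probability 0.46; immigrant with probability 0.588 (the immigrant-enriched
composition of the population the generator emulates); on-treatment with
probability 0.5 (an undocumented mix of patients and survivors; 0.5 is the
neutral choice). Covariates are drawn independently of the traits: no
joint covariate–score distribution is published, so demographic-mechanism
results are *qualitative* — the mechanism selects by covariate rank, and
only the induced ordering matters.

## 2. Calibration

`LatentTraitModel.fit()` solves the parameters in four blocks against one
fixed 50,000-subject calibration sample (common random numbers, so every
bisection objective is smooth and the fit is deterministic given its
seed):

1. **Item locations μ_i** — bisection so the analytic discretized-normal
   mean Σ_j Φ((μ_i − j − ½)/σ) equals the target item mean; exact up to
   solver tolerance.
2. **Global scale σ** — bisection so the two simulated subscale SDs match
   their targets in mean relative error. One σ cannot match both SDs
   exactly (fitted: anxiety 4.39 vs 4.20, depression 3.92 vs 4.11); the
   split difference is accepted because no acceptance quantity depends on
   the SDs directly.
3. **Loadings λ_anx, λ_dep and latent correlation ρ** — bisection of each
   simulated Cronbach's α against its target: λ_anx against the anxiety
   α, λ_dep against the depression α, then ρ against the 14-item distress
   α (which the subscale fits leave as its only free parameter).
4. **QoL weights** — with sd(QoL) = 1 fixed, the two subscale correlation
   targets give a 2×2 linear system in (w_a, w_d) using trait–score
   covariances estimated on the calibration sample; σ_q² = 1 − Var(w_a
   T_anx + w_d T_dep). The distress–QoL correlation is then determined:
   r_t = (r_a·sd_a + r_d·sd_d)/sd_t ≈ −0.794 vs the −0.796 target, a
   built-in consistency check.

Every bisection validates its bracket and raises a calibration-failure
error naming the worst residual if a target is unreachable (e.g. an α of
0.999).

**Item-mean targets.** The published per-item means (2 dp) sum to 5.52
(anxiety) and 5.11 (depression) while the published subscale means are
5.66 and 5.07 — a gap larger than rounding can explain, presumably
because item-level and form-level summaries used slightly different
available-case sets. The default targets rescale each subscale's item
means proportionally to sum to the subscale mean; no item moves by more
than 0.03. The depression α is calibrated to 0.83 (the value the source
text states; its table prints 0.84 — the ±0.02 tolerance covers both).

**Fidelity and limits.** A 100,000-subject cohort reproduces the item
means (±0.01), subscale means (±0.03), alphas (±0.005) and QoL
correlations (±0.005). Distribution *shape* is only approximately right:
the depression normal-band (score ≤ 7) proportion comes out ≈ 75.1 % vs
76.1 % observed — the real data are slightly more skewed than a
discretized normal. Consequences: population-bias results for
rank-selection mechanisms, which depend on tail means, are reproduced to
within ~0.2 points rather than exactly (complete-case bias ≈ −3.0 vs
−3.17 published). Passing tests show the *methods* behave as published
under a faithful-moments cohort; they cannot certify behaviour under
distribution shapes the model does not capture (e.g. strong zero
inflation or differential item difficulty).

## 3. Sample sizes

Dataset sizes are the totals needed to detect standardized differences
d = 0.8, 0.5, 0.2 with a two-sided two-sample t test at 80 % power,
α = 0.05, computed from the exact noncentral-t distribution (df = 2m − 2,
noncentrality d·√(m/2)) by incrementing the per-group size m: totals 52,
128, 788. The normal approximation would give 50 for d = 0.8; the exact
computation is required. Equal group sizes are assumed (totals are even).
No test is ever run — the numbers only set n.

## 4. Missingness induction

Two stages, per replicate:

* **Candidates.** `random`: each subject independently with probability
  p_sub (binomial count — this mechanism is defined by per-subject
  uniform draws, not by rank). `subscale`: exactly round(p_sub·n)
  subjects with the highest *true* target-scale score. `demographic`: top
  round(p_sub·n) by the logistic linear predictor β·(age_z, male,
  on_treatment, immigrant), default β = (1, 1, 1, 1) — only the ordering
  matters. Ties in either ranking are broken by a seeded random
  permutation before a stable sort.
* **Deletion.** Each in-scope item of each candidate is deleted
  independently when a uniform draw falls below p_item. Scope is the
  analyzed scale's items: 7 for a subscale, all 14 for distress. (Whether
  deletion should also touch the other subscale's items is not specified
  anywhere; the per-scale scope is the reading consistent with the
  published "n method" counts, e.g. ~40 of 52 half-rule survivors at
  p_sub = p_item = 0.5, and is configurable via `target_scale`.)

Item-level deletion is uniform across items by design; differential item
missingness is out of scope.

## 5. The seven handling methods

Definitions as in the imputation module docstring; numerical choices:

* Imputed values are real-valued and never rounded; observed cells are
  never modified; every completed cell lies in [0, 3].
* **Half-rule**: "at least half of 7 items" = ≥ 4 observed (3.5 is not
  attainable; ≥ 4 also matches the published scored-subject counts).
  Distress under the half-rule is reported only when both subscales pass.
* **Complete case** excludes per analyzed scale: a subject missing only
  anxiety items still contributes a depression score. Whole-form
  exclusion would be stricter but does not match per-scale reporting.
* **MICE**: m = 10 chains, each initialized at item means, 10 burn-in
  sweeps over items 1..14 in order; each incomplete item is regressed by
  OLS on the other 13 over the rows where it was observed, and its
  missing cells are redrawn as prediction + N(0, σ̂²) noise (σ̂² =
  RSS/dof, floored at 1e-12), truncated to [0, 3] after each draw. The 10
  completed matrices are averaged cell-wise before scoring — the
  point-estimate equivalent of scoring each set and averaging the
  estimates; variance combination across imputations is out of scope. A
  degenerate regression (fewer than 2 usable rows, or a singular system)
  falls back to item-mean ± N(0,1) noise for that item in that sweep, and
  is logged. With n = 52 and 14 regressors the OLS step is deliberately
  minimal-norm (`lstsq`), which handles rank deficiency without pivots.
  `mi_half` reuses the same completed matrix as `mi` within a replicate.

## 6. Metrics and aggregation

Individual metrics average over the subjects a method actually scored
(mirroring the "n method" columns); a replicate in which a method scores
nobody yields undefined (NaN) metrics, which aggregation counts and
excludes rather than zeroing — a cell where every replicate is undefined
is flagged invalid. Population imprecision is aggregated as the mean over
replicates of the per-replicate squared bias (the MSE of the sample
mean), so aggregated imprecision ≥ (aggregated bias)² by Jensen's
inequality — a property the tests assert. "Important" bias is |bias| ≥
2.1 points (10 % of the subscale range).

## 7. Engine and reproducibility

All requested methods are evaluated on the *same* masked replicate,
removing between-method Monte-Carlo noise from comparisons. Each
replicate's generator is seeded by (master_seed, SHA-256 hash of the
cell's coordinates, replicate index), so adding, dropping or reordering
grid levels never changes another cell's draws; cell streams are also
independent of the source-cohort draw. Results CSVs are written with a
fixed float format and are byte-identical across runs with the same
configuration and seed.

Default design: source cohort n = 1385 (the complete-form count the
generator emulates), 1000 replicates per cell. The test suite and the
acceptance script use reduced designs chosen so Monte-Carlo standard
errors stay well inside each comparison's tolerance: 200 replicates for
the single headline cell (SE of the complete-case population bias
≈ 0.04), 100 replicates per cell for the 18-cell maximum-bias sweep, and
a 100,000-subject cohort for descriptives (SE of a subscale mean
≈ 0.013).

## 8. Known limitations

* One global item scale trades off the two subscale SDs (±0.2); severity
  band proportions inherit a ~1-point discrepancy.
* Covariates are independent of the traits, so demographic-mechanism
  *bias magnitudes* are not comparable to values estimated on real data
  (where covariates correlate with distress); directions and orderings
  are.
* The MICE engine is a linear Gaussian FCS with truncation — adequate for
  point-estimate scoring of 0–3 items, not a general-purpose imputer (no
  predictive-mean matching, no proper posterior draws of β).
* The extreme-missingness grid keeps the per-scale deletion scope, so
  p_item = k/14 corresponds to an expected k/2 of 7 subscale items
  deleted; results there are directional comparisons of the two subscale
  methods, not calibrated reproductions.
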
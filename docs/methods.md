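# Methods

## Design and likelihood

The unit of analysis is the twin pair. With `T` phenotype variables per
person (predicted brain age anchored to `T` chronological-age intervals),
a pair contributes a `2T`-vector assumed multivariate normal with mean
`(μ, μ)` — means equal across twin order and zygosity — and covariance

```
Σ_pair(z) = [[Σ_A + Σ_C + Σ_E,    r_A(z)·Σ_A + Σ_C],
             [r_A(z)·Σ_A + Σ_C,   Σ_A + Σ_C + Σ_E]]
```

with `r_A(MZ) = 1`, `r_A(DZ) = 0.5`, shared environment fully correlated
within pairs in both groups, and non-shared environment uncorrelated.
These three constants are the identifying assumptions of the classical
twin design; they are hard-coded, not estimated.

The raw-data (FIML) likelihood sums each pair's observed-subvector normal
log-density: rows/columns of missing entries are deleted *within* the pair,
never the pair itself. Pairs are grouped by missingness pattern and
summarized by per-pattern sufficient statistics `(n, Σx, Σxxᵀ)`; patterns
of equal dimension are stacked and evaluated with batched Cholesky/solve
calls, so one likelihood evaluation costs roughly
`O(#dimensions · T³)` independent of sample size. On complete data this
reduces exactly to the two-group closed form, which the tests verify to
1e-8 relative error against an independent row-by-row density oracle.

## Parameterization

All component matrices are built from path coefficients (squares or Gram
products), so Σ_A, Σ_C, Σ_E are positive semi-definite by construction and
the optimizer needs no inequality constraints beyond simple bounds. Path
signs are not identified; scale-like paths are bounded below at zero and
reported quantities are variances. Means are `T` free parameters (the
data are residualized, so means are ≈0, but they are estimated rather than
fixed).

Model families (all constructible with any component subset containing E):

- **Univariate ACE/AE/CE/E** — one path per component.
- **Correlated factors** — per component a lower-triangular `T×T` path
  matrix (Cholesky); the saturated reference for component structure.
- **Autoregression (quasi-simplex)** — per component a latent chain
  `g_t = β_t g_{t−1} + ζ_t` with innovation paths, plus non-shared
  environmental occasion residuals. The first occasion's innovation
  carries the full initial variance (no prior state). **Identification:**
  with per-occasion E residuals the quasi-simplex is rank-deficient — the
  first occasion's E innovation trades against its residual, and likewise
  at the last occasion — so the default shares a single residual variance
  across occasions (`residual_structure="equal"`); `"free"` reproduces the
  textbook diagram at the cost of two unidentified directions and an
  inflated parameter count. A variant with genetic occasion residuals
  exists for sensitivity analysis (`genetic_residuals=True`).
- **Common pathway (1 or 2 factors)** — each latent phenotype factor has
  total variance fixed to 1, split as `a_f² + (c_f²) + e_f² = 1` with the
  E part derived from the constraint; thus `a_f²` *is* the factor's
  heritability and "the factor is 74% genetic" is a direct parameter
  function. Loadings `λ_1..T` are free (first bounded non-negative for
  sign identification; a second factor's first loading is fixed to 0).
  Per-occasion A and E residuals. One factor requires `T ≥ 3`, two require
  `T ≥ 4`.
- **Independent pathway** — separate common A and E factors with free
  loadings acting directly on occasions, plus per-occasion residuals.
  Nests the one-factor common pathway (proportional loadings).

Derived summaries: standardized components `Σ_X[i,i] / Σ_W[i,i]`, the
common-vs-residual split for factor models, and component correlations
`rG_ij = Σ_A[i,j]/√(Σ_A[i,i]·Σ_A[j,j])` (rE, rC analogous); cells with a
vanishing component variance are reported as NaN.

## Optimization

`fit` minimizes −2lnL with multi-start L-BFGS-B (default 10 starts; the
model-selection pipeline uses 3 plus cross-seeded starts, see below).
The first start is data-informed: means at observed means, scale-like
paths scaled to the pooled SD, and each family's moment initializer
applied to rough component estimates from the classic identities
`Σ_A ≈ 2(X_MZ − X_DZ)`, `Σ_C ≈ 2X_DZ − X_MZ`, `Σ_E ≈ W − X_MZ` computed
from pairwise-complete sample blocks. Remaining starts are seeded jitters.
Non-positive-definite proposals evaluate to +∞ (optimizer-safe). A fit
that converges from no start is returned flagged `converged=False` with a
warning, and the pipeline excludes it from selection.

High-dimensional Cholesky fits can stop in local optima several likelihood
units above structured submodels, which corrupts likelihood-ratio
orderings. The pipeline therefore cross-seeds starts: every candidate
starts from the reference fit's implied components, the 2-factor common
pathway and independent pathway additionally from the exact embedding of
the 1-factor solution, and the reference is refit from every candidate's
solution. After this, fitted −2lnL respects nesting in practice (asserted
by tests).

## Inference

- **LRT**: `χ² = Δ(−2lnL)`, `df = Δ(free parameters)`, central chi-square
  reference by default — the convention of applied twin analyses even for
  boundary-constrained variance components, so conventional decision
  sequences are reproduced; the 50:50 chi-bar-square mixture is available
  (`boundary=True`). A nested fit beating its parent beyond tolerance
  raises a refit error rather than returning a negative χ².
- **AIC** = −2lnL + 2k on the raw likelihood; ties break toward fewer
  parameters.
- **Profile CIs**: bounds where the profiled −2lnL (re-optimizing all
  other parameters under an equality constraint, SLSQP) rises by the χ²₁
  quantile (3.841 at 95%), located by outward marching with warm starts
  and bisection; standardized quantities are clipped to [0, 1] with an
  explicit boundary flag.

### Model-selection pipeline

Stage 1 fits the correlated-factors reference and the candidates
(autoregression, 1- and 2-factor common pathway, independent pathway).
A candidate is *adequate* when its LRT against the reference is
non-significant (α = 0.05). Among adequate candidates, a fuller model
that nests another adequate candidate (cp2 and ip both nest cp1) is
discarded when the LRT between them is non-significant — parameters that
can be fixed to zero without significant deterioration are — and the
lowest AIC among the survivors wins. The parsimony step matters: with a
pure lowest-AIC rule the probability that the fuller neighbor of a true
1-factor common pathway wins by chance (P(χ²₃ > 6) ≈ 0.11 for the
independent pathway) does not shrink with sample size, capping recovery of
the true model near 80%; the nested-LRT step restores ~95% per comparison.
Stage 2 refits the winner with reduced component sets (ACE → AE → CE → E;
for AE winners just E) and accepts a reduction when its LRT is
non-significant and its AIC lower. Per-variable residual genetic variances
of a common/independent-pathway winner are additionally tested by fixing
each to zero (diagnostic rows in the comparison table). If no candidate is
adequate the reference itself is retained, flagged in the notes; a winner
whose loadings are all ≈0 is flagged as degenerate.

The default component set is AE, matching the two-component multivariate
diagrams this pipeline mirrors; `components="ACE"` inserts the drop-C
stage.

## Correlation estimators

- Cross-interval phenotypic correlations treat both twins as individuals
  with pairwise-complete observations (Pearson with Fisher-z CIs, or
  polyserial with the column variable split into equal-count bins — the
  ordinalization convention is ours, chosen because the estimate converges
  to the Pearson value as bins grow).
- Twin-pair correlations are ML under a bivariate normal with mean and
  variance equal across twin order (double-entry/intraclass convention,
  invariant to relabeling). For fixed r the mean and variance maximizers
  have closed forms, leaving a one-dimensional profile in r whose χ²₁
  crossings give asymmetric likelihood-based CIs. Perfectly correlated
  pairs are reported at the boundary ±1.
- Polyserial correlation: thresholds from the ordinal margins
  (Φ⁻¹ of cumulative proportions), ρ by ML on the conditional likelihood,
  profile-likelihood CI. Matches a brute-force grid maximizer to 2e-3 on
  small samples (property-tested).

## Preprocessing

- `assign_interval` uses completed years (floor of age): 55.9 → 51–55.
  A boundary convention is unavoidable; floor matches "age at assessment"
  in completed years.
- `age_anchor` keeps at most one record per subject per interval (earliest
  wave — the first observation), errors on duplicate subject/wave records,
  drops and tallies out-of-range ages, and reports how many subjects
  contribute to 1/2/3 intervals.
- `residualize` regresses each interval variable independently on the
  requested covariates (scanner and ethnicity as dummies, age and birth
  year centered within interval) by OLS with intercept, pooling both
  twins as individuals — only means are being adjusted, so family
  clustering is deliberately ignored here. Whether such residualization
  should pool intervals instead is not determinable from the design we
  mirror; per-interval was chosen and is flagged as a choice, not a fact.
  Rank-deficient designs raise an error naming the collinear columns
  (pivoted QR).

## Synthetic cohorts

`simulate_wide` draws complete pairs from the exact model-implied pair
distribution (eigendecomposition sampling, so degenerate/zero-variance
models are allowed). `simulate_cohort` emulates the target study design:
three waves with truncated-normal ages (means 56.1/61.8/67.5, SD 2.6,
published ranges), twins sharing birth year, ethnicity and age at
assessment; wave ages redrawn until increasing within subject; a 1.5T
scanner at wave 1 and 3T later; ethnicity category frequencies
0.883/0.053/0.034/0.030; birth years uniform on 1943–1955. The phenotype
recorded at a wave is the subject's latent trajectory value for the
interval containing that wave's age, plus scanner (+1 phenotype unit
default), cohort (0.1 units/birth-year) and ethnicity (0–0.4 unit) shifts
— so a subject assessed twice within one interval yields a genuine
duplicate, exercising the deduplication rule. Default cohort size is 734
subjects (170 MZ + 130 DZ complete pairs + 134 singletons) with per-wave
participation 0.8; attrition is independent per subject and wave by
default (`pair_attrition=True` shares it within pairs) — within-pair
attrition correlation is not documented for the design we emulate, so it
is configurable rather than assumed.

What the generator does **not** emulate: non-normal phenotypes, real
prediction-model error structure (heteroscedasticity over age,
training-sample bias), selective attrition correlated with the phenotype,
and scanner effects on variances (only means shift). Passing tests
therefore show the estimators are correct under the stated model, not that
the model is right for any particular real cohort.

## Validation studies and problem sizes

`twinage.validation` backs the test suite and `scripts/acceptance.py`:

- AE recovery: 50 replicates of 2000+2000 complete pairs, generating paths
  a=0.8, e=0.6 (standardized A = 0.64).
- CP factor recovery: 25 replicates of 1500+1500 pairs, factor genetic
  path 0.86 (factor heritability 73.96%), loadings 0.8, residual paths
  0.3/0.45.
- CI coverage: 500 replicates of 300+300 pairs, nominal 95%.
- Selection consistency: 100 replicates of 200+200 pairs (CP truth) and
  25 replicates (simplex truth) through the full pipeline.

Replicate counts and pair numbers were chosen so Monte-Carlo error is
small relative to the assertions (3 MC SEs for recovery, ±2 points for
coverage) while the whole suite stays desk-scale on one CPU.

## Known limitations

- The likelihood is continuous-normal only; no ordinal-threshold FIML.
- No definition-variable (continuous-age) modeling — age-interval
  anchoring is the supported design; no latent growth-curve models (mean
  structure is destroyed by residualization) and no hybrid
  simplex-plus-common-factor models.
- LRTs on variance components use the central reference by default
  (conservative at boundaries); profile CIs assume a unimodal profile.
- The polyserial matrix method's binning convention is a package choice;
  with genuinely ordinal data supply the ordinal variable directly to
  `polyserial_correlation`.
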
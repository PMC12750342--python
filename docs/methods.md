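# Methods

## Problem setting

In karst regions with high geochemical backgrounds, paddy soils carry
naturally elevated total cadmium and arsenic, yet the rice grown on them
often stays within food-safety limits: alkaline pH and abundant Fe/Mn
oxides immobilise the metals, decoupling total soil concentration from
plant uptake. Judging such soils by national risk screening values (RSV)
therefore produces large false-positive rates — soils flagged unsafe whose
rice is fine. This package derives *region-specific* soil thresholds from
paired soil–rice survey data and scores them against the national system.

Two thresholds are derived per element (Cd, As) and pH bin
(neutral: 6.5 < pH ≤ 7.5; alkaline: pH > 7.5):

- **Safety threshold (ST)** — the regional analogue of the RSV: the soil
  total at which a fitted transfer model predicts grain concentration
  equal to the food-standard maximum allowable concentration (MAC).
- **Hazard threshold (HT)** — the regional analogue of the risk
  intervention value (RIV): HT = MAC × HC95, where HC95 is the
  95th-percentile reciprocal bioconcentration factor from a fitted
  sensitivity distribution; at soil levels above HT an estimated 95% of
  rice exceeds the MAC.

## Transfer model

The model is ordinary least squares on the log10 scale,

    lg(C_rice) = c + b·pH + d·SOM + a·lg(C_soil) + Σ_k e_k·lg(oxide_k),

with pH and SOM untransformed and every concentration (soil total,
available fraction, six Fe/Mn oxide fractions) entering as its base-10
logarithm. Candidate predictors are screened by the p-value of their
Pearson correlation with lg(C_rice) (α = 0.05, computed on the transformed
scale). Collinearity is controlled by variance inflation factors,
VIF_j = 1/(1 − R²_j): while any VIF exceeds 5, the member of the most
correlated pair (|r| > 0.7) is dropped, preferring to keep the soil-total
form over the available form — available and total concentrations of the
same metal are near-collinear, and the total is the quantity regulated.
Fits report R, R², adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1), the
overall F-test p-value, and per-predictor VIFs. Per-coefficient t-tests
are reported but play no role in screening, which is correlation-based.

Relative predictor importance is reported as the absolute standardized
coefficient |b_j|·s_xj/s_y, max-scaled to 100%. This is an explicitly
labelled surrogate: commercial packages report "normalized importance" by
unstated algorithms, so rankings are comparable across tools but exact
percentages are not.

## ST derivation

The fitted model is inverted at the MAC with covariates fixed: pH at the
bin's representative value (7.0 or 8.0), SOM and the oxide fractions at
study-wide means (a single set, not per-bin). When the soil total appears
in exactly one term the inversion is the algebraic rearrangement
lg(x*) = (lg MAC − Σ other terms)/a. The As model also contains the
available fraction, which is substituted by the linear tie
A-As = 0.721·(S-T-As) − 0.263 (on the linear scale, before the log) so the
total appears in two terms; the solver is then Brent root finding on
lg(x) over [−2, 4] (0.01–10,000 mg·kg⁻¹, wide enough for any paddy soil),
with the lower bracket edge raised to where the tie turns positive. Every
returned ST is round-trip verified: the model prediction at ST matches
the MAC to 1e-10 on the lg scale, and closed form and root finder agree
to 1e-6 relative where both apply.

A reproducibility caveat carried in the test suite: re-deriving ST from
the *published, 3-decimal* regional coefficients gives ≈4.98/≈6.46
(Cd, pH 7/8) and ≈96.1/≈97.5 (As), whereas the regional tables print
4.54/7.12 and 91.43/92.30 — those were evidently computed from
full-precision coefficients that are not public. The procedure is exact;
agreement with the printed STs is asserted at ±15%.

## SSD and HT derivation

Per element and pH bin, each site contributes BCF = C_rice/C_soil (stored
as the dimensionless ratio; "×100%" is a display convention — the
published reciprocal values 48.29–194.3 are only consistent with the
ratio) and its reciprocal 1/BCF. The empirical cumulative percent of
1/BCF uses the Hazen plotting position y = 100·(rank − ½)/n by default
(Weibull 100·rank/(n+1) available; the choice is exposed because the
source workflow does not state one), with average ranks on ties, so y is
always strictly inside (0, 100). The S-curve

    y = a / (1 + (x/x0)^b)

is fitted by nonlinear least squares (scipy `curve_fit`), initialised at
a = 100, b = −2, x0 = median(x). Because y *rises* with x, b is negative
(the conventional form with b > 0 is decreasing); the exact inverse

    x = 10^( lg(a/y − 1)/b + lg x0 )

is sign-agnostic. HC95 is the inverse evaluated at y = 95 on the *fitted*
curve, not the empirical 95th percentile, and HT = MAC × HC95 with no
intermediate rounding. If a free-asymptote fit converges with a < 95 the
percentile is unattainable and an error is raised; the pipeline therefore
pins a = 100 by default (`fix_a_at_100`), which is the natural asymptote
of a cumulative percent and stabilises bins with ~30 sites whose upper
plateau is not yet visible in the data.

## Evaluation

A (soil threshold, grain limit) pair classifies each site by the sign
pair (ln(soil/threshold), ln(grain/limit)): quadrant I both exceed (true
positive), II soil safe but grain exceeds (false negative), III both safe
(true negative), IV soil exceeds but grain safe (false positive). Sites
exactly on a boundary count as safe (the exceedance conditions are strict
inequalities). Rates are quadrant shares of all classified sites — so
accuracy + FP + FN = 100 exactly — and are reported to one decimal with
half-up rounding. Criterion scoring applies each of RSV, ST, RIV, HT to
the samples of its own pH bin.

Quality classes per element: I (priority protection) at or below the
lower threshold, II (controllable risk) up to the upper threshold, III
(strict control) above it; exact boundary ties take the safer class, and
the composite site class is the worst across elements. An optional
co-monitoring flag demotes class III to II when the site's measured grain
is within its limit (off by default).

## Synthetic data generator

No field data are public, so the generator emulates the survey's
documented structure; its defaults are the study conditions:

| quantity | default | basis |
|---|---|---|
| n | 125 sites (116 modeling / 9 validation) | survey size |
| pH | 25.6% U(6.56, 7.5) ⊕ 74.4% U(7.5, 8.25) | reported range and bin shares |
| SOM | truncated normal, mean 34.55, sd 12 g·kg⁻¹ on [9.53, 70.30] | reported mean and range; sd assumed |
| soil totals | log-normal, means 2.16 (Cd), 60.18 (As) mg·kg⁻¹; sd 0.5 lg units | reported means; dispersion assumed |
| oxides | log-normal at the regional means (C-Fe 390, C-Mn 80, F-Fe 34450, F-Mn 1080, Am-Fe 4190, Am-Mn 970); sd 0.15 lg units | reported means; dispersion assumed |
| available As | 0.721·total − 0.263 + N(0, 5), floored at 0.001 | published tie; noise assumed |
| available Cd | 0.45·total + N(0, 0.15), floored at 0.001 | typical availability share; assumed |
| grain | regional transfer models + N(0, σ) on the lg scale | σ_Cd = 0.25, σ_As = 0.02 |

The grain noise levels were set by variance arithmetic so that refitting
the generating specification at n = 116 lands near the regional fits'
adjusted R² (≈0.72 for Cd, ≈0.997 for As): the Cd linear predictor has
variance ≈0.19 lg² under these covariate distributions, and
0.19/(0.19 + 0.25²) ≈ 0.75. Oxides, SOM and pH are drawn independently —
the real survey documents cross-correlations among soil properties that
the generator does not reproduce — and there is no spatial structure.
Passing tests therefore demonstrate correctness of the *procedures*
(inversion, fitting, scoring) under the stated conditions, not agreement
of dataset-dependent statistics (validation R², Table-style accuracies,
importance percentages) with the unreleased field data; those are covered
by interval sanity checks only.

## Numerical choices and degenerate inputs

- Split, generation and pipeline substreams derive from one root seed via
  `numpy.random.SeedSequence.spawn`, so stages are independently
  reproducible and a rerun writes byte-identical artifacts.
- Perfect collinearity in a VIF computation is reported as `inf`, not an
  exception; a rank-deficient OLS design raises, naming the dependent
  columns.
- Root finding uses `brentq` with xtol 1e-13; an unbracketed root raises
  with a sampled residual curve for diagnosis.
- Samples with pH ≤ 6.5 (below the study range) are excluded from
  threshold workflows with a warning.
- ST ≤ HT is *not* asserted: nothing in the construction guarantees the
  ordering (for As the two come out within a few percent of each other).

## Sizes used in the checks

Unit tests run at n = 12–200; generator calibration at n = 10,000;
coefficient-coverage at 200 replicates of n = 116; the end-to-end
pipeline at the survey scale of 125 sites (which completes in well under
a second). These sizes make every check exact or tight while keeping the
default suite fast.

## Known limitations

- The available-fraction ties are linear with additive noise, which can
  produce values near the 0.001 mg·kg⁻¹ floor at small totals and does
  not bound available below total.
- HC95 is a point estimate; no bootstrap or profile confidence intervals
  are propagated into HT (none are published for the reference values).
- Only the logistic SSD form is implemented; log-normal or Burr
  alternatives are out of scope.
- The regional constants bundled in `paddythresh.reference` are specific
  to neutral-to-alkaline karst paddies of the Gejiu–Mengzi area; applying
  the derived thresholds elsewhere requires refitting on local data.
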
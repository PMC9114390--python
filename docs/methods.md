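# Methods

## Game, utilities and the structural/regression identity

The task is a binary trust game. Player A chooses between an outside
option Z with payoffs (z_A, z_B) and trusting (W), simultaneously stating
a belief τ_A ∈ [0, 1] that Player B will cooperate. After W, Player B
chooses Cooperate → (x_A, x_B) or Defect → (y_A, y_B). Two strict
orderings define the game: y_A < z_A < x_A (trust is a genuine risk for
A) and z_B < x_B < y_B (B is tempted to defect). Guilt is
belief-dependent: if B defects, B lets A down by
τ_A·x_A + (1 − τ_A)·y_A − y_A = τ_A·(x_A − y_A) relative to what A
expects, and a guilt-averse B pays γ utility per point of that harm.
Guilt is role-dependent: only the second mover carries preference
parameters.

Three utility specifications for B (after W):

- absolute-difference inequity: u = pay_B − α·|pay_A − pay_B|;
- Fehr–Schmidt: u = pay_B − φ·max(pay_A − pay_B, 0) − ω·max(pay_B − pay_A, 0);
- combined: absolute inequity on both branches plus the guilt cost
  γ·τ_A·(x_A − y_A) on Defect only.

Stochastic choice is logistic in the utility difference, with an optional
temperature (scale) and intercept (bias); both default to 1 and 0, under
which the combined model's log-odds are exactly
1·Reward + γ·Guilt + α·Inequity in the design regressors
(Reward = x_B − y_B, Guilt = τ_A·(x_A − y_A),
Inequity = −(|x_A − x_B| − |y_A − y_B|)). This identity is what makes the
per-subject logistic regression structurally interpretable (β2/β1 → γ,
β3/β1 → α) and is asserted as a property test. Exact indifference in the
deterministic rule resolves to Defect, since the cooperation condition is
a strict inequality.

## Task-design generator

Designs default to 45 trials with the fixed belief schedule
{0.6: 7, 0.7: 5, 0.8: 13, 0.9: 11, 1.0: 9}; τ is stored as a fraction and
percent inputs are converted at the boundary. The actual payoff tables of
the original task are not public, so the generator draws integer payoffs
uniformly on a configurable range (default 1–20 points), ranks three
distinct draws per player to satisfy the orderings, and rejection-samples
whole candidate designs until all pairwise Pearson correlations among
(Reward, Guilt, Inequity) are below 0.30 and the guilt–inequity pair is
below 0.05 in absolute value. This reproduces the statistical structure
the downstream estimation needs — near-orthogonal psychological
regressors — not any particular payoff values. Acceptance probability per
candidate is roughly 20–25% under the defaults, so the 100,000-candidate
budget is conservative; failure (e.g. unmeetable bounds) raises, naming
the bounds. Pearson's r is used throughout (the significance-test framing
of the design checks matches the linear-correlation estimator). Designs
with fewer than 3 trials, or with a zero-variance regressor, return
flagged diagnostics instead of raising.

## Synthetic cohorts

The generator emulates the structure of a two-country online study with
cohorts of 294 (59.5% women, "KR-like") and 347 (54.8% women, "UK-like").
Defaults, chosen once as study conditions:

| quantity | default | rationale |
|---|---|---|
| γ women / men | N(0.3, 0.3) / N(0.5, 0.3), left-censored at 0 | no published preference distributions; interior cooperation rates (~0.28 vs ~0.40) and a detectable gap |
| α | N(0.15, 0.1), censored at 0 | modest inequity aversion relative to guilt |
| trait→γ slope (men only) | 0.15 per trait point | conscientiousness in UK-like, neuroticism in KR-like; sized to be detectable at n ≈ 300, as the real interactions evidently were |
| Big Five | truncated normals, mean 3, SD 0.8 on [1, 5] | BFI-10-style 1–5 scores; item-level simulation skipped |
| gender shifts | women +0.4 neuroticism, +0.3 agreeableness | the robust cross-country direction of Big Five gender differences |
| copula correlations | gender–income 0.25, income–education 0.30 | the study reports these as significant without magnitudes |
| education / income scales | ordinal 1–6 / 1–10 | invented bands; placeholders, as the real responses' scales are not published |
| age | N(40, 12), clipped to 18–79 | placeholder |
| temperature / intercept | 1 / 0 | keeps the structural identity exact |

Gender, income and education dependence is induced by a Gaussian copula
(gender by thresholding its latent at the configured quantile, ordinals
by quantile-slicing theirs). γ is left-censored rather than resampled, so
a mass of non-guilt-averse participants at γ = 0 exists by design.
Choices are simulated as independent Bernoulli draws through the
log-odds identity. The "observed" participant table never contains the
latent truth; parameter-recovery tests join the separate truth table.

What the generator does **not** emulate: dropout, inattention,
trial-order effects, within-session learning, item-level BFI-10
measurement error, realistic marginal distributions of age/SES (the real
supplementary descriptives are not available), or Player A behavior
(unused by the analyses). Passing tests therefore demonstrate that the
estimation chain recovers what this generating process encodes — not that
real populations have these parameter values.

## Per-subject estimation

Each participant's 45 choices are fit by logistic regression with the
Jeffreys-prior penalty ℓ(β) + ½·log det I(β) (Firth-type bias reduction),
which keeps estimates finite under the complete or quasi-separation that
short binary records routinely produce. The solver is Newton iteration on
the modified score X′(y − p + h(½ − p)), h the weighted hat-matrix
diagonal, with step-halving on penalized-likelihood decreases,
convergence at max-norm ≤ 1e-8, cap 100 iterations. Standard errors come
from the inverse penalized information. The intercept-only case has the
closed form p̂ = (successes + ½)/(n + 1), used as an exact oracle in the
tests; general small problems are checked against a derivative-free
maximizer of the penalized likelihood.

Model comparison: `abs` (columns 1, Reward, Guilt, Inequity; k = 4)
versus `fs` (columns 1, Reward, Guilt, disadvantageous and advantageous
inequity contrasts; k = 5). Both retain the Guilt regressor, so the
comparison isolates the inequity specification. BIC = −2ℓ + k·ln(n) with
n = trial count and ℓ the **unpenalized** log-likelihood at the
bias-reduced estimate — the choice that keeps BIC comparable across
models under standard asymptotics; a penalized variant sits behind a
flag. BIC ties select `abs` (fewer parameters). With only 45 trials the
one-parameter penalty is decisive unless the asymmetry is large: in
simulations with φ = 0.6, ω = 0.1 the `fs` model only wins the majority
of records at roughly 50 stacked design copies (~2250 trials), which is
the scale the consistency test uses.

## Group inference

**Mixed logit.** Choices are pooled per country and regressed on Reward,
Guilt, Inequity, Gender (men = 1) and Gender × Guilt with a Gaussian
random intercept per participant, integrated by non-adaptive
Gauss–Hermite quadrature (8 nodes default; estimates are stable within
1e-3 beyond 16 nodes on the scales tested). The marginal likelihood and
its analytic gradient are maximized by L-BFGS-B with log-σ bounded in
[ln 1e-6, ln 50]; standard errors come from a central-difference Hessian
of the negative marginal log-likelihood. The marginal likelihood is
verified against brute-force trapezoid integration on toy data.
McFadden's R² uses an intercept-only ordinary logistic fit as the null
(the null is not defined elsewhere; this is the package's convention, and
its values are not comparable across different nulls). Coefficients are
estimated on the raw regressor scale; the ×10³ display lives in the
reporting layer with an explicit `scale` field.

**Calibration and a known limitation.** The type-I calibration test uses
a null in which the fitted model is correctly specified: common γ = 0.4
and α = 0.15 across subjects, between-subject heterogeneity as a Gaussian
intercept (SD 0.5), no gender gap, cohorts of 80; the Gender × Guilt Wald
test then rejects at the nominal 5% (±2 points over 500 replicates).
Under subject-level *slope* heterogeneity (γ varying across subjects, as
the default cohort generator produces), a random-intercept-only model is
misspecified and the same Wald test is markedly anticonservative (~25%
at n = 40 in our measurements). This caveat applies equally to
random-intercept-only analyses of real data; random slopes are out of
scope here, so the group-level evidence for a gender gap should lean on
the participant-level β(Guilt) analyses, which do not share the problem.

**Lasso.** β(Guilt) from the `abs` subject fits is regressed on gender +
Big Five + age/education/income (9 predictors), and optionally the eight
gender × covariate products (17 predictors; raw products by default, a
centering flag exists). Predictors are standardized to unit population
variance; the objective is (1/2n)·RSS + λ‖β‖₁ with an unpenalized
intercept; the grid is 100 log-spaced values from the data-determined
λ_max down to 1e-3·λ_max; λ is chosen by seeded ten-fold CV at the
error minimum by default (one-standard-error rule behind a flag).
Coefficients are reported back on the original covariate scale. The inner
coordinate-descent solver is scikit-learn's; the tests verify the
solution independently via the KKT conditions and the single-predictor
soft-threshold closed form. Zero-variance predictors (e.g. gender columns
in a single-gender cohort) are dropped and reported.

**OLS cross-check.** The same design matrices are fit by ordinary least
squares with two-sided t-tests; rank deficiency raises an error naming
the collinear columns — the instability the penalized fit exists to
avoid, surfaced rather than papered over.

**Recovery conventions.** Group-level recovery of γ and α uses ratios of
group means (mean β2 / mean β1), in which per-subject attenuation of the
bias-reduced estimates cancels; means and medians of per-subject ratios
give the same answer within tolerance in our simulations.

## Pipeline, seeds and problem sizes

`run_full_study` runs design → cohorts → choices → per-subject fits →
BIC selection → mixed logit → Lasso (both specifications) → OLS
cross-check, per country, and writes every intermediate artifact plus a
`report.json`/`report.md` whose numbers are recomputable from those
artifacts. The master seed s derives stage seeds as s·1000 + k (k = 0
design, 1 participants, 2 choices, 3 CV folds); identical config + seed
reproduces byte-identical CSVs. Cohorts below max(folds + 1, 20)
participants get flagged "insufficient n" instead of group fits. The
events-per-variable helper implements the 10-events-per-variable floor
(17 predictors → n ≥ 170).

Simulation sizes used in the test suite — 500 subjects for recovery, 100
replicates of 300-participant cohorts for interaction power, 500
replicates of 80-participant cohorts for type-I calibration, 50 stacked
designs for BIC consistency — are chosen to make the Monte Carlo error
small relative to each check's tolerance at desk scale.

## Known limitations

- No random slopes or GEE alternatives; see the calibration caveat above.
- The FS comparison model's exact column specification in the original
  analysis is not published; both models here share the Guilt regressor.
- Whether BIC there used the penalized or unpenalized likelihood is
  unknown; both are available, unpenalized is the default.
- Education/income bands and age distributions are invented placeholders.
- Player A's decision model is out of scope (only B carries parameters).
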
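# Methods

This note documents the models, algorithmic choices and simulation design
behind `tlecortex`, including the decisions made where the underlying
methodology left the design open, and what the synthetic experiments do and
do not establish about real data.

## Data model

The unit of analysis is a subjects × features table.  Features are
(region, hemisphere, measure) triples over the 34-region Desikan–Killiany
cortical parcellation and four surface measures — cortical thickness (CTh,
mm), surface area (CSA, mm²), gray matter volume (GMV, mm³) and mean
curvature (MCu, mm⁻¹) — 68 features per measure, 272 combined.  Labels
serialize as `lh_entorhinal_CSA`-style strings using FreeSurfer region
spellings, so `aparcstats2table` exports load unmodified (with a sidecar
metadata TSV carrying group, age, sex and scanner).  Canonical feature
order is measure-major, then hemisphere (left, right), then the FreeSurfer
aparc region order; it is the final tie-break key everywhere a sort can
tie, which makes every ranking deterministic.

Loaders reject missing values by default; an opt-in flag imputes
per-feature means computed within group.  Matrices are row-per-subject;
indices are 0-based internally, 1-based in reports.  The scanner field
(1.5T/3.0T) is carried but no harmonization is applied — the dual-scanner
batch shift is treated as part of the noise a classifier must tolerate.

Subcortical volume tables (40 segmentation structures) reuse the same
generation and statistics machinery as plain DataFrames with the standard
metadata columns; the cortical table type is not forced onto them because
their labels live in a different (aseg-style) namespace.

## Statistical engines

**t filter.**  Pooled-variance two-sample t per feature, two-sided p at
n₁+n₂−2 df.  Features with zero pooled variance get p := 1.  Retention
threshold α defaults to 0.05 with no multiple-testing correction (the
analysis this package reimplements reports raw thresholds); a
Benjamini–Hochberg switch exists in the group-statistics layer.  Ordering:
ascending p, ties by descending |T|, then canonical label order.

**SCDRM.**  The objective J(W) = ‖XW − Y‖₂,₁ + λ‖W‖₂,₁ (Y one-hot, c = 2
here) is convex but nonsmooth.  It is solved by iteratively reweighted
least squares: with residual rows rᵢ and weight rows wʲ, each iteration
solves the reweighted ridge system (Xᵀ Dₐ X + λ D_b) W = Xᵀ Dₐ Y with
Dₐ = diag(1/max(‖rᵢ‖, ε)), D_b = diag(1/max(‖wʲ‖, ε)), ε = 10⁻⁸.  This is
the standard majorize–minimize scheme for ℓ₂,₁ objectives and each step
provably does not increase the ε-smoothed objective, which is what the
recorded objective trace reports.  When d > n the system is solved in the
n-dimensional dual via the push-through identity
W = diag(b) Xᵀ (X diag(b) Xᵀ + λ diag(a))⁻¹ Y, making cohort-scale fits
(d = 272, n ≈ 100) cheap.  Initialization is ridge regression with penalty
λ; convergence is declared at relative objective change < 10⁻⁶ (cap 200
iterations).  Feature score is the row norm ‖wⁱ‖₂; retained features need
score > 10⁻⁶ × max score, and a solution whose largest row norm is at the
solver floor (≤ 10⁻⁸) counts as all-zero and retains nothing.

The test suite checks the solver against an independent generic convex
minimizer (L-BFGS-B on the smoothed objective with analytic gradients, two
starts); on random small instances the IRLS objective matches the oracle
optimum to well under 1%.

λ is not a quantity the reimplemented analysis reports; it is treated as a
hyperparameter chosen inside the inner CV by the classification accuracy
of a linear SVM on the top-20 ranked features (ties to the smaller λ).
Default grid {0.001, 0.01, 0.05, 0.1, 0.5, 1.0}.

**SVM-RFE.**  Linear kernel (primal weights must exist), C fixed at 1
during elimination, step 1 by default.  Features are scored by wⱼ² and the
weakest is removed; the final ranking is reverse elimination order, and the
reported score is the elimination rank.  Ties in wⱼ² (e.g. duplicated
columns) are broken by canonical label order.  All features are "retained"
— the incremental evaluation downstream decides how many to use.  Because
libsvm accumulates kernel sums in row order, permuting subjects can swap
near-tied noise features deep in the ranking; the informative head of the
ranking is stable, and tests assert top-k stability plus rank correlation
rather than bitwise tail equality.

All three engines assume standardized inputs; the harness z-scores with
training-fold statistics (zero-variance features get SD 1).

## Evaluation harness

Outer loop: leave-one-out over subjects.  Inside each outer training set:
standardization, selector ranking, and — for each prefix size k of the
ranking — an SVM whose hyperparameters are chosen by stratified
inner-5-fold grid search (a single-candidate grid skips the inner loop; if
a class has fewer members than folds the split count shrinks, and fewer
than 2 per class is a stratification error).  The held-out subject
therefore never influences any fitted quantity; a dedicated
instrumentation test perturbs the held-out features and asserts the fold
model is unchanged.  Out-of-fold predictions pooled per k give the metrics
curve; the reported optimal k is the pooled-curve argmax with ties to the
smallest k (per-fold optima need not agree, and a single reported number
requires a convention).  Decision values (signed distance to the
hyperplane) at the optimal k, pooled across folds, feed the ROC.

Metrics are the exact confusion-matrix ratios with patients as the
positive class (LTLE is positive in LTLE–RTLE, by the convention that the
first-listed group is positive).  A zero denominator yields an explicit
"undefined" (None), never NaN.  The ROC is a threshold sweep (ties
grouped) with trapezoidal AUC; this equals the Mann–Whitney U statistic
normalized by (positives × negatives), an identity the tests verify to
10⁻¹² against `scipy.stats.mannwhitneyu`.

The default SVM grid follows the canonical LIBSVM ranges — linear and RBF
kernels, C = 2⁻⁵…2¹⁵ and γ = 2⁻¹⁵…2³, log₂-spaced with step 2.  Simulation
studies in the tests and the acceptance script use a deliberately reduced
harness (`reduced_cv_config`: linear kernel, C = 1, curve capped at
k ≤ 30, λ grid {0.01, 0.1}) so that a full leave-one-out study over a
133-subject cohort runs in seconds to minutes; with 15 planted effects the
conclusions are insensitive to the richer grid, which mainly matters near
the decision boundary of harder problems.

**Leakage policy.**  `leak_free` (default) recomputes the ranking inside
every outer fold.  `paper_compat` ranks once on the full dataset, which is
how ambiguously described published pipelines are often implemented and is
optimistically biased; the mode exists to allow that comparison and warns
loudly when used.

## Synthetic cohorts

No region-level tables from the original clinical population are publicly
deposited, so the generator emulates the study conditions: group sizes
41 (LTLE) / 34 (RTLE) / 58 (NC); per-group 1.5T scanner counts 21/18/28;
male counts 23/18/29; ages normal with the reported group means and SDs
(25.5 ± 8.2, 25.0 ± 8.5, 23.2 ± 4.1 years), floored at age 6.

Features are, per measure, multivariate normal with equicorrelation
ρ = 0.3 across the 68 regions (regional measures are correlated in real
cortices; equicorrelation is the simplest positive-definite structure and
samples in O(nd)).  Baselines are plausible natural units (CTh 2.5 ± 0.15
mm, CSA 700 ± 80 mm², GMV 2000 ± 250 mm³, MCu 0.13 ± 0.02 mm⁻¹).  Nuisance
terms, in per-measure SD units: age slope −0.01/year, male offset +0.1,
3.0T-scanner offset +0.2 — small but nonzero so that nuisance handling is
actually exercised.  Group effects are planted as Cohen's d shifts applied
to the positive group's subjects at chosen features; the default map
plants 15 effects per comparison at the features reported as most
discriminative for that contrast, |d| decaying linearly 1.5 → 0.5 with
rank, negative for CTh/CSA/GMV (atrophy) and positive for MCu.  One
integer seed drives every draw through a single generator stream.

Calibration checks: with no effects and ρ = 0 the t filter retains ≈ 5% of
features at α = 0.05 (measured 5.1% over 200 replicate cohorts); a planted
d = −3 effect reproduces its empirical standardized mean difference within
the tested ±0.15 band and tops the t ranking in at least 95% of seeds.

**What the simulations do not show.**  Real cortical data have
heteroscedastic, regionally structured covariance, non-Gaussian tails,
lateralized disease gradients and scanner-by-region interactions, none of
which the equicorrelated Gaussian model reproduces.  Passing recovery
tests therefore demonstrates that the pipeline is correct and that the
selectors behave as designed under known signal — not that the specific
accuracies quoted for any real cohort would replicate.  Notably, the
planted-effect design is "univariately matched": each informative feature
carries its own mean shift, which favours the t filter in pure recovery
counts (median 14/15 in its top 30 versus 10/15 for SVM-RFE and 8/15 for
SCDRM at cohort scale), while the multivariate selectors distribute weight
across correlated neighbours.  Classification accuracy, the quantity of
practical interest, still satisfies SVM-RFE ≥ t filter on the large
majority of seeds.

## Degenerate inputs and numerical conventions

Zero pooled variance → p := 1 (T = 0 if means equal, ±∞ otherwise).
Zero-variance features standardize with SD 1.  A selector that retains
nothing in a fold falls back to its full ranking order (so every fold
contributes a k = 1 prediction).  Single-subject training groups (which
leave-one-out creates from a 2-subject group) contribute zero to the
pooled variance.  All reported sorts carry the canonical-label final
tie-break.  Seeds derived for folds and inner splits are deterministic
functions of (config seed, fold index, k) reduced mod 2³¹−1.

## Known limitations

* Binary comparisons only; no three-class formulation.
* No scanner harmonization (ComBat-style) — the batch term is carried as
  metadata and noise, matching the reimplemented analysis.
* The ℓ₂,₁ solver assumes c ≥ 1 one-hot targets; regression-style
  continuous Y is untested territory.
* Leave-one-out with incremental evaluation is O(n · k_max) SVM fits per
  selector; the full LIBSVM grid at 272 features is computationally
  possible but intended for real analyses rather than the test suite's
  simulation sizes.
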
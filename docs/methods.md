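# Methods

## Model and procedure

The screen targets the causal chain *E → M_g → Y* per analyte *g* on a
high-throughput panel, with *E* a randomized (or conditionally randomizable)
exposure, *M_g* the analyte's (log2-scale) abundance or change, and *Y* a
numeric outcome change.  Two linear component tests are computed for every
analyte against the same designs:

- E→M: `M_g ~ 1 + E (+ covariates)`, coefficient of `E`;
- M→Y|E: the partial association of `M_g` and `Y` given `E`, fit in the
  orientation `M_g ~ 1 + Y + E (+ covariates)` (coefficient of `Y`).

The joint-significance p-value is `p_joint = max(p_EM, p_MY)` (two-sided
components).  The directional rule halves `p_joint` when the mediated
direction `sign(β_EM)·sign(β_MY)` equals the prespecified sign of the total
effect, and otherwise sets the p-value to one.  A variant mode flips the
rule for users hunting suppressors: analytes *opposing* the prespecified
direction are halved and consistent ones get p = 1.  Exactly one of the two
modes halves any given analyte (when both component estimates are nonzero);
an exactly zero component estimate is conservatively assigned p = 1 in both
modes.

Validity rests on the direction being fixed *before* seeing the mediation
data.  The screen therefore computes the total effect (`Y ~ 1 + E (+
covariates)`) and gates on agreement between its sign and the prespecified
one; the default gate refuses to run on disagreement (`error`), with `warn`
and `ignore` available — simulations use `ignore` with the generative truth.

### Why the analyte is the response in the M→Y test

Moderation borrows variance information *across analytes*, so the analyte
must be the regression response.  For the unmoderated t-statistic the two
orientations (`M ~ Y + E` vs `Y ~ M + E`) give identical t and p — both
equal the partial-correlation test — which a dedicated test verifies to
1e-10.  Under moderation the orientations genuinely differ (each analyte's
residual variance is shrunk toward the panel prior), and the
analyte-as-response orientation is the one that makes shrinkage meaningful.

## Empirical-Bayes variance moderation

Per-analyte OLS residual variances s²_g on d_g df are modeled as
s²_g ~ s₀² F(d_g, d₀), i.e. a scaled inverse-chi-square prior on σ²_g.  The
prior is fitted by moment matching on the log scale: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over the
expected sampling variance mean ψ′(d_g/2) identifies d₀ through trigamma
inversion, and the mean of e identifies s₀².  Implementation choices:

- Trigamma inversion by Newton's method with the closed-form start
  x₀ = 0.5 + 1/y; tolerance 1e-8, at most 50 iterations.
- Zero excess dispersion returns d₀ = +∞ (complete shrinkage) with s₀² set
  to the pooled mean variance.  (The log-moment estimate exp(mean(e)) is an
  alternative; the two differ by O(1/d) and are equal in the limit.)
- Fewer than two usable analytes: d₀ = 0 (no moderation), logged.
- Zero-variance analytes are dropped before prior estimation rather than
  entered as s² = 0, which would corrupt the log-moment matching; they are
  reported in the fit's exclusion list.
- No robust (outlier-winsorized) prior fitting and no variance–mean trend:
  plain moment matching only.

Moderated statistics use s²_post = (d₀s₀² + d_g s²_g)/(d₀ + d_g) on
d_g + d₀ total df, capped at the pooled residual df when d₀ = ∞; above 10⁶
df the normal reference replaces the t distribution.  d₀ = 0 reproduces the
ordinary t-test exactly (verified to 1e-12), and the implementation
reproduces limma's `lmFit`/`eBayes` output on a frozen fixture to the
printed precision.

Missing phenotype values are handled by listwise deletion per model; no
imputation.  Sample alignment between the analyte matrix and the phenotype
table is by strict id intersection with a logged report of dropped samples.

## Comparators

- **Joint significance**: unmoderated `max(p_EM, p_MY)`, no direction.
- **Simplified directional screen**: the directional rule on unmoderated
  components (for settings without a panel to moderate across; a
  single-analyte panel degenerates to this exactly).
- **Potential outcomes (quasi-Bayesian)**: for a single mediator, fit
  `m ~ e` and `y ~ m + e` by OLS, draw the two path coefficients from their
  asymptotic normal sampling distributions (≥1000 draws), and use the draws
  of the product a·b (the ACME in the linear no-interaction model) for the
  percentile CI and the two-sided tail probability of zero.  The p-value is
  floored at 1/nsim.

Benjamini–Hochberg adjustment is delegated to statsmodels with NaN
passthrough.  The 2×2 Fisher comparison of method detection counts uses the
conditional hypergeometric p (scipy), the sample odds ratio, and the
log-OR normal 95% CI with Haldane's 0.5 correction for zero cells; a paired
McNemar variant is provided (common-random-number studies make detections
paired) but the unpaired 2×2 construction is the default.

## Simulation design

One structural model serves all studies:

    M_g = a_g·E + ε_g,   Y = c′·E + Σ_g b_g·M_g + ε_Y,   ε ~ N(0, 1)

with a_g = a for mediators and exposure-only analytes (0 for nulls) and
b_g = +b / −b / 0 for consistent / inconsistent mediators / others.
Defaults and the reasons for them:

- **Effect sizes** follow the standardized small/medium/large conventions
  of the mediation-simulation literature: 0.14, 0.39, 0.59 (overridable).
- **Exposure** defaults to standard normal.  This was calibrated once
  against the reference power figures for the medium-effect n = 50 cell
  (the balanced 0/1 two-group alternative, provided as `binary-balanced`,
  implies a between-arm mean difference equal to *a* and produces far lower
  power than the standardized conventions intend) and then frozen.  The
  mediation estimators accept binary or numeric exposures for the same
  reason.
- **Direct effect** c′ defaults to a, so the total effect has a
  well-defined direction even under no mediation — the null-validity claim
  concerns known-direction totals.
- **Noise SDs** are fixed at 1 (coefficients are on the standardized
  scale); `noise_sd` rescales both analyte and outcome residuals.
- **Panels**: single-mediator studies use G = 500 (1 consistent mediator +
  499 nulls) so the moderation prior has a panel to learn from; omics
  scenarios add 200 exposure-only analytes and 1/5/25 mediators.
- **Dependence** between analytes is generated parametrically (contiguous
  equicorrelated blocks, default block size 10 with ρ = 0.5, or a low-rank
  factor structure; any user-supplied correlation root is accepted).  A
  data-derived expression-correlation structure is deliberately not
  shipped: it requires an external download and a covariate/surrogate-
  variable processing pipeline, and reference results indicate dependence
  has little effect on the conclusions.
- **Dependence applies to non-mediator residuals only.**  If a true
  mediator's residual were correlated with other analytes, those neighbours
  would carry genuine conditional association with the outcome despite
  their non-mediator truth labels, and a label-based FDR would not be a
  meaningful target for any method.  Keeping mediator residuals independent
  makes the truth labels semantically exact.
- Scenario 3 uses equal numbers of consistent and inconsistent mediators of
  equal effect (n_mediators of each).
- Seeds are mandatory everywhere; identical config + seed is bit-identical.

What the generator does *not* emulate: missingness and detection-limit
imputation, longitudinal designs, heavy-tailed or heteroscedastic analytes,
and realistic (data-derived) correlation. Passing tests therefore
demonstrate the statistical properties of the methods under a clean linear
Gaussian data-generating process, not robustness to those real-data
features.

## Monte-Carlo studies

`run_power_study` evaluates all requested methods on the same stream of
replicate datasets (common random numbers; replicate streams spawned from a
single master seed).  Power is the fraction of replicates in which the true
mediator passes the threshold rule — nominal p < α for single-panel cells,
BH FDR ≤ q over the whole panel for omics cells — or the mean per-replicate
true-positive proportion for multi-mediator panels.  For null
configurations the same quantity is the per-analyte type-I error.  Binomial
MC standard errors are always reported.  Replicate counts used here:
B = 10,000 for single-panel cells, B = 1,000 for omics scenarios, B = 2,000
for null-validity and B = 400 per cell for FDR-control checks — sizes at
which the MC error is well below the comparison tolerances.

Realized FDR uses the standard convention that a replicate with no calls
contributes 0, so the average estimates the FDR.

## Numerical and degenerate-input choices

- Rank-deficient designs and constant model terms are hard errors naming
  the offending columns; constant analytes are excluded with a warning and
  listed in the output.
- p-values are clipped to (0, 1]; an exactly zero coefficient gives t = 0,
  p = 1; total-effect estimates below 1e-10 of the outcome scale are
  reported as sign 0 (which the default gate treats as "do not run").
- Result tables are sorted by the directional p-value with the analyte id
  as a deterministic tiebreak.
- Text serialization is TSV with 10-significant-digit scientific notation;
  CSV input is accepted by delimiter sniffing; GCT 1.2 is read by skipping
  its two header lines.

## Known limitations

- Single-mediator models per analyte: no multi-mediator joint modeling, no
  latent-mediator decomposition, no confounder search, no pathway-level
  mediation.  Results on real data should be treated as exploratory.
- Mediators are tested marginally, so correlated analytes can share
  significance (see the dependence note above).
- The exposure must be numeric (binary 0/1 two-group, or a score); no
  multi-arm categorical exposures.
- The observed n = 15 FDR-level power on 500-analyte panels is essentially
  zero under the standardized medium effect size: BH detection among 500
  tests requires per-analyte p ≈ 10⁻⁴, which medium-size paths at n = 15
  (noncentrality ≈ 1.5 per component) essentially never reach.  Omics-scale
  FDR power studies are therefore only informative at larger effect sizes
  or sample sizes.
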
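# Methods

`groomnet` reconstructs, as a reusable and testable pipeline, a standard
analysis of social grooming networks in group-housed chimpanzees: scan
observations → co-presence-normalized directed grooming matrices → two
individual weighted network measures → multi-model mixed-effects
inference. This note documents the model, the defaults, the numerical
choices, and what the synthetic data do and do not establish.

## Observation model and matrix construction

The observational unit is an instantaneous scan taken every 2 minutes
during 20-minute sessions; each present individual is scored once per
scan, and only "social grooming given" enters the pipeline. For each
observation period (an interval of fixed group composition labelled
stable or unstable) the directed weight from individual *i* to *j* is

    w_ij = 100 · (scans where i groomed j) / (scans i and j co-present),

a percentage of joint opportunity. Co-presence is operationalized as
joint membership in a scan's present set. A dyad with zero co-present
scans has an undefined weight; the default refuses to build the matrix,
and an explicit "missing" policy instead drops both individuals' records
for that period.

Data-sufficiency filters mirror the study design: a period is retained
only if every member appears in ≥ 480 scans (16 h of observation) and
the observation sessions are adequately spread. The published analysis
states sessions were "evenly distributed" without a numeric rule, so the
evenness rule here is an explicit stand-in with configurable thresholds:
sessions (20-minute timestamp blocks) must fall in ≥ 50 % of the
period's calendar weeks, and the fraction of morning sessions (start
before 14:00) must lie in [0.35, 0.65].

Stability can be supplied per period (table mode) or derived from
composition events: each addition/removal/shuffle opens a 4-month
unstable window, overlapping windows merge, and the quiet gaps between
windows are stable only when they last at least 4 months. The partition
tiles the span exactly and adjacent intervals are reported unmerged so
the provenance of each label stays visible. When both a supplied label
and a classifier label exist, the supplied label wins with a warning.

## Network measures

With `s_i = Σ_j w_ij` (outgoing strength):

* **Vertex strength centrality** `VSC_i = s_i / (N − 1)` — the mean
  percent of co-present scans spent grooming a given partner,
  standardized for group size. It lives on the percent scale because the
  weights do.
* **Edge weight disparity** `Y2_i = Σ_j (w_ij / s_i)²`, bounded by
  1/(N−1) (perfectly even) and 1 (single partner). The **deviation from
  edge weight disparity** `DEWD_i = Y2_i − 1/(N−1)` shifts the lower
  bound to 0 so that groups of different size are comparable; its upper
  bound is (N−2)/(N−1). Both are undefined for non-groomers (`s_i = 0`);
  such records are dropped from the DEWD analysis rather than
  zero-filled, which is why the DEWD table has fewer rows than the VSC
  table.

A logit transform of DEWD is available for sensitivity analysis. Because
the theoretical maximum depends on group size, each value is first
rescaled by its own record's (N−2)/(N−1), then boundary-squeezed as
`y' = (y(M−1) + 0.5)/M` over the M records before `log(y'/(1−y'))`. The
untransformed DEWD remains the default response.

## Mixed models and multi-model inference

Each response (VSC or DEWD) is modelled as a Gaussian LMM with five
binary fixed factors — group-composition stability (TPstability),
arrival age category, sex, origin, and predominant housing condition
during infancy (PHCinfant) — and crossed random intercepts for
individual identity and observation time period. Reference levels
(coded 0) are stable, subadult, F, captive and with_conspecifics, so a
negative Origin coefficient means wild-caught individuals score lower.

The LMM engine is implemented in-package (`mixedlm.py`): the marginal
covariance `V = σ_e²I + σ_id²Z₁Z₁' + σ_per²Z₂Z₂'` is evaluated by dense
Cholesky factorization and the (restricted) log-likelihood is maximized
over log-variances with L-BFGS-B from two starting points (a
proportional split of the OLS residual variance, and a near-boundary
start). At the sample sizes this package meets (~119 rows, ~36
random-effect levels) each fit takes milliseconds, so no sparse or
profiled-likelihood machinery is warranted. The fitter agrees with
statsmodels' `MixedLM` (variance-component formulation of crossed
intercepts) to ~1e-6 in log-likelihood in the test suite; statsmodels is
kept as an independent cross-check rather than the implementation
because AICc bookkeeping and Satterthwaite degrees of freedom need the
parameter count and variance-component Hessian under our control.

Candidates are all 2^5 = 32 subsets of the five factors, including the
null model, fitted by **maximum likelihood** (not REML: AICc comparisons
across fixed-effect structures are only valid under ML). The source
analysis reports 33 candidates including the null model; five binary
factors yield 32 subsets, and no 33rd specification is identifiable from
the description, so this package enumerates 32. Parameter count
`k = 1 + (#fixed coefficients) + 2 random-intercept variances + 1
residual variance`, and

    AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1).

Ranking gives ΔAICc and Akaike weights over all converged candidates
(non-converged fits are dropped with a warning); ties in AICc are broken
toward fewer parameters, then enumeration order. Models with ΔAICc < 10
form the averaging subset.

**Conditional averaging**: for each term, the subset weights are
renormalized over the models containing it; the estimate is the weighted
mean and the pooled SE is `Σ w'_m √(se_m² + (θ̂_m − θ̄)²)`, which folds
between-model spread into the within-model variance. The **adjusted SE**
column first inflates each model's SE by `t_{0.975, n−k} / z_{0.975}`
(a small-sample correction; the convention behind the published column
of the same name is not documented, so this explicit choice is fixed
here) before the same pooling; z and two-sided p use the standard
normal. **RVI** per factor is the sum of Akaike weights over subset
models containing it, reported with the count of containing models.

**VIF** uses the plain 1/(1−R²) from an OLS regression of each binary
predictor on the other four; perfect collinearity is reported as
infinity rather than an error.

**Type-III tests** refit the model of interest by REML with sum-coded
(±0.5) factors, so for two-level factors each term's Wald test is the
Type-III test even in the presence of its interaction; F = t² with 1
numerator df. Denominator df follow Satterthwaite: with
`f(θ) = L(X'V(θ)⁻¹X)⁻¹L'`, `df = 2f²/(g'Ag)` where g is the numerical
gradient of f and A = 2H⁻¹ with H the numerical Hessian of the REML
deviance in the variance components (central differences; forward
differences at a variance boundary). The df is capped at the residual
rule n − p, which is also the documented fallback (flagged
`between_within` in the output) when the Hessian is singular or yields a
non-positive quadratic form. In balanced designs with vanishing
random-effect variance the machinery reproduces classical one-way ANOVA
F and df to ~1e-5.

Interaction models (e.g. Origin × PHCinfant for VSC) add one product
term to the full five-factor model and are fitted apart from the
averaging set, since the interaction inflates VIFs against its
components. The four interaction cell means are predicted at the cell's
factor combination with the remaining covariates averaged over the data
(an estimated-marginal-means convention); empty design cells are flagged
non-estimable.

## Synthetic data

No raw scan data are deposited with the source analysis, so a generator
produces datasets with the statistical structure the pipeline assumes.
Per scan, each present individual grooms with probability
`inv-logit(β0 + β'x_i + u_i + v_p)` — covariate effects plus individual
and period random intercepts — and a groomer directs the event at a
partner drawn from a per-(individual, period) preference vector sampled
from a symmetric Dirichlet. Stability acts through the concentration:
small α yields lopsided preferences, i.e. concentrated grooming and high
DEWD. This Dirichlet-multinomial mechanism is the minimal one producing
a stable/unstable DEWD contrast.

Defaults are the study conditions: 18 individuals with independent
Bernoulli(0.5) covariates; the published 18-period plan (group sizes
4–9, 7 stable / 11 unstable) at 480 scans per period, giving 119
individual-period records; activity intercept −2.2 on the logit scale
(baseline ≈ 10 % per-scan grooming probability, which puts VSC in the
low-percent range where the published intercept sits); a wild-origin
effect of −1.0 logit on activity; σ_id = 0.3 and σ_per = 0.2 (modest
intra-class correlation, chosen once as a realistic magnitude for
behavioural rates); α_stable = 5 and α_unstable = 0.8. Sessions are laid
out to satisfy the default evenness rule (alternating morning/afternoon
blocks spread across the period's weeks). Randomness is stream-split
from one master seed so the roster is invariant to the scan count.

What the generator does **not** emulate: dominance, kinship and
reciprocity dynamics, diurnal activity patterns, observational error,
and partial presence by default (all members are present at every scan,
matching whole-group outdoor sessions; a presence probability below 1 is
available for robustness checks). Passing recovery tests therefore show
that the pipeline machinery detects effects of the assumed form at the
study's scale — not that the real behavioural data meet those
assumptions.

The recovery experiment (20 replicates at the defaults) runs the entire
chain — generate, count, matrices, measures, candidate fits, ranking,
averaging — and scores sign agreement of the averaged Origin estimate,
the stable/unstable DEWD contrast, and the RVI distribution under an
all-null configuration. Problem sizes (20 replicates, 480 scans per
period, VSC response for the model-fitting arm) were chosen to hold the
full experiment to a few minutes on one core while leaving the
acceptance margins wide.

## Numerical choices and limitations

* Variances are optimized on the log scale within [e^−25, e^12];
  boundary estimates (zero variance) therefore appear as ~1e−10 and the
  `converged` flag comes from the optimizer.
* Member order within a matrix is lexicographic, making exports and
  tests deterministic.
* Half-open ISO-8601 date intervals everywhere; the stability classifier
  does calendar-month arithmetic (clamping to month ends).
* The Satterthwaite implementation supports 1-df contrasts only, which
  covers all two-level factors and their pairwise interactions; factors
  with more than two levels would need multi-df contrasts and are out of
  scope.
* The published coefficient tables cannot be reproduced numerically
  because the underlying scan records are not public; the pipeline is
  validated instead by bookkeeping against the published design tables,
  exact measure oracles, and simulation-based parameter recovery.
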
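# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `symptomnet` pipeline, in the order the stages run.

## Synthetic cohort model

The generator (`symptomnet.cohort`) is a latent Gaussian copula over the
16 GAD-7/PHQ-9 symptom items. A planted partial-correlation matrix `P`
(symmetric, zero diagonal, entries in (−1, 1)) defines the standardized
precision matrix `K = I − P`; the latent correlation matrix is the
rescaled inverse `Σ = D K⁻¹ D`. `K` must be positive definite and is
validated at construction (the offending eigenvalue is reported
otherwise). Because partial correlations are invariant to diagonal
rescaling, the round trip latent-correlation → precision → partials
reproduces `P` exactly; this is also why rank/polychoric network
estimation on the discretized items is a consistent estimator of `P`, and
hence why parameter-recovery tests against the planted truth are
meaningful.

Each latent score is cut into ordered categories by fixed per-item
thresholds. Default thresholds are solved so the marginal category
distribution is a geometric decay with the item mean equal to the
published item means of the emulated survey (GAD items 0.53–0.89, PHQ
items 0.29–1.01 on the 0–3 scale) — the right-skewed shape typical of
symptom screeners. Only the printed means are targeted; the survey's full
item marginals are unpublished, so the SDs match only approximately.

**The planted network** is a chain within each instrument plus four strong
edges: GAD2–GAD3 (0.30), PHQ1–PHQ2 (0.28), PHQ3–PHQ4 (0.26) and the
anxiety→depression bridge GAD5–PHQ8 (0.22). Chain weights are staggered
over 0.10–0.19 so that all 15 planted weights are distinct: with tied
weights the rank correlation between truth and even a perfect estimator is
bounded well below 1 (about 0.77 for a 3-valued truth over 15 edges), so a
strict planted ranking is what makes rank-recovery thresholds sharp.

**CTQ-SF trauma items** come from a separate factor model — a shared
trauma factor (loading 0.35, inducing comorbid abuse across subscales)
plus a subscale factor (loading 0.60) plus unique noise — independent of
the symptom network. One severity parameter per subscale is the *target
probability of exceeding the subscale's cut-off*; the required latent mean
shift is solved deterministically by 24-point Gauss–Hermite quadrature
over the two factors (items are conditionally independent given the
factors, so the subscale-score distribution is a 5-fold convolution) and
bisection. Defaults: sexual abuse 3.6% (the published survey prevalence),
emotional abuse 4%, physical abuse 3%, emotional neglect 6%, physical
neglect 5% — the last four are plausible moderate-severity screening rates
chosen once, as no counts are published for them. Responses are generated
already keyed; the reverse-scored item list is carried as metadata only.

**Sex structure.** Demographic covariates are drawn per sex from the
published sex-by-category proportions of the survey's CSA subsample.
Female symptom latents are shifted by +0.2 SD (males −0.1, females +0.1,
so pooled marginals stay on the calibrated thresholds), reproducing the
direction of the published sex difference in GAD-7/PHQ-9 totals. An
optional second partial matrix generates the female stratum when
sex-specific network differences are wanted; the default cohort uses a
shared network.

What the generator does **not** emulate: the strong general factor that
gives real symptom scales their high internal consistency (synthetic
Cronbach's alpha is ~0.3 against ~0.9 in real data — the planted network
is deliberately sparse); item-level response styles; any CTQ→symptom
dependence (the emulated study analyzes networks only within the screened
subsample, so none is needed); missing data (an injector exists but is off
by default, as the survey reported no missing-data handling). Passing
recovery tests therefore demonstrate estimator correctness under the
copula model, not robustness to these real-data features.

## Screening

Subscale scores are plain item sums; a participant is flagged when a
subscale meets its published moderate-severity cut-off (EA ≥ 13, PA ≥ 10,
SA ≥ 8, EN ≥ 15, PN ≥ 10). The analysis cohort keeps rows flagged for
sexual abuse and no other subscale (the comorbid-abuse exclusion).
Prevalence is the SA-flagged fraction of all retained participants — the
numerator counts rows *before* the comorbid exclusion, the accounting
under which the published 3,479/96,218 reproduces the published 3.62%.
The default interval is Wald, `100·(p̂ ± z√(p̂(1−p̂)/n))` clipped to
[0, 100], because it reproduces the published 3.50–3.73% exactly; Wilson
is available (`method="wilson"`, giving 3.50–3.74% on the same counts).
The attention-check filter takes a caller-supplied predicate, since the
survey's attention items are not published.

## Descriptives

Pearson chi-square without continuity correction (it reproduces all five
published sex-by-category statistics to two decimals; Yates would not) and
the pooled-variance two-sample t (df = n₁+n₂−2). Cronbach's alpha is
`k/(k−1)·(1 − Σσᵢ²/σ_total²)` with sample variances. Formatting follows
the survey's table: percentages to one decimal, statistics to two.

## Network estimation

Default correlation input is Spearman — computed by average-ranking each
column (a fast closed-form path for small-integer data) and taking Pearson
on the ranks — because it is robust for 4-category Likert items and cheap
enough for resampling; two-step ML polychoric (thresholds from marginal
proportions via Φ⁻¹, then per-pair likelihood maximization over the
bivariate-normal cell probabilities) is available when attenuation bias
matters, and Pearson for continuous (e.g. residualized) data. An
indefinite rank correlation matrix is projected to the nearest positive
definite correlation (eigenvalue clipping + rescaling) before fitting.

The graphical lasso penalizes off-diagonal precision entries only. The
solver (`symptomnet._glasso`) is the block coordinate-descent algorithm
(outer sweeps over columns; inner soft-threshold coordinate descent on
each column's lasso subproblem), jitted with numba and warm-started along
the penalty path; exact zeros from the soft threshold define the edge set
(an entry counts as an edge when strictly nonzero). Stationarity is
checkable via the KKT residuals `|S_ij − (Θ̂⁻¹)_ij| ≤ λ` (≈ 1e−13 at the
default tolerance). The λ path is 100 log-spaced values from
λ_max = max|S_ij| down to 0.01·λ_max (convergence tolerance 1e−4, 1000
sweep cap); resampling stages typically use 10–30 values.

EBIC selection uses γ = 0.5 (the standard conservative default for this
estimator family) and scores each fit by the *unpenalized* Gaussian MLE
restricted to the fit's sparsity pattern — the penalized likelihood biases
model-size comparison. That restricted MLE is computed by the node-wise
regression form of iterative proportional scaling (solve each node's
least-squares on its neighbors until the implied covariance matches `S`
on the allowed entries), cached by sparsity pattern along the path. The
additive Gaussian constant is omitted from all log-likelihoods (it cancels
in every comparison). EBIC ties break toward the larger penalty.

Covariate adjustment residualizes each item on an intercept plus dummy
indicators (first level dropped; aliased columns removed by pivoted QR
with a warning); the adjusted network is then estimated from the
residuals. The original-vs-adjusted comparison reports the Spearman
correlation of the 120 upper-triangle weights and an independent-sample
pooled t over the two weight vectors. Note that for *ordinal* items,
residualization breaks ties, which itself perturbs rank correlations; the
orthogonal-covariate invariance (adjustment changes nothing when
covariates are noise) therefore holds for Pearson input, and adjusted
Spearman networks should be compared against each other, not against the
unadjusted ordinal fit, when effects are small.

## Centrality

Expected influence is the one-step signed incident sum (the definition
used in this literature for networks with signed edges); bridge expected
influence restricts the sum to cross-community edges, so the decomposition
`EI = bEI + within-community sum` is exact by construction and is fuzzed
in the tests. Predictability is nodewise linear R² on the observed item
scores — a transparent approximation to mixed-model nodewise fits; for
ordinal items it understates latent-scale shared variance, and its
absolute level also scales with network density, so on the sparse planted
network it runs well below the ~50% reported for real (denser, strongly
factored) data. A singular design falls back to a small ridge with a
warning.

## Network comparison test

Observed group networks and every permuted pair are re-estimated with the
full shared estimator (correlation + EBIC-glasso path) — no shortcut
estimator inside the permutation loop. Statistics: absolute global
strength difference `|Σ|w₁| − Σ|w₂||`, maximum absolute edge difference
`M`, and per-edge absolute differences. p-values use the add-one
estimator `(1 + #{perm ≥ obs})/(1 + P)`, so they are never exactly zero;
per-edge p-values are Holm-adjusted over all 120 node pairs (the family is
every compared edge; restricting to observed-nonzero edges is possible via
the returned raw p-values). The pooled rows are put in canonical
(lexicographic) order before permuting, which makes the p-values of the
two symmetric statistics exactly invariant to relabeling the groups under
a fixed seed. Default 1000 permutations; the calibration studies in the
tests run 200 replications × 200 permutations on a 6-node subnetwork at
n = 300 per group, sizes chosen to keep the null-rejection study's tens of
thousands of re-estimations tractable while avoiding the degenerate
regime where EBIC selects empty networks and the strength statistic
becomes a point mass.

## Stability

Edge accuracy: non-parametric row bootstrap (default B = 1000; ≥ 100
required), percentile 95% CIs per edge — percentile rather than BCa, as
plain bootstrap CIs are the convention for this methodology. Edge pairs
(and expected-influence node pairs) "differ significantly" when the
percentile CI of their bootstrapped difference excludes zero. Replicates
whose estimation fails are dropped and counted; more than 5% failures
aborts. For edges whose bootstrap distribution is a point mass at zero
plus rare nonzeros, the bootstrap mean can sit marginally outside the
percentile interval; this is a property of percentile CIs, not a defect.

Case-dropping stability: for each drop proportion q in 0.05–0.75 (step
0.05), B subsamples of ⌈(1−q)n⌉ rows are drawn without replacement and
the Spearman correlation between full-sample and subsample centrality is
recorded (identical vectors count as 1.0; a constant vector as 0.0). The
CS-coefficient is the largest q whose correlations are ≥ 0.7 with
probability ≥ 0.95, 0 if none; 0.25/0.5 are applied purely as interpretive
labels (unstable / acceptable / good). Grid points leaving fewer than
p + 2 rows are skipped with a warning.

## Pipeline

`run_pipeline` executes the stages in order with sub-seeds spawned from a
single master seed via `SeedSequence`, records row counts after every
filter (mirroring the survey's participant flow), and writes a manifest
with content hashes; a rerun with the same config is byte-identical. No
timestamps enter any artifact for exactly that reason. Figures are
deliberately out of scope — network layouts are not reproducible
quantities — so exports are edge lists, TSV tables and JSON.

## Problem sizes used in the test and acceptance studies

Chosen to keep the full suite within a typical CI budget while leaving
each check statistically sharp: recovery batches of five seeds at
n = 2000 and 5000 (16 nodes, 30-λ path); type-I calibration with 200
replications × 200 permutations (6 nodes, 300/group, 10-λ path); power
with 25 seeds at 1000/group (16 nodes, Δw = 0.25 planted on the
GAD2–PHQ4 pair, whose mid-scale marginals keep discretization attenuation
moderate); CS ordering with 10 paired seeds at n = 500 vs 5000 (drop grid
0.1–0.7 step 0.1, B = 50). The analysis scripts run the full pipeline at
the survey scale (96,218 simulated participants, ~2,400 analyzed after
screening).

## Known limitations

* Polychoric estimation is O(pairs × likelihood evaluations) and is not
  the resampling default; Spearman input attenuates latent-scale weights
  (uniformly enough that rankings, centrality orderings and difference
  tests are unaffected under the copula model).
* The survey's own estimator settings (correlation input, λ grid, γ) are
  unpublished, so estimated weights are validated against planted truth
  and by internal properties, not against the published figures.
* Predictability and Cronbach's alpha levels are not comparable to
  real-data values for the reasons above (sparse planted network, no
  general factor).
* The NCT here implements the global strength, structure (M) and per-edge
  hypotheses; centrality-invariance sub-tests are not implemented.
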
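# Methods

## The censored representation of qPCR data

A qPCR reaction either crosses the fluorescence threshold at some cycle
`Ct` before the assay's maximum cycle (the *cutoff*, user-set, default 40)
or it does not. We treat threshold crossing as an event on the cycle axis
and the cutoff as administrative censoring: the event indicator is
`event = (Ct < cutoff)`, strictly — a recorded value that *meets* the
cutoff is treated as uncertain, matching the convention that undetermined
reactions are pre-coded as a number at or above the cutoff.

Normalization subtracts a reference Ct per sample. Event status is decided
on the raw Ct scale first; the observed value (or, for censored samples,
the censoring point itself) is then shifted:

```
time = min(Ct, cutoff) − normalizer_Ct
```

so a censored sample is censored at the sample-specific point
`cutoff − normalizer_Ct`. Negative normalized times are legal and left
unshifted: every downstream method (rank-based testing, partial
likelihood) is invariant to a common location shift. Multiple reference
assays combine as the arithmetic mean of their Ct values, which is the
geometric mean on the linear abundance scale since Ct is log2-scaled.

A normalizer Ct at or above the cutoff leaves the normalized censoring
point undefined; the package raises an error by default (a `drop`
policy is available and is what the simulation engine uses, where such
draws are possible in principle but vanishingly rare under the default
normalizer law).

## Two-group test

The test statistic is the Fleming–Harrington weighted log-rank sum over
distinct event times of the pooled sample,

```
T = Σ_j w_j (d_{1j} − d_j n_{1j} / n_j),   w_j = S(t_j−)^ρ (1 − S(t_j−))^γ,
```

with `S` the pooled Kaplan–Meier estimate. Internally `T` is carried in
linear-rank-score form: per-subject scores
`c_i = Σ_{t_j ≤ t_i} w_j d_j / n_j − δ_i w(t_i)` (Nelson–Aalen
orientation, as in rank-transform implementations), whose group-1 sum
equals `−T` for every labeling. The sign convention is irrelevant
two-sided and documented for one-sided use: a positive group-1 score sum
means group 1 reaches the threshold *later* (higher normalized Ct).

Inference is conditional on the observed pooled data: under the null the
group labels are exchangeable, so the null distribution of `T` is its
distribution over the `C(n, n1)` label assignments.

- **Enumeration** when `C(n, n1) ≤ 2×10⁶` (the `auto` policy): the
  p-value is the exact proportion of assignments with `|T| ≥ |T_obs|`,
  counted with a relative `1e-12` slack so float ties are included.
  Two-sided exceedance uses `|T − E[T]|` with `E[T] = 0` (centered
  scores) rather than doubling a tail, which is well defined for
  asymmetric permutation distributions.
- **Monte Carlo** otherwise: `B` sampled assignments (default 10,000;
  2,000 inside power loops) and the estimator `p = (b+1)/(B+1)`, which
  never reports zero and is itself a valid test.

Weights default to ρ = γ = 0 (the classical log-rank), the most
conventional choice; both parameters are exposed (`--rho/--gamma`)
because late-cycle-sensitive weighting (γ > 0) is natural for
low-abundance targets. With zero events overall the statistic carries no
information and the test reports p = 1 with an explicit warning flag.
Ties between censorings and events at the same time keep the censored
subjects in the risk set (the standard convention, applied consistently
in the KM estimate, the scores, and the partial likelihood).

## Semiparametric regression

The *CTOT rate* is the conditional rate of reaching the threshold at a
given cycle — the hazard on the cycle axis. The model multiplies a
common unspecified baseline rate by `exp(β x)`; `exp(β)` is the CTOT
ratio per covariate unit. β is estimated by maximizing the Cox partial
likelihood on the normalized censored data, with Efron's tie correction
by default (Breslow selectable); the two coincide exactly without tied
event times.

Numerical choices: Newton–Raphson from β = 0 with step-halving whenever
a step would decrease the likelihood; convergence when the gradient
max-norm or the relative log-likelihood change drops below `tol`
(default 1e-9), at most 25 iterations; standard errors from the inverse
negative Hessian; Wald z, two-sided p and `exp(β ± z_{α/2}·se)` CIs
(default level 95%). A monotone partial likelihood (separation) is
flagged when |β| exceeds 20 and raises an explicit non-convergence error
instead of returning a silently divergent estimate. A constant covariate
and a zero-event dataset are rejected up front.

The proportional-rate assumption (covariate effect constant over cycles)
is documented, not diagnosed — no Schoenfeld-type residual test is
computed. The public fit reports a single coefficient, matching the
one-explanatory-variable interface; the partial-likelihood core accepts
vector predictors for extensibility.

The score test at β = 0 with Breslow ties equals the log-rank chi-square
and is used as a cross-module consistency check. The identity is exact
only for untied event times: with `d_j > 1` the Breslow information
omits the hypergeometric factor `(n_j − d_j)/(n_j − 1)` that the
textbook log-rank variance includes, so the check runs on tie-free data.

## Comparators

MC imputes censored target Ct at the cutoff, CO drops censored samples,
and both then run a two-sample t-test on ΔCt (Welch by default; pooled
available, and pooled is what the commercial-tool emulation
`equal_variance_t` uses together with capping at the tool's maximum
cutoff). When CO leaves a group with fewer than two samples the analysis
is reported as *not possible* — the choosing-not-to-analyze outcome — as
an explicit error, and the power engine counts such replicates as
non-rejections while tallying them separately.

## Synthetic-data generator and what the simulations show

`gen_two_group` draws target Ct per group and normalizer Ct from
independent normal laws (an optional correlation couples them) and
leaves raw values intact so the cutoff censors downstream exactly as on
real data. Defaults emulate the layouts the package targets: 10–12
samples per group, target Ct around 30–34 cycles with sd ≈ 1–1.5,
normalizer around 20 cycles with sd 0.5 (a stable reference), cutoffs 32
or 40, 1000 replicates at two-sided α = 0.05. `gen_ph_regression` makes
the proportional-rate assumption literally true:
`T = (−ln U / (λ e^{βx}))^{1/k}` with a Weibull(k = 2, λ = 4.6e-4)
baseline placing typical crossing near cycle 30, covariate
N(0.51, 0.41²) (a hemolysis-absorbance-like reading), cutoff 40
(roughly a quarter to a third of samples censored).

Randomness discipline: one master seed; per-replicate substreams
`(seed, rep)` so every method inside a replicate sees identical data
(paired comparison); the permutation null inside a replicate uses a
further derived substream.

What the generator does *not* emulate: technical replicates and plate
effects, amplification-efficiency variation, non-normal Ct distributions
(a heavy lower tail from truly absent targets), normalizer instability,
and correlation structure among targets. Passing simulations therefore
demonstrate correctness and calibration of the *statistics* under the
stated laws, not robustness to every feature of real qPCR data.

Problem sizes used by the test suite and the acceptance script — chosen
as desk-scale defaults — are 1000 replicates for size/power (Monte-Carlo
se ≤ 1.6 power points), 500 replicates at n = 200 for parameter
recovery, 200 datasets for the enumeration-oracle equivalence check and
50 for Monte-Carlo/exact agreement at B = 99,999.

## Data interface

CSV only (RFC-4180, header row mandatory, UTF-8, 10 MB cap by default),
parsed quote-aware with hard errors on ragged rows, duplicate or empty
header names, and oversize input. Numeric coercion accepts scientific
notation and surrounding whitespace; locale decimal commas are not
supported (ambiguous in CSV). Blank required cells drop the row with a
warning and a count; any other non-numeric text in a required column is
an error — undetermined reactions must be pre-coded numerically at or
above the cutoff. Binary group labels are ordered lexicographically and
the mapping is reported; two-sided results are invariant to it.
Descriptive summaries use sample (n−1) sd/variance.

## Known limitations

- Two groups only; no stratification, frailty, or time-varying effects.
- Exact inference is conditional (permutation) — it does not extend to
  k-group or continuous-predictor settings, where the regression mode is
  the intended tool.
- The MC comparator's downstream test variant in published power figures
  is not uniquely determined; both Welch and pooled variants are
  provided, with Welch the default.
- Power figures from the simulation engine depend on the assumed
  population parameters; when a study's true parameters are unknown, the
  engine characterizes qualitative behavior (calibration, ordering of
  methods) rather than reproducing specific published percentages.
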
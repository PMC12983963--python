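# Methods

## The hierarchy and its weights

The evaluation tree has one first-level judgment matrix over the three
factor groups (B1 environmental, B2 physiological, B3 behavioral) and
one second-level matrix per group, eleven indicators in all.
Configuration documents carry only the strict upper triangle of each
matrix; the lower triangle is completed with *exact* reciprocals and a
unit diagonal. Rounded decimal reciprocals (0.33 for 1/3, 0.25 for
1/4) must never be entered: with rounded reciprocals the environmental
consistency ratio moves from 0.003 to roughly 0.077, i.e. the rounding
is far from innocuous at 3-decimal reporting precision. Fraction
strings ("1/3") are accepted and parsed exactly.

Weights use column normalization with row averaging: normalize each
column of `A` to sum 1, average the rows, renormalize. The maximum
eigenvalue is estimated as the mean of the component-wise Rayleigh
ratios `(A w)_i / w_i` under those weights. Both choices are the
classical hand-computation variants of AHP rather than the principal
eigenvector; a true eigen-solver (`ahp.principal_eigen`) ships as a
cross-check utility, and for the matrices in the shipped fixtures the
two agree to about 3 decimals in the weights. Consistency is
`CI = (λ_max − n)/(n − 1)`, `CR = CI/RI` with the standard RI table
for orders 1–10 (RI = 0 for n ≤ 2, where CR is defined as 0), and
acceptance is the strict inequality `CR < 0.10`, so a matrix at
CR = 0.094 passes and one at exactly 0.10 fails.

Total-sorting (global) weights multiply each indicator's local weight
by its group's first-level weight; the eleven global second-level
weights of any hierarchy therefore sum to 1. Weight synthesis refuses
a hierarchy containing an inconsistent matrix unless forced; loading a
configuration only *warns* about inconsistent matrices (the shipped
farmer panel's physiological matrix sits at CR ≈ 0.17, and rejecting
it at load time would make the panel's perfectly consistent first
level unusable too). `strict_consistency=True` restores hard failure.

## Fuzzy comprehensive evaluation

Memberships live on the ordered five-grade scale none < mild <
moderate < severe < extreme. Composition is the ordinary vector-matrix
product (the weighted-average operator `M(·,+)`): with row-stochastic
membership rows and sum-1 weights it is a convex combination, so the
group vector is itself a distribution over grades. Max–min composition
is available behind an operator flag for comparison but is never the
default; it discards weight mass information and is not what the
shipped worked example uses.

Two weight modes are supported and documented because field write-ups
commonly mix them. In **global mode** (the default) the second-level
composition uses *global* weights — each `W_g` sums to the group's
share rather than to 1 — and the first-level weights are applied again
at aggregation; the resulting `V` sums to less than 1 (≈ 0.43 in the
worked example, whose `W1–W3` sum to ≈ 0.55, 0.35, 0.12) and the final
normalization absorbs the double weighting. **Local mode** uses
within-group sum-1 weights at both stages and needs no
renormalization. The classification is identical in both modes for any
hierarchy-derived weights, because within each group global weights
are proportional to local ones; the worked example carries explicit
global-scale weights and is evaluated in global mode.

Maximum-membership classification breaks ties toward the more severe
grade — a welfare-conservative convention; the worked example never
hits a tie.

### Membership sources

Explicit expert-scored membership matrices (row-stochastic, validated
to sum 1 per row within 1e-9) take precedence. Absent those, each
indicator uses five trapezoidal membership functions expressed in
indicator units. The shipped default (`membership_default.yaml`) is
built from five severity-level *centers* per indicator via a
hat-function construction: adjacent levels overlap linearly between
their centers, so raw memberships sum to 1 everywhere on the domain
without renormalization, and the end levels plateau out to the domain
bounds. Decreasing center sequences mark lower-is-more-severe
indicators (temperature, standing time, respiratory rate, body size).
These breakpoints are illustrative plumbing for exercising the
pipeline on synthetic cohorts — they are not survey-derived and should
be replaced for any real assessment. Out-of-domain values raise a
domain error naming the indicator and bounds rather than silently
clipping.

## Environmental indices

THI uses the common livestock form
`(1.8T + 32) − (0.55 − 0.0055·RH)(1.8T − 26)` (T in °C, RH in %); it
is strictly increasing in T for RH < 100 and reduces to the dry-bulb
term at saturation. Alternate "modified" cold-stress forms can be
registered by name. Wind chill uses the JAG/TI formulation with wind
in km/h and the standard calm-air convention: at or below 4.8 km/h the
index is the air temperature itself, which makes the function
discontinuous at that boundary (documented, deliberate). All wind
speeds in this package are km/h throughout. THI categorization against
user-supplied cutpoints is right-open (a value equal to a cutpoint
falls in the lower bin).

## Statistics

Kendall's tau-b is implemented directly — signed pair products for
C − D, tie corrections `n1, n2` from the tied-group counts, and the
tie-adjusted normal approximation for the two-sided p-value — so it
can be verified against an O(n²) brute-force pair-counting oracle and
an independent library implementation, both of which the test suite
does. Constant series raise rather than returning NaN.

Two-group tables follow the livestock-journal convention of one pooled
SEM column per variable: `sqrt(MSE · (1/n1 + 1/n2)/2)`, which for
balanced groups is `sqrt(MSE/n)`; per-group SEMs are available behind
a flag. The default test is Student's pooled-variance t (Welch behind
a flag); significance letters a/b are assigned only at p < 0.05, with
'a' on the higher mean. Generalized linear mixed modelling of repeated
measures is out of scope here: it needs raw longitudinal data and an
estimation machinery that dedicated mixed-model packages already
provide.

## Metabolite screening

PLS-DA is fitted by NIPALS (via scikit-learn's PLS regression) on
log2-transformed (half-minimum offset for zeros), autoscaled features
against a centered 0/1 group response, 2 components by default (score
plots are conventionally two-dimensional). R2Y is in-sample explained
response variance; Q2 is its cross-validated counterpart from
stratified K-fold held-out predictions, 7 folds by default, capped at
the smaller group size. VIP is computed from the fitted unit-norm
x-weights and per-component captured response variance; the identity
`Σ vip² = n_features` is checked numerically in the tests.

The differential call requires all three criteria at once, with
*inclusive* boundaries exactly as stated: VIP ≥ 1, ratio ≥ 1.5 or
≤ 1/1.5, p ≤ 0.05. Ratios are treatment/control means on the raw
abundance scale; the treatment group defaults to the second label in
sorted order (deterministic and invariant to sample reordering) and
can be given explicitly. Per-feature p-values are Welch's t on log2
abundances by default, raw scale optionally — which scale the
convention intends is genuinely ambiguous in field practice, so both
are supported and the log2 default is declared here once. Raw spectra
processing, metabolite annotation, and pathway enrichment are out of
scope (external tools and databases).

## Synthetic data

The cohort generator encodes the study conditions as defaults: 10
calves per group for 60 days; an outdoor temperature path that
descends along a half-cosine from 1.21 °C to −26 °C (time-average
≈ −12.4 °C) plus AR(1) noise (ρ = 0.7, innovation SD 2 °C), clipped to
the printed range; RH in 71–75 %, wind in 8.4–9.4 km/h; a constant
5 °C / 75 % indoor barn. Growth starts at 35.39 ± 1.57 kg with
phase-wise average daily gains (indoor 0.76 then 0.71 kg/d, outdoor
0.66 then 1.22 kg/d, break at day 30) and a multiplicative individual
frailty (SD 0.05); body sizes interpolate the day-1/30/60 group
anchors. Behavioral indicators draw Gaussian daily noise with SD
reverse-engineered as SEM·√10 from the group summary tables (raw SDs
are unpublished); urination and defecation are Poisson counts; lying
and standing always sum to 1440 min.

What this emulates is the *marginal* group structure the analysis
assumes — means, spreads, ranges, phase trends. What it deliberately
does not emulate: within-day behavior rhythms, autocorrelated
individual behavior, weather-behavior coupling (lying time is not
driven by the simulated temperature), or thermoregulatory physiology.
Passing tests therefore demonstrate that the pipeline recovers
configured structure, not that real calves behave this way.

The metabolome generator puts Gaussian log2 noise (SD 0.5 by default)
around per-feature baselines and shifts a chosen number of spiked
features by log2 of a fold change in the outdoor group, with fold-
change magnitudes drawn from the observed differential envelope
(1.5–4.86, random direction) unless fixed explicitly; the ground-truth
spike list is returned for recovery tests. The recovery checks use a
fixed 2-fold spike at log2 SD 0.4 over 20 seeds and require ≥ 90 %
sensitivity with ≤ 5 % false positives.

## Numerical choices and degenerate inputs

- Internal arithmetic is full double precision; the 2-dp weight and
  3-dp CR rounding seen in reports is display-only.
- Reciprocity is validated to 1e-9 after exact completion; membership
  rows and weight sums to 1e-9.
- All-zero membership vectors raise a degenerate-input error at
  normalization instead of producing NaN.
- Every stochastic component takes an explicit seed; identical
  configuration and seed give byte-identical CSV output.
- Result CSVs are written with `%.17g` so floats round-trip through
  text exactly.

## Known limitations

- The two expert/farmer judgment-matrix fixtures encode single panel
  consensus matrices; aggregation of multiple raters is out of scope.
- The default trapezoid breakpoints are illustrative, not elicited.
- The farmer physiological matrix is inconsistent (CR ≈ 0.17) by this
  module's method; synthesizing farmer global weights requires the
  explicit force flag, and downstream use of that panel should be
  limited to its first level.
- Q2 depends mildly on the cross-validation fold assignment and hence
  on the random state; R2Y, VIP and the screening calls do not.
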
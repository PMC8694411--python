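# Methods

This note records the models implemented in `soilmfc`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data do and
do not establish.

## Generative model for tMFC voltage

Each terrestrial microbial fuel cell (tMFC) *i* under treatment *c* is
simulated as

    y_ij = (α + δ_c + a_i) + (β + γ_c + b_i) · t_j + ε_ij

* `α = 339.94` mV, `β = 1.73` mV/day — the control group's fixed intercept
  and slope from the published treatment-model fit (intercepts are
  interpreted at day 0; `intercept_at_day` changes the origin).
* `(δ_c, γ_c)` — treatment offsets against control, defaulting to the
  published contrasts: gasoline (−472.09, +1.65), DNT (−12.19, −0.79), urea
  (+15.7, +7.08), fertilizer (−290.22, +0.24), petroleum (−216.33, +8.31).
  These reproduce the published per-treatment lines exactly (e.g. urea
  355.64 + 8.81 t).  Gasoline's line is negative throughout the run, the
  study's observed regime for that fuel.
* `(a_i, b_i)` — one bivariate-normal draw per cell: SDs `sd_a = 60` mV,
  `sd_b = 1.7` mV/day, correlation `rho_ab = 0`, each multiplied by a
  per-treatment `variance_scale` (control 1.0, gasoline 1.19, DNT 0.71,
  urea 0.45, fertilizer 0.18, petroleum 2.02).  The scales are the ratios of
  the published within-treatment intercept SEs to control's; `sd_a` and
  `sd_b` are set so a six-replicate fit yields SEs of the magnitude the
  per-treatment tables print (SE ≈ sd/√6).  Urea/fertilizer are therefore
  the tight treatments and petroleum/gasoline the noisy ones, which drives
  the SE-ordering and confusion-structure properties downstream.
* `ε_ij ~ N(0, sd_eps²)`, `sd_eps = 7` mV — the point-to-point fluctuation
  scale of the published example trace (ten control voltages varying by
  roughly ±7 mV between readings).
* Cadence: measurements at t = 0, 1/m, …, `duration_days` with `m = 2` per
  day and 31 days, i.e. 63 points per cell and 51 inside the day 6–31
  analysis window.  (The published observation count of 210 per cell is not
  reconstructible from the stated twice-daily cadence; both the cadence and
  duration are configurable so either reading can be produced.)
* Establishment transient: before `ramp_end_day = 5` the deterministic line
  is blended linearly from `onset_level = 100` mV to the mixed-model line,
  emulating the reported rise-then-stabilise shape of early incubation.  The
  functional form is this package's choice; no published form exists.

Randomness: each series draws from a substream keyed by
`(seed, crc32(treatment), replicate)`, so adding or removing a treatment
never perturbs the other series, and a fixed seed is bitwise reproducible.

What the generator does **not** emulate: mechanistic electrochemistry
(anode colonisation kinetics, internal resistance), autocorrelated or
heteroscedastic residuals, diurnal structure, petroleum's reported
late-onset recovery, or sensor drift/outliers.  Tests passing on this
generator show the pipeline's operations are correct under the stated
statistical assumptions — not that a physical sensor achieves any particular
accuracy.

## Stability window

Traces are cut into consecutive, non-overlapping blocks of 3–6 measurements;
the OLS slope within each block (in mV per measurement interval by default,
mV/day with `per_day=True`) measures short-term drift.  The onset of
stability is the earliest block index from which, for every later block, the
fraction of replicate slopes with |slope| ≤ threshold strictly exceeds the
quorum (default 0.5, i.e. "most").  Slopes are computed per replicate by
default; a treatment-mean variant exists (`per_replicate=False`).

The operation's default threshold is the published 0.5 mV.  Note that this
figure cannot be satisfied by the published trajectories themselves: their
fitted slopes (1.73–10.04 mV/day ≈ 0.9–5.0 mV per twice-daily measurement)
exceed 0.5 even without noise, so taken literally the criterion never
declares stability.  We therefore treat the published number as a loose
summary of a unitless criterion and, when detecting the onset on default
synthetic data, use a threshold of 10 mV/measurement with 6-point blocks —
large enough to pass the post-transient slopes plus noise
(≈ 5 + 3·1.7 mV/measurement at worst) and small enough to reject the
establishment ramp (≈ 12–25 mV/measurement).  This reproduces the reported
day 5–10 onset.  Downstream analysis defaults to the fixed day 6–31 window
regardless, matching the study's choice; onset detection is the data-driven
alternative.

## Windowing and splitting

Staggering extracts every stride-1 window of w consecutive points (w = 4, 5,
6 ≈ 2, 2.5, 3 days at twice-daily sampling): a gap-free run of n points
yields n − w + 1 windows.  Windows containing a flagged missing point, or
spanning a timing gap larger than 1.5× the series' median sampling interval,
are excluded; no further edge trimming is applied.

The default split samples 20% of *windows* uniformly (|test| = round(0.2 n)),
which is faithful to the published procedure but leaks overlapping windows
between partitions.  A `replicate` mode assigns whole cells to the test set
(in seeded random order) until the window fraction first reaches the target,
for leakage-free evaluation; the two modes can be reported side by side.

## Standardization

Four schemes: `raw` (identity), `all` (one z-score over every training
value), `per_compound` (z-score per treatment), `control` (all values scaled
by the control group's mean/SD — deliberately *not* mean-0/SD-1 for treated
groups, which are expressed in units of control variability).  SDs use the
n−1 denominator (`ddof` configurable).  Parameters are fitted on the
training partition and applied to both partitions; fitting before or after
windowing is equivalent for these value-wise affine schemes because windows
are verbatim slices.

A practical note: with continuous-valued inputs, a single global affine
transform (`all`, `control`) cannot change RBF/KNN behaviour here, because
L1 distances scale uniformly and the influence-field ceiling is set as a
percentile of pairwise training distances (scale-adaptive).  The schemes
genuinely differ under `per_compound` scaling (label-dependent geometry) and
under 8-bit quantization (`quantize_8bit`), which is how the physical
chip — an integer machine — sees them.

## RCE/KNN classifier emulation

A neuron is (prototype p ∈ R^w, category c, active influence field r ∈
[min_if, max_if]).  It fires on input x when d(x, p) < r, with d the L1 norm
(the hardware's metric; L∞ available).  Confidence: Identified (all fired
neurons share one category), Uncertain (disagreement), Unknown (nothing
fired; no label is produced).

Training (RBF mode) follows the standard restricted-Coulomb-energy
procedure, since the chip's recognition semantics are documented but its
learning pass is not: presented in seeded random order, each input (i)
shrinks the field of every firing wrong-category neuron to
max(min_if, d) — fields never grow — and (ii) commits a new neuron at the
input if no correct-category neuron fired, with field clamp(distance to the
nearest different-category prototype, min_if, max_if), or max_if when no
other category exists.  Epochs repeat until a full pass makes no commitment
and no strict shrink (default cap 20).  Because min_if > 0, every committed
prototype fires on itself at distance 0, which yields the 100% Best-Match
training recall property.

Defaults: `max_if` = 95th percentile of pairwise training distances
(estimated from ≤400 sampled windows), `min_if` = 10⁻³·max_if.  The
hardware notion of "unit distance" is treated as "within the neuron's
field", not a literal 1.0.

Interpreters: Dominant (plurality of fired categories; ties broken toward
the nearest tied neuron), Best Match (nearest fired neuron), Unanimous
(Dominant, but Uncertain outcomes are re-binned to Unknown with no label),
Minimum Consensus m (Dominant's label only if its category has ≥ m fired
neurons).  KNN mode stores one neuron per training window, all neurons fire,
the k nearest vote (ties at the k-th distance broken by training order), and
Unknown is impossible by construction.  Published result tables pair the
Unanimous interpreter with nonzero "Unclear" cells in one row; by this
package's definitions Unanimous cannot emit Unclear outcomes, and that row
is treated as accuracy arithmetic only.

8-bit quantization mode (off by default; all shipped analyses use continuous
values) clips values to a configured range, maps them to integers 0–255 and
uses integer distances, for hardware-faithful runs.

## Evaluation grid

Every test classification falls in one of five bins (Correct/Incorrect ×
Identified/Unclear, plus Unknown; "Unclear" is the Uncertain bin).  General
Accuracy = 100(CI+CU)/(CI+CU+II+IU) and Identified Accuracy = 100·CI/(CI+II);
Unknowns are excluded from both denominators.  These formulas reproduce every
fully-printed published outcome row's accuracy columns within the ±0.2
rounding budget of the cells, which is the package's validation of the
denominator convention.

Filters mark (never delete) models with pct_unknown > 50 (strict) or
Identified share CI+II < 25 (strict; a per-class variant is available via
`per_class=True`).  The default grid is 3 window lengths × 4 standardizations
× ten method variants — RBF × {Dominant, Best Match, Unanimous, MC-2, MC-3}
and KNN × k ∈ {3, 4, 5, 10, 15} — 120 configurations; the published total is
120 without a stated decomposition, so this decomposition is the package's
(configurable) choice.  Within a (w, scheme) cell each method is trained once
and scored under every interpreter/k.

## Mixed-effects layer

Fitted with statsmodels' MixedLM by maximum likelihood (never REML, so LRT
and AIC/BIC comparisons across fixed-effect structures are valid):

* baseline `voltage ~ day + (1|tMFC)`;
* treatment `voltage ~ day * C(treatment)` with control reference coding,
  random intercept per cell;
* per-treatment baseline-form fits, whose SEs measure within-treatment
  variability.

The model description in the source text implies per-cell random slopes
while its operational formula has a random intercept only; the formula is
implemented as the default and `random_slope=True` provides `(day|tMFC)`.
AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln n with k counting fixed effects,
variance parameters and the residual variance.  R² follows
Nakagawa–Schielzeth: marginal = Var(Xβ)/(Var(Xβ)+Var(Zu)+σ²), conditional
adds Var(Zu) to the numerator.  The LRT statistic is 2Δℓ (clipped at 0
against round-off) on a χ² with df = parameter-count difference; fits must
share a data fingerprint and nested fixed-effect names.

Inference on fixed effects uses the normal approximation by default
(`df = ∞`, labelled).  `df_method="satterthwaite"` computes Satterthwaite
degrees of freedom for the random-intercept model from first principles:
df_j = 2(SE_j²)²/Var(SE_j²), with Var(SE_j²) = gᵀA g, where g is the
central-finite-difference gradient of [XᵀV(θ)⁻¹X]⁻¹_jj with respect to
θ = (log σ², log τ²), and A the inverse observed information of the profile
log-likelihood (2×2 finite-difference Hessian; V⁻¹ via Woodbury).  Coverage
of the resulting t-intervals is verified by simulation in the test suite.
Degenerate inputs with exactly zero residual variation (an all-zero-variance
generator) cannot be fitted by ML — the likelihood is unbounded — so the
exact OLS line is returned with zero variance components, flagged
`singular`, with NaN likelihood summaries.

End-state comparison: one-way ANOVA on each cell's final-day voltage by
treatment (F from the standard between/within decomposition; F = 0 with
p = 1 when group means coincide) and Tukey HSD pairwise contrasts
(statsmodels).  No additional multiplicity correction is layered on.

## Problem sizes and numerical choices in the shipped analyses

* Parameter-recovery runs: 20 seeds × 6 replicates per treatment at the full
  twice-daily, 31-day cadence — the estimator SD of the averaged urea slope
  is ≈ 0.07 mV/day and of the gasoline contrast ≈ 9 mV, comfortably inside
  the two-printed-SE acceptance bands (±0.82 and ±80.1).
* The LRT type-I-error simulation uses the study's 36-cell layout (6
  treatments × 6 replicates) at daily cadence with no treatment effects,
  random-intercept-only generation (`sd_b = 0`, uniform variance scales):
  500 simulations give a rejection rate near the nominal 5%.  Smaller group
  counts (9–18 cells) push the ML LRT to 6–13% — a property of the
  chi-square asymptotics, not of the implementation — and generating random
  slopes that the fitted model omits inflates rejection to ≈ 87%, which is
  why the null design matches the fitted model's covariance assumptions.
* Grid runs in tests use restricted settings lists and/or reduced generator
  designs; a full 120-model grid on the default experiment takes well under
  a minute on one CPU.
* Floating-point: CSV writers emit `repr` values and readers parse with
  round-trip-exact conversion, so series and window files are lossless.
  Classifier serialization round-trips prototypes and fields bit-exactly
  through JSON `repr` semantics.

## Known limitations

* The RCE learning pass is the standard algorithm, not a register-level
  NM500 emulation; hardware context switching, neuron capacity (576/chip)
  and degenerate-field handling are not modelled beyond `max_neurons`.
* Satterthwaite df is implemented for the random-intercept model only;
  random-slope fits fall back to the normal approximation.
* The published real-data coefficients and accuracies (e.g. the 96.6%
  flagship model) are functions of undeposited raw data; this package
  validates formula consistency and parameter recovery, and makes no claim
  to reproduce those real-data values from new measurements.
* The window-level split is kept as the faithful default despite its
  overlap leakage; replicate-level splitting is the honest alternative and
  typically scores lower.
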
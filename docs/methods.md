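# Methods

## Model

A trial is a Wiener diffusion on the evidence axis: starting at
`z = zr·a`, drifting at rate `v` with within-trial noise scale `s`,
absorbed at 0 ("new" response) or `a` ("old" response). Observed RT is
the absorption time plus a non-decision component `t0`. Across trials,
drift is Normal(`v`, `sv`), the start point Uniform with range `sz`,
and `t0` Uniform with range `st`. `s` is a free scaling constant:
multiplying `v`, `a`, `sv`, `sz` and `s` by a common factor leaves
every prediction unchanged, so all quantities are reported under
`s = 0.1` and APIs accept any `s` via `rescale_params`.

Parameter validity is enforced at construction: `a > 0`, `0 < zr < 1`,
`t0 ≥ st/2`, the start-point range strictly inside the boundaries.

## First-passage numerics

Internally parameters are standardised to a unit diffusion coefficient
(`v' = v/s`, `a' = a/s`). The lower-boundary defective density is
evaluated with both classical series expansions — the reflection
(small-time) sum and the sine (large-time) sum — switching at scaled
time `τ = t/a'² = 0.15`, near where their term counts cross; term
counts per call are chosen from the standard error bounds at an
absolute truncation tolerance of 1e-10. The upper boundary is the
reflection `v → −v`, `zr → 1 − zr`.

The defective CDF uses the termwise-integrated large-time series
(`F(t) = P_absorb − Σ_k c_k e^{−λ_k t}`); for `τ < 5e-3`, where that
series converges slowly, it falls back to 32-node Gauss–Legendre
quadrature of the density under a `t = τu²` substitution that resolves
the essential singularity at 0. Unit tests pin the CDF against direct
quadrature of the density at 1e-6.

The signed-RT predicted CDF negates lower-boundary RTs so both
response types share one axis. Trial-to-trial variability is
integrated out by deterministic quadrature — Gauss–Hermite (order 12)
over drift, Gauss–Legendre (order 8) each over start point and `t0` —
so predictions are smooth, reproducible and collapse exactly to the
no-variability case when the ranges are 0.

## Trial sampling

The default sampler inverts the model's own signed-RT CDF on a dense
grid (4096 points per response side, spanning the support until the
slowest series mode has decayed below ~1e-9), so simulated data agree
with the predicted distributions by construction. An independent
Euler–Maruyama path simulator (`Δt = 1e-4 s`, trial-level parameter
draws) exists purely as an oracle: tests require the closed-form
absorption probability and the predicted CDFs to match its output
within Monte-Carlo error, which guards both implementations against a
shared mistake. All sampling requires an explicit seeded generator;
nothing draws from global state.

## Synthetic studies

Three generators emulate standard recognition-memory designs with a
4-s response deadline (slow trials are flagged censored, then removed
by the 300/4000-ms trim together with anticipations):

- **exp1 — test composition, targets `zr`.** Two groups of 30; 140 old
  + 70 new test trials (old-bias) vs 70 + 140 (new-bias). Group-mean
  truths follow published distribution-level estimates for this
  manipulation: `zr` 0.66 vs 0.49, `a` 0.14 vs 0.13, `v_old`
  +0.04/+0.05, `v_new` −0.14.
- **exp2 — speed vs accuracy feedback, targets `a`.** Two groups of
  30, 140 + 140 trials; `a` 0.09 vs 0.17, `t0` 0.54 vs 0.67, `v_new`
  −0.17 vs −0.09, `v_old` +0.04/+0.05. The speed-condition deadline
  feedback followed the response, so it is modelled only through the
  parameter differences, not by censoring at 1 s.
- **exp3 — presentation frequency (within subject), targets `v`.**
  Three conditions of 90 trials (not presented / once / twice); drift
  magnitudes 0.19 (toward "new"), 0.03, 0.13, generated under the
  closed-form estimator's assumptions (`zr = 0.5`, no across-trial
  variability) with 26 participants.

Values never reported for these designs are package defaults, chosen
once as plausible for deadline-paced recognition and config-overridable:
exp1 `t0 = 0.6 s`; exp2 `zr = 0.55` (both groups were old-biased, no
mean printed); exp3 `a = 0.12`, `t0 = 0.55 s`; unreported
between-participant SDs default to 0.08. Recovery of a targeted
parameter is insensitive to these choices. Two printed drift-rate SDs
for the speed/accuracy study (0.83, 0.56, 0.76) are an order of
magnitude out of scale with every neighbouring value under `s = 0.1`
and are treated as misprints for ≈0.08/0.06/0.08.

Between-participant heterogeneity is Normal around the group mean,
truncated to the valid region by rejection; shared parameters (`a`,
`zr`, `t0`) are drawn once per participant, drift rates independently
per condition and stimulus class (within-participant parameter
correlations are not modelled — they are not reported for such
designs and nothing here asserts them). With all SDs at 0 every
participant shares the generating truth, which is the configuration
the recovery scenarios use.

What the generator does **not** emulate: stimulus-level variation
(word concreteness, picture category), primacy/recency structure,
sequential effects such as post-error slowing, feedback dynamics
within the test phase, and contaminant RTs. Passing recovery tests
therefore show that the estimators invert the model under its own
assumptions at realistic trial counts — not that real data satisfy
those assumptions.

## Estimators

**EZ (closed form).** Responses are accuracy-coded (response matches
stimulus class). With `Pc` the proportion correct, `L = logit(Pc)` and
`VRT` the correct-RT variance:

    v  = sign(Pc − ½) · s · [L(L·Pc² − L·Pc + Pc − ½)/VRT]^¼
    a  = s²L / v
    t0 = MRT − (a/2v)·(1 − e^y)/(1 + e^y),  y = −va/s²

`zr` is fixed at 0.5 and variability at 0. The inversion is exact
under those assumptions; a unit test verifies the round trip on
analytic moments to 1e-4. `Pc ∈ {0, ½, 1}` is an error by default (the
screening convention is to drop such condition fits); an optional edge
correction substitutes `1 − 1/(2n)`.

**KS.** Per stimulus class, `T` is the supremum distance between the
empirical signed-RT CDF and the model's predicted signed CDF,
evaluated on both sides of every ECDF jump. The per-class p-value is
the asymptotic Kolmogorov law at that class's `n` (no small-sample
correction); classes combine by multiplying p-values — the combination
rule is not dictated by the statistic itself, and the product mirrors
how multi-distribution fits are scored in the program this back-end
emulates. The fitter minimises `−Σ log p`. Because `p` saturates at 1
in double precision exactly where good fits live, `log p` is computed
as `log1p(−CDF)` with the small-`x` series of the Kolmogorov CDF,
keeping the objective strictly monotone in `T` everywhere.

**Chi-square.** Per response within a class, observed RTs are binned
at their 0.1/0.3/0.5/0.7/0.9 quantiles (six bins per response, twelve
per class — the toolbox convention this mirrors does not print its
exact defaults; this interpretation is documented rather than claimed
as the original's). Expected counts come from the predicted signed
CDF; adjacent bins collapse until every expected count is ≥ 1, keeping
the statistic defined for participants with very few errors, and a
response type with fewer than 11 trials triggers a warning (unstable
quantile edges), not an error. `df = bins − classes − free parameters`
(clamped at 1).

**Optimisation.** KS and chi-square fits run Nelder–Mead in a
transformed unconstrained space (log for `a`, `t0` and the variability
ranges, logit for `zr`), started from EZ-derived values with the start
point seeded by inverting the closed-form absorption probability at
the observed "old"-response proportion. Drift and start point trade
off along a curved valley with genuinely separated local minima (a
moment-based start absorbs start-point bias into the drift), so the
search is staged: a pilot phase runs short simplex searches from five
`zr` offsets (±1.2, ±0.6, 0 on the logit scale) and promotes the best
two candidates; full runs then start from the seed point, those
candidates, and two random perturbations (SD 0.35, fixed internal
seed — fits are deterministic), with a final polish from the incumbent
at `xatol = 2e-4`. Convergence uses `xatol = 1e-3`, `fatol = 1e-6`.
On benchmark data this search matches or beats oracle starts (the
generating truth) in ~29/30 fits. Estimating `sv/sz/st` (the
eight-parameter single-condition model) is supported but off by
default in recovery runs, which both generate and fit with the ranges
at 0.

**Design matrices and restricted fits.** Each parameter is shared
across conditions or free per condition; drift is additionally split
by stimulus class. A "shared" drift means shared per class (old-item
and new-item drifts stay distinct), which keeps restricted models
psychologically sensible in multi-condition designs. `restricted_fit`
frees exactly one of `v/a/zr/t0` across conditions — the tool for
asking which single parameter explains a within-subject manipulation.

## Screening and group inference

A participant whose fit statistic rejects the model at p ≤ 0.05 is
flagged `screened` and excluded from group analyses for that fit only
(an option mirrors the stricter drop-from-all-conditions rule some
toolboxes force). Between-group comparisons use Student's t, switching
to Welch when a Levene pretest rejects variance homogeneity at 0.05 —
reporting conventions in this literature mix integer and fractional
dfs without stating a rule, so the pretest is this package's explicit
one. Within-subject parameters get a one-way repeated-measures ANOVA
(via pingouin) with Greenhouse–Geisser-corrected dfs when a sphericity
pretest rejects at 0.05 (no Huynh–Feldt), partial eta squared as the
effect size, and ordered Helmert contrasts (level 1 vs the mean of
later levels, then successive). Cohen's d uses the pooled SD. d′ and c
use the 1/(2N) correction for extreme rates. No multiple-testing
correction is applied across parameters (α = 0.05 throughout), and
`binomial_exceedance(n, k, α)` quantifies how many significant fit
rejections chance alone would produce.

## Recovery and validation harnesses

`recovery_experiment` simulates a named scenario (all participants at
the generating truth, dispersion 0), trims, fits, screens, and reports
per-parameter mean/SD/bias/RMSE. The bundled scenarios reproduce each
study's conditions at the published group-mean estimates; the
distribution-level scenarios use 30 participants × 210–280 trials, the
closed-form ones 26 × 90.

`run_validation` generates a study in which *only* the targeted
parameter differs between groups or conditions (non-target parameters
pooled across cells, heterogeneity at the reported spreads), fits
every participant, and checks that the manipulated parameter carries
the largest standardized effect (|d| between groups, partial eta
squared within). The test suite asserts this for seeds 1–5 at reduced
sizes (12 per group for the between-subject designs with one random
restart, 20 participants within); the reduced sizes keep the full
suite a few minutes long while leaving the target effects (d ≈ 1.8,
η²p ≈ 0.3) far above noise level.

## Known limitations

- The drift criterion (a zero-point shift of drift) is out of scope,
  as is maximum-likelihood and hierarchical/Bayesian estimation.
- The asymptotic Kolmogorov p is conservative at small per-class n;
  screening rates inherit that.
- EZ's edge cases (perfect or chance accuracy) are excluded rather
  than corrected by default, matching the screening convention; with
  90-trial conditions at the bundled drift values they are rare.
- Near-flat KS objectives mean individual estimates can wander within
  a p ≈ 1 plateau; group means remain accurate (the recovery suites
  quantify exactly how accurate). In those suites the KS back-end
  shows a small downward tendency in recovered start points at ~200
  trials per participant — on the order of a few percent of the value,
  comparable to its Monte-Carlo standard error — while boundary
  separation, non-decision time and drift recover without measurable
  bias.
- The one printed quantity this package knowingly cannot reconcile is
  a reported binomial exceedance of 0.19 for 1 rejection in 60 tests
  at α = 0.05; the formula gives 1 − 0.95⁶⁰ ≈ 0.954, and the α that
  would yield 0.19 is not recoverable. The formula, not the printed
  number, is implemented and tested.
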
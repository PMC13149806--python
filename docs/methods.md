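# Methods

`driftspread` implements a simulation-and-analysis pipeline for studying
choice-induced preference change — the *spreading of alternatives* (SoA) —
under sequential-sampling models of value-based choice. This note documents
the models, the synthetic cohort that stands in for experimental ratings,
the numerical choices, and the limits of what the tests demonstrate.

## Models

All three models accumulate noisy evidence for option 1 over option 2 in
1 ms steps until the net evidence reaches an absorbing bound `±θ`; the sign
at absorption gives the choice and the crossing step `T` gives the response
time, `RT = T/1000 + NDT`, with the non-decision time `NDT` (s) covering
encoding and motor latency.

* **DDM** — per-step increment of net evidence `δ·(μ1 − μ2) + ε`, with `μ_i`
  the overall value ratings and `δ` a per-participant drift efficiency.
* **maDDM** — one stream per attribute `a` (here pleasure P and nutrition
  N): increments `δ^a·(μ1^a − μ2^a) + ε^a`; the streams sum into the net
  accumulator.
* **stDDM** — the maDDM with per-attribute onset latencies `s^a` (s): a
  stream contributes nothing before its onset.

Noise `ε ~ N(0, σ²)` with `σ² = 0.5` per option-stream per 1 ms step, drawn
independently per option and per attribute. Only differences matter for
stopping and readout, so the implementation integrates each attribute's
*difference* process directly (variance `2σ²` per stream per step, `2nσ²`
for the net process with `n` attributes); this is distributionally
identical to simulating the options separately and halves the draws. A
literal reading in which the two options share one noise draw would cancel
in the difference and freeze the process, so it is not used. Before an
attribute's onset in the stDDM, its noise is silenced along with its drift
(a `pre_onset="noise"` flag switches to noise-only-before-onset).

Trials are capped at 10,000 steps (10 s, the trial-exclusion ceiling);
capped trials are flagged non-terminated and excluded downstream. The cap
is an argument, and oracle comparisons lift it because the closed forms
describe the uncensored process.

## Spreading-of-alternatives readout

After a choice, the accumulator state defines an inferred value difference
`dV_T = E/(drift·T)` and the spread is `SoA = C·(dV_T − dV)` with `C = +1`
if option 1 was chosen and `−1` otherwise, i.e. chosen-minus-rejected. For
multi-attribute models "drift" is a vector and the readout is genuinely
open; two readouts are provided:

* **net** (default): `dV_T = E/((Σ_a δ^a)·T)`. Net evidence weights
  attributes by drift shares `δ^a/Σδ`, while the anticipated `dV` weights
  them by the rating weights `w_a`; when deliberation weights attributes
  differently from stated ratings (snack choices notoriously overweight
  taste), the inferred value tilts toward the deliberation-dominant
  attribute, and the tilt grows with attribute disparity. This is the
  mechanism that produces a positive disparity→SoA relationship in the
  attribute-aware models and none in the value-only DDM.
* **per_attribute**: infer `dμ̂^a = E^a/(δ^a·T_a)` per attribute (`T_a`
  shortened by the onset under the stDDM; an attribute with `T_a = 0`
  contributes its anticipated difference — nothing accumulated, nothing
  spreads) and recombine with the rating weights. This readout is unbiased
  for the rating-scale value difference and preserves the noise-free
  identity `dV_T = dV` exactly — and for the same reason it cancels the
  drift-vs-rating mismatch and produces no systematic disparity effect. It
  is retained as an option and for the noise-free identity tests.

`dV_T` is not clipped or winsorised by default.

## Derived quantities and exclusions

Per-participant attribute weights come from OLS of V on (P, N) with an
intercept (ratings need not pass through the origin). Disparity follows the
iso-value projection: `D = |(Δattr)·[−w_P, w_N]| / ‖[−w_P, w_N]‖`, symmetric
in the pair and invariant to jointly rescaling the weights. Negative
estimated weights pass through but are flagged, since the geometry presumes
positive marginal rates of substitution.

Trials with RT < 0.5 s or > 10 s are excluded (boundary values retained —
strict inequalities). Participants whose logistic slope of choice on dV is
below 1 are screened out; complete separation keeps the participant (a
perfectly consistent responder is the opposite of a noisy one) with a
logged warning.

## Synthetic cohort

No experimental ratings ship with the package, so a generator emulates the
free-choice-paradigm structure: per participant, `n_options` snack-like
options rated for P, N (uniform marginals on [0, 1] via a Gaussian copula,
cross-option correlation −0.3 by default — tastier foods tend to be rated
less nutritious) and overall value `V = clip(w_P·P + w_N·N + η, 0, 1)` with
`η ~ N(0, 0.1)` and participant weights `w_P ≈ 0.6 ± 0.15`,
`w_N ≈ 0.4 ± 0.15` (taste dominates stated value). Options are paired by a
uniformly random perfect matching, each option in exactly one pair; the
defaults (50 participants × 120 options → 60 trials) give a median |dV|
near 0.2 on the unit rating scale.

True accumulator parameters are drawn from truncated normal hyperpriors,
calibrated once so that the simulated study reproduces the empirically
reported bands for consistency and median RT by difficulty
(roughly 65–95% and 2–3 s):

| parameter | DDM | maDDM/stDDM | units |
|---|---|---|---|
| drift δ | 0.065 ± 0.013 | δ_P 0.045 ± 0.011, δ_N 0.019 ± 0.0095 | evidence/ms per value unit |
| threshold θ | 65 ± 11 | 90 ± 15 | evidence units |
| NDT | 0.4 ± 0.1 | same | s |
| onset s_N | — | 0.3 ± 0.15 (s_P = 0) | s |

The multi-attribute threshold is ~√2 larger because the two-stream
difference process has twice the noise variance; parameters are
model-specific, as they would be when each model is fitted separately to
the same data. Drift weights tilt toward pleasure (share ≈ 0.7) more than
the rating weights do (share ≈ 0.6), reflecting the attribute-timing
literature in which in-the-moment choices overweight the immediately
gratifying attribute relative to stated evaluations; this drift-vs-rating
mismatch, heterogeneous across participants, is what powers the disparity
effect under the net readout.

What the generator does **not** emulate: real rating distributions
(unknown; no public data), option-identity effects, session/order effects,
post-choice rating noise, or any cognitive model of how isolated ratings
arise. Passing tests therefore demonstrate internal consistency of the
models, estimators and analyses under plausible conditions — not fidelity
to any particular empirical cohort.

## Likelihood and fitting

Choices and RTs are fitted per participant by MAP with a Laplace
(curvature) covariance at the mode — a deliberate, self-contained
replacement for variational toolbox machinery, since the downstream use is
point estimates. Priors are Gaussian on transformed parameters (log for
`δ`, `θ` with natural-scale centre 1; logit for NDT and onsets with centre
0.4), SD 1 on the transformed scale (configurable); `σ² = 0.5` stays fixed
to pin the evidence scale.

For constant-drift models the RT likelihood is the analytic Wiener
first-passage density at the chosen boundary, evaluated by the standard
small-time/large-time series (switch at normalised time 0.15, 10 terms —
far below 1e−10 truncation error in this regime) with the drift entering
as an exponential tilt computed in log space. Decision time is
`RT − NDT` in ms; trials with `RT ≤ NDT` contribute a finite floor penalty
(log 1e−12) instead of −∞. Because fitted data have passed the RT window,
the likelihood is by default *conditioned on the 0.5–10 s window*
(normaliser by 400-point trapezoid); without this correction NDT is
systematically overestimated by ≈ 0.09 s and θ underestimated. Residual
biases from ignoring the 10 s simulation cap are small (NDT median
absolute error ≈ 0.05 s at 200 trials).

The stDDM has piecewise-constant drift, so its first-passage distribution
is propagated on a space–time grid: cell masses on the interval between the
barriers, per-step transitions by exact Gaussian cell integrals (columns
sum to one analytically, so mass is conserved to float precision), one
transition matrix per drift/variance regime. Because the grid monitors the
boundary only at discrete times, the barrier is pulled inward by
`0.5826·σ·√dt` (Siegmund / Broadie–Glasserman–Kou continuity correction);
with the defaults (dt = 0.25 ms, dx = 0.075) the zero-onset solution
matches the analytic density within ~3×10⁻⁴ s⁻¹ sup-norm. The dominant
spatial error scales as dx²·(steps), so refining dt without refining dx
can *increase* error. Grid likelihood evaluations are much slower than the
analytic path; stDDM fitting is provided but not recommended at cohort
scale.

A note on the 1 ms simulator vs continuous-time oracles: the discrete walk
overshoots the barrier, which inflates mean decision times by roughly
`(1 + 0.5826·σ_step/θ)² − 1` (≈ 1.3% at θ = 90, ≈ 2.6% at θ = 45).
Oracle-equivalence checks therefore run at θ = 90, inside the continuum
regime where the closed forms are claimed.

## Statistical analyses

Mixed-effects regressions per the study design: `SoA ~ |dV| + D` and
`log(RT) ~ |dV| + SoA` as linear mixed models with random intercepts and
slopes by participant (REML; on convergence failure the model falls back to
random intercepts, then to cluster-robust pooled OLS, each logged);
choice ~ dV as a binomial mixed model with logit link via the variational
Bayes GLMM (posterior means/SDs reported as coefficients/SEs; its
initialisation draws from the global RNG, which is pinned for byte-stable
reports), with a cluster-robust GLM fallback under separation. CIs are
`coef ± 1.96·SE`; p-values are reported per coefficient without
multiple-testing correction (a flag exists, off by default).

Median splits of |dV| are pooled across trials (ties to "easy"); RT cells
are summarised by medians, consistency and SoA by means. Quantile-bin
tables use 5 bins by default, with edges from the reference distribution and within-bin median splits.

### Power at desk scale

At 50 × 60 the |dV|→SoA (negative) and SoA→log RT (negative) fixed effects
are decisively signed for all three models across seeds. The disparity→SoA
effect in the attribute-aware models is positive in nearly all runs
(typical coefficient +0.05…+0.20) but its 95% CI excludes zero only
intermittently: the empirical literature this design mirrors rests on cohorts of
several hundred participants, with roughly an order of magnitude more
trials and correspondingly tighter CIs.
The acceptance test asserts the CI criterion at the canonical seed and
documents this as a power limitation rather than adjusting conditions.

## Determinism

One top-level seed feeds named substreams (attributes, weights, rating
noise, pairing, true parameters, per-model trial streams, fit starts).
Reports are written with fixed float formatting and sorted JSON keys;
rerunning the pipeline with the same config yields byte-identical tables.

## Known limitations

* stDDM likelihood is grid-based and slow; no analytic FPT for
  time-varying drift is attempted.
* The RT-window truncation correction is applied for ddm/maddm fits but
  not the stDDM grid likelihood.
* No hierarchical (group-level) estimation and no formal model comparison.
* No starting-point bias, collapsing bounds, or inter-trial variability.
* No model of isolated (pre/post) rating production; spread is read out
  from the accumulator, not from simulated post-choice ratings.
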
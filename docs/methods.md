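# Methods

This note documents the models, algorithms and design choices behind
`cowjbt`: what is computed, under which assumptions, and where the
numerically delicate decisions lie.

## Experiment schedule

The design is fixed: 8 training sessions, testing period 1 (2 sessions),
3 wash-out sessions of regular training, testing period 2 (2 sessions);
every session has 7 trials of at most 90 s.

Training sessions draw their cue order uniformly (seeded) from the set of
admissible sequences — first trial P, second N, last P, no cue three times
in a row, composition 4 P / 3 N. Brute-force enumeration shows exactly
five such sequences (PNPPNNP, PNPNPNP, PNPNNPP, PNNPPNP, PNNPNPP); the
test suite re-derives this set independently. The 4 P / 3 N composition
is itself a design choice: the constraints plus the canonical worked
sequence imply it, but it is not forced by the ordering rules alone.
Testing sessions are fixed as `[P, N, a1, a2, a3, N, P]` with the
ambiguous block Ap/An/A in period 1 and A/Ap/An in period 2; each period
therefore shows each ambiguous cue exactly twice, and the
reference-to-ambiguous trial ratio within a testing session is 4:3.

## The cow agent

Each synthetic cow carries two Gaussian generalisation gradients on the
normalised cue axis (P at x = 0, N at x = 1, cues 0.25 apart ≙ 1.6 m):

* net approach tendency
  `T(x) = V_P exp(−x²/2σ_P²) − V_N exp(−(x−1)²/2σ_N²)`;
* Go decision with probability `logistic(β_dec (T − θ))`;
* Go latency `L0 − k_lat·T + N(0, sd_lat)`, clipped below at 1 s; a draw
  reaching the 90 s ceiling means the cow did not arrive in time and is
  recorded as a NoGo at exactly 90 s, so the censoring invariant
  (NoGo ⇔ latency = 90) holds by construction.

Learning is session-level: every punished approach to N multiplies `V_N`
by `1 + η_V`, and each completed training or wash-out session shrinks
both gradient widths by `1 − η_σ` down to a floor. Ambiguous cues are
never reinforced and trigger no update; testing sessions leave the agent
unchanged. Because both gradients are monotone on [0, 1], `T` is strictly
decreasing in x for every parameter setting, which yields the monotone
graded latency profile a valid JBT expects.

### Punisher presets

The committed presets (`default_presets()`) were calibrated once by a
coarse search and then frozen; all knobs are plain dataclass fields.
Shared baseline: σ_P = 0.45, V_P = 1, β_dec = 5, θ = 0.05, L0 = 21 s,
k_lat = 14 s per tendency unit, sd_lat = 5 s, η_σ = 0.04, σ floor 0.35.
Arms differ in the aversive gradient: NOTH starts at V_N = 0.06 with a
slow learning rate (η_V = 0.10) — aversion stays weak, the approach
response remains invigorated and NoGo-to-N learning is the bottleneck;
AIR (V_N = 0.10, η_V = 0.18) ends roughly balanced; ELEC starts at
V_N = 0.30 with η_V = 0.70, a wide σ_N = 0.60 and **no** gradient
sharpening (η_σ = 0), the coarse-discrimination-under-severe-threat
mechanism that produces peak-shift-like suppression spreading toward P.
Between-cow heterogeneity is Gaussian multiplicative jitter (CV 0.25,
0.30 for ELEC) on widths, saliences and η_V (clipped below 0.95 to keep
the learning rate in [0, 1)).

At 200 cows per arm these presets give trained fractions of about
71% / 89% / 96% (NOTH/AIR/ELEC; 85% overall), overall NoGo rates ordered
NOTH < AIR < ELEC (≈ 0.31 / 0.35 / 0.46), NoGo-at-P highest under ELEC
and lowest under AIR, and mean SA larger under ELEC than under AIR.

What the generator does **not** emulate: arena geometry beyond the 1-D
cue axis, within-session fatigue or satiation, carry-over of affect
between sessions, and any quantitative latency distribution per cue — no
such distributions are published, so simulator realism is judged only on
directions and orderings. Tests passing on simulated cohorts therefore
show that the pipeline recovers the structure the generator plants, not
that real cows behave this way.

## Scores

* Remaining latency `1 − latency/90` maps (0, 90] onto [0, 1); NoGo → 0.
* Correct responses: Go within 20 s at P; NoGo at N. Ambiguous trials are
  never scored.
* Learning speed: 1-based index of the second session of the earliest
  consecutive pair with ≥ 13 correct of 14; 9 when never reached.
* Adjusted latency: per cow and testing period, latencies are averaged
  per cue over the period's two sessions (NoGo trials enter at 90 s, the
  value they are recorded with) and rescaled so P ↦ 0, N ↦ 1. Values
  outside [0, 1] are legitimate (e.g. An above 1 when a cow keeps
  approaching N). A cow whose mean N latency does not exceed its mean P
  latency cannot be rescaled; it is excluded from validity/sensitivity
  with a logged reason rather than silently dropped.
* Signed area: the observed curve is piecewise linear through (0, 0),
  (0.25, v_Ap), (0.5, v_A), (0.75, v_An), (1, 1) — the endpoints are
  exact because adjusted means at P and N are 0 and 1 by construction,
  so area accrues only over the ambiguous region. Each segment of the
  difference from the identity baseline is split at its sign crossing and
  integrated by the trapezoid rule (exact for piecewise-linear input).
  `SA = +A⁺ if A⁺ ≥ A⁻ else −A⁻`; the tie takes the positive branch. The
  sign convention makes positive SA pessimistic, matching the reading
  that a negative SA indicates a punisher-driven positive bias. (A
  literal `sign(max(A⁺,A⁻))·max(A⁺,A⁻)` is degenerate — the sign of a
  nonnegative maximum is never negative — so the dominant-area reading is
  the only one consistent with that interpretation.)

## Exact nonparametric tests

Signed-rank and rank-sum tests compute exact two-sided p-values
(`2·min(P(T ≤ t), P(T ≥ t))`, capped at 1) by dynamic programming over
the observed mid-ranks doubled to integers, which enumerates the full
conditional null distribution even under ties. Thresholds (n ≤ 15
signed-rank, combined n ≤ 16 rank-sum, n ≤ 8 Spearman) keep every
analysis at the study's group sizes exact; larger samples fall back to
tie-corrected normal (or t) approximations. Zero differences are dropped
before ranking (the conventional treatment). Degenerate inputs —
all-zero differences, zero-variance vectors — return an explicitly
flagged undefined result.

The Freeman–Halton test enumerates all tables with the observed margins
recursively and sums the probabilities of tables no more probable than
the observed one; empty rows/columns are dropped first, and a table left
with a single row or column has exactly one configuration (p = 1). The
Friedman statistic delegates to scipy after explicit complete-block
handling (incomplete blocks dropped with a warning; an all-tied layout
returns χ² = 0, p = 1, which scipy's tie correction cannot represent).

Type-I error of the exact tests at α = 0.05 is verified by simulation
(10,000 null replicates at the study's sample sizes) to lie in
[0.03, 0.07] — exact rank tests are conservative at these n because of
the discreteness of their null distributions.

## Mixed models

Both trial-level models are fitted by maximising the Laplace-approximated
marginal likelihood. Random intercepts are independent Gaussians per
grouping factor; "sessions within cows within groups" is coded as three
independent intercept factors (group, cow, cow-session), the standard
nesting-by-coding construction. The inner problem (joint random-effect
mode) is solved by damped Fisher scoring — the expected information is
positive definite for both families, and for a single grouping factor it
is diagonal, giving a fast vectorised path used heavily by the
parameter-recovery simulations. The outer optimisation (fixed effects,
log σ per factor, log φ for the beta family) uses L-BFGS-B with
finite-difference gradients and warm-started inner modes; σ is bounded
below at e⁻⁸ and estimates under 10⁻³ are reported as boundary zeros
(variance components genuinely at zero pile at this boundary, roughly
half the replicates under a zero-variance truth, as theory predicts).

The hurdle model factorises exactly: the NoGo indicator's Bernoulli
likelihood and the positive part's beta likelihood share no parameters,
so the two parts are fitted separately and their log-likelihoods add.
Remaining latencies within 10⁻⁶ of the open-interval bounds are clipped
before the beta density (a response of exactly 1 — a 0 s approach — is
physically impossible). The NoGo part omits the punisher × cue
interaction by default (it is restorable via configuration); the positive
part and the binary correct-response model include it.

Fixed-effect covariance comes from the numerically differentiated
observed information of the outer objective, so the reported standard
errors account for variance-parameter uncertainty. Wald tests are
`b' V⁻¹ b` on a term's coefficient block with df = block size. Estimated
marginal means average the linear predictor over the other fixed factors'
levels with equal weights (the weighting is a choice; no observed-margin
weighting is attempted); pairwise contrasts are reported as logit
differences and odds ratios with 95% Wald CIs, Bonferroni-adjusted over
the contrast family. Inference uses normal/χ² references throughout; no
residual-df convention is claimed.

During development the implementation was checked against `glmmTMB`
(binary part: agreement to 4 decimals in coefficients, standard errors,
σ and log-likelihood; beta part: ~3 decimals). The shipped test suite
uses only in-repo oracles: statsmodels GLM for the zero-variance limit,
scipy densities for the hurdle likelihood, and simulation for recovery
and CI coverage (500 replicates at 36 cows × 112 trials: coefficient
bias ≈ 0.003, coverage 0.94–0.95).

## Pipeline conventions

Analyses of validity, sensitivity and repeatability include only cows
that met the training criterion, mirroring the study's analysis
population. Every section reports
`cows_in = cows_analysed + cows_excluded` with per-cow reasons; warnings
never silently change results. Significance and tendency levels default
to α = 0.05 and α = 0.10. Reports are JSON with a provenance block
(package version, config hash, cohort size); coefficient tables are
plain lists convertible to CSV with pandas.

## Problem sizes

Default problem sizes were chosen to keep the feedback loop tight while
staying at the study's scale where it matters: unit tests run cohorts of
4 cows per arm; directional cohort checks use 200 cows per arm; parameter
recovery uses 500 replicates at the study's 36 × 112 layout; the
acceptance script analyses one 36-cow cohort including all three mixed
-model fits (~half a minute on one CPU).

## Known limitations

* Laplace (not adaptive quadrature) integration: variance components of
  binary models with few observations per group are mildly biased toward
  zero, the known Laplace behaviour; the study-scale recovery tests bound
  the practical effect.
* The simulator's latency model is affine-Gaussian with clipping — it
  makes no claim about real latency distributions.
* Spearman S-values depend on the tie policy of the software that
  produced them; mid-ranks are used here and rho (not S) is reported.
* The exact rank tests' doubled-one-tail two-sided convention matches R;
  other conventions (e.g. summing both tails by probability) can differ
  in the third decimal for tiny n.
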
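# Methods

This note documents the models, parameter choices, and numerical
decisions behind `binpsych`, and states what the synthetic pipeline can
and cannot show about real data.

## Stimuli (`signals`)

A trial is two intervals of four 400-ms pure tones (50-ms raised-cosine
ramps, 25-ms gaps; 400 ms between intervals), rendered at 48 kHz. The
reference interval is diotic; tones 2 and 4 of the target interval carry
the manipulation. An IPD of φ is rendered as ∓φ/2 phase offsets in the
left/right channels (positive φ = right ear leading), so the 180° case
of the frequency-limit task becomes −90°/+90°. An ILD of δ is rendered
as ∓δ/2 dB amplitude scaling. Intensity increments and level roves are
diotic amplitude offsets.

Rove draws: one level offset per tone (eight per trial) uniform on
{−10, −9.5, …, +10} dB, applied identically to both ears; the IPD rove
draws |φ| uniform on {0, 1, …, 45}° for tones 2 and 4 of both intervals
with signs making tone 2 left-leading and tone 4 right-leading.
Applying the rove diotically (one draw per tone, not per ear) is a
design choice: it weakens single-ear loudness cues, which is the rove's
purpose, without perturbing the interaural level difference the task is
about. A per-ear rove would add ILD noise and change the task itself.

Presentation level is an abstract dB scalar (nominally sensation
level). No headphone, ear-simulator or real-ear calibration is
modelled; amplitude 1.0 corresponds to 60 dB on this abstract scale so
that all legal trials stay below full scale.

`measure_interaural` recovers per-tone IPD/ILD from rendered audio by
complex demodulation at the probe frequency and broadband RMS, and the
test suite round-trips every manipulation through it (tolerances: 1°
phase, 0.01 dB level).

## Psychometric model (`psychometrics`)

Probability correct is `p(x) = 0.5 + (0.5 − λ)·S(u)` on a transformed
axis `u` (base-2 log for frequency, so widths are octaves; natural log
for IPD/ILD/increment, where one octave = ln 2 axis units). `S` is a
logistic for the IPD tasks (negative slope for the frequency limit:
performance falls with frequency) and a Weibull — a Gumbel sigmoid on
the log axis — for the level tasks. Width is defined as the axis
distance between the points where `S` crosses 0.06 and 0.94, i.e. the
53% and 97% correct points of the lapse-free curve.

Fitting is a grid posterior: midpoints span the stimulus grid extended
one octave on each side (logistic) or the stimulus grid (Weibull) in 41
steps; widths are 21 log-spaced values from 0.1 to 8 octaves; lapse
takes 11 values 0, 0.01, …, 0.1. Priors are uniform on midpoint and
lapse and log-uniform on width (uniform weights on the log-spaced
grid). The point estimate is the MAP combination (posterior-mean
threshold available by option); grid ties break to the lowest flat
index. The binomial log-likelihood is clipped at 1e−12 to avoid
log-of-zero at degenerate parameter corners.

Edge flags are performance-based: a MAP midpoint pinned at the grid
edge where discrimination is easy flags `above_ceiling`, at the
opposite edge `below_floor`; the threshold is still reported.

Reporting rules applied to human-style estimates: frequency limits
fitted below 65 Hz rest on extrapolation below the lowest presented
frequency and are replaced by the 100-Hz confidence upper bound
(flagged); JNDs beyond the maximum presented stimulus are substituted
by that maximum (180° IPD, 16 dB ILD, 10 dB increment). The validation
simulations use the *raw* fits — the rules above are derived from them.

## Adaptive procedure (`adaptive`)

Stimulus grids: 57 log-spaced frequencies from 125 to 2000 Hz (start
500 Hz, 60 trials); 50 IPDs from 0.5° to 180° (start 90°, 60 trials);
80 ILDs from 0.1 to 16 dB (start 6 dB, 50 trials per condition); 47
increments from 0.1 to 10 dB (start 6 dB, 60 trials). The IPD, ILD and
increment start values are deliberate exceptions that do not lie on
their grids; trial 1 presents them exactly and the posterior update
computes their likelihood column on the fly.

Selection is greedy expected information gain: the grid value
maximising the mutual information between the next binary response and
the (midpoint, width, lapse) posterior, `H(E[p]) − E[H(p)]`, with ties
to the lower grid index. This is the standard objective of the
Bayesian-adaptive family; posterior-variance minimisation could be
swapped in behind the same interface. The adaptive posterior and the
final fit share one parameter grid, so a run is a pure function of
(observer, grid, seed); probability tables are cached per task kind.

The three ILD rove conditions interleave trial-by-trial as a
round-robin whose within-triple order is shuffled per triple — the
protocol specifies interleaving but not its exact schedule.

One property worth stating because it is counterintuitive: chance
responses are *not* uninformative. They exclude midpoints above the
tested range (a genuine PF there would beat chance), piling posterior
mass below the 125-Hz floor while leaving the marginal within that
low region near-flat. This asymmetry is exactly why the specificity
simulation can certify that a listener with an FL estimate above
125 Hz was not guessing.

## Observers (`observers`)

PF observers answer correctly with their own function's probability at
the presented value; the random responder is Bernoulli(0.5); the
single-ear ideal observer compares the manipulated-tone level between
intervals within the right (incremented) ear, giving a decision
statistic ILD/2 + D with D triangular on ±20 dB under the ±10-dB rove.
Its closed-form psychometric function crosses 75% at
`2R(1 − 1/√2) = 40 − 20√2 ≈ 11.72 dB` (R = 20 dB full rove range),
scales linearly with the rove range, and is verified against Monte
Carlo to 0.005 in probability and 0.05 dB in threshold. Observers are
memoryless; practice effects live one level up.

## Protocol and practice (`battery`)

Session 1: FL, ILD (three interleaved conditions), IPD JND, FL.
Session 2: FL, INT JND, IPD JND, FL. Each FL measurement is preceded by
a 15-trial adaptive ILD familiarisation run at 500 Hz (with the
matching reference tones raised by ILD/2 in both ears so loudness
cannot cue the target) and a 10-trial task run; the JND and intensity
measurements get 10-trial runs; the ILD battery gets a 6-trial No Rove
run plus three interleaved 10-trial runs. Training results are recorded
but excluded from all estimates. Skipped measurements are representable
and flagged.

Practice is a multiplicative shift of the true threshold per
measurement index, normalised to mean 1 so the participant's trait is
the across-measurement mean. Defaults reproduce the least-squares-mean
trajectories 745/756/812/833 Hz (FL) and 35/22° (IPD JND). A mean shift
(not a variance change) is the simplest mechanism consistent with a
group-level trajectory, and there is no practice × predictor
interaction in the generator.

## Synthetic cohort (`cohort`)

Traits are drawn from a latent multivariate normal and mapped to
normal or lognormal marginals *on the analysis scale* (log for Trail
Making times and JNDs, linear for the FL, age, PTA_LF, MoCA), so the
target correlations survive the marginal transforms exactly. Marginal
targets: age 69 ± 10 y (bounded 48–85), PTA_LF 44.5 ± 4.5 dB HL
(37–52), MoCA 26 ± 2.2, TMA 38 ± 20 s, TMB 75 ± 40 s, FL 787 ± 257 Hz,
IPD JND 28.5 ± 20°, Level-Rove ILD JND 3.9 ± 2.5 dB, INT JND
1.2 ± 0.6 dB. The IPD JND and ILD JND spreads are not published as
moments and were chosen once as realistic for an older hearing-impaired
group (the JND spread must reach the 180° clamp occasionally, as
observed); all others follow the study's descriptives.

The correlation matrix pins the published coefficients (FL↔JND −.89,
FL↔TMB −.86, JND↔TMB .81, ILD↔TMA .74, ILD↔FL −.70, ILD↔JND .66,
FL↔age −.47, JND↔age .37; FL/JND↔TMA at ∓.71, the midpoint of the
published .66–.76 range). Two cells are derived rather than free:
TMA↔TMB = .72 (these tests co-vary strongly in every aging sample) and
age↔TMB = (−.47)/(−.86) ≈ .547, the unique value consistent with the
finding that TMB time perfectly mediates the age effect on the FL
(r_age,FL = r_age,TMB · r_TMB,FL). Remaining cells default to ±0.3 with
the sign implied by whether the traits share a "higher is worse"
direction; everything is config-overridable. The assembled matrix is
made positive-semidefinite by alternating projection between the PSD
cone and the affine set holding the pinned cells and unit diagonal
fixed — this converges here (minimum eigenvalue ≥ −1e−10 within ~100
sweeps) and leaves every pinned cell exact; if a user override makes
the sets disjoint, the code falls back to the plain PSD projection of
the last iterate.

Repeated measurements multiply the trait by its practice factor and a
lognormal test-retest error (σ = 0.05 log units), then apply the same
reporting substitutions as the measurement pipeline. ILD thresholds for
the No Rove and IPD/Level Rove conditions scale the Level-Rove trait by
2.8/3.9 and 4.0/3.9 (the ratio of the published condition means).
`traits_to_observers` closes the loop: each trait becomes a PF observer
whose 75% point is the trait value (default width 2 octaves, lapse
0.02 — configurable; the closed-loop tests use width 1 to represent
attentive, steep listeners).

What the generator does **not** emulate: audiogram shape across
frequency, within-run nonstationarity (fatigue, lapses of attention
that cluster in time), session gaps, floor/ceiling interactions between
tasks, or any causal structure beyond the correlation matrix plus the
one mediation constraint. Passing tests therefore show that the
*procedures and statistics* behave as published under their stated
assumptions — not that the generator is a model of hearing.

## Statistics (`stats`)

Pearson correlations on per-participant averages with the transform set
above; two-sided p; Benjamini–Yekutieli q values (via statsmodels,
cross-checked in tests against the hand-computed step-up with
c(m) = Σ 1/i and against BH × c(m)). Partial correlations residualise
both variables on the controls (age, PTA_LF by default) and use
t with n − 2 − #controls degrees of freedom; semi-partials are not
used. Power for a correlation uses the Fisher-z approximation
`Φ(|atanh r|·√(n−3) − z_{1−α/2})` (plus the negligible opposite tail);
it reproduces the published statement that n = 20 gives 0.8 power at
r = .58.

The ANCOVA stage deliberately simplifies the original mixed-effects
machinery (Kenward–Roger denominator degrees of freedom, marginal R²)
to ordinary least squares on per-participant averages with backward
elimination (drop the largest p > .05 until all remain significant):
the headline relationships are between participant-level aggregates,
and the repeated-measures structure is small. Aliased candidates
(rank deficiency, or a candidate correlating with the response at
|r| > 0.9999) are flagged rather than fitted. Mediation follows
Baron–Kenny: total effect c, paths a and b, direct effect c′;
"perfect" requires c, a, b significant and c′ not, "partial" a
significant but shrunken c′.

## Problem sizes and tolerances

The validation experiments use the published 2,000 runs; the acceptance
script reports exactly those. Cohort calibration checks use n = 20,000
draws (correlations recovered to ±0.02); the closed-loop
cohort→battery→stats check uses 10 seeds of a 20-participant cohort and
requires a significant negative FL↔TMB correlation in ≥90%; parameter
recovery uses 200 runs (median error ≤ 0.25 octave for a one-octave
observer). Monte-Carlo cross-checks use 1e5 draws. All simulations are
seeded; run-level seeds derive from a `SeedSequence` and stay below
2³¹.

## Known limitations

* The grid-posterior fitter is not a numerical clone of psignifit 4
  (no beta-binomial overdispersion; different priors); only its
  qualitative contracts are reproduced, and the chance-detection
  fractions land near, not exactly on, the published percentages
  (≈99.5% vs 98%, ≈7% vs 5%) — within the stochastic tolerances the
  validation suite asserts.
* The exact objective of the cited adaptive method is re-specified as
  greedy mutual information; trial sequences will differ from the
  original implementation even at matched seeds.
* Whether the original fits used MAP or posterior-mean thresholds is
  unknown; MAP is the default and the option is exposed.
* The single-ear ideal observer's decision statistic matches the
  published 11.7-dB bound, which is the only available evidence that
  the cited derivation used the same construction.
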
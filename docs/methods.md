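# Methods

## The decision model

Voluntary and cued finger movements are modelled as a race between four
linear ballistic accumulators, one per finger. On each trial the active
accumulators (three in a choice trial, one in a specified trial) start at
independent uniform draws from `[0, c0]` and grow linearly at rates drawn
independently from `Normal(mu_i, sigma_i)`. The first accumulator to reach
the threshold `b` determines the response, and the observed response time
adds a constant non-decision latency `t0`:

    RT = min_i (b - start_i) / rate_i + t0        (over active i with rate_i > 0)

A sampled non-positive rate means the accumulator never finishes; a start
point at or above threshold finishes immediately. Trials on which no active
accumulator finishes within the trial deadline (default 2.4 s, the trial
duration) are omissions and are excluded from summaries, mirroring the
behavioural exclusion of non-responses.

Parameters and units:

| symbol | meaning | units | typical default |
|---|---|---|---|
| `mu_1..mu_4` | mean accumulation rates | evidence/s | 2.0 |
| `sigma_1..sigma_4` | rate SDs | evidence/s | 0.6 |
| `b` | response threshold | evidence | 1.2 |
| `c0` | start-point range | evidence | 0.4 |
| `t0` | non-decision time | s | 0.25 |

The model is scale-invariant: jointly rescaling `mu`, `sigma`, `b` and `c0`
leaves all predictions unchanged. Fitting leaves all eleven nominal
parameters free (reported parameter counts are nominal); only
scale-invariant quantities (ratios, `t0`, predicted summaries) should be
interpreted across fits.

## Conditions and modulation

Four conditions arise from trial type crossed with the relation to the
previous response: choice with the repetition option available or absent,
and specified trials cueing the previous or a different finger. Choice /
repetition-absent is the baseline. A modulated parameter (`mu`, `b` or
`t0`) carries one multiplicative ratio per non-baseline condition, shared
across accumulator identities. With repetition-only scope the ratio applies
to the previous action's accumulator (in specified conditions, to the
single active accumulator); with all-accumulator scope it applies to every
active accumulator.

## The design family

Six binary features define the model family: (1) per-accumulator start
ranges; (2) threshold modulated by condition; (3) mean rates modulated by
condition; (4) non-decision time modulated by condition; (5) one shared
mean rate for all accumulators in specified conditions; (6) modulation
applies to all accumulators rather than the repetition one only.

Two normalisation rules make flags interpretable: feature 6 requires at
least one of features 2–4 (there must be a modulation for its scope to
matter), and feature 5 requires feature 3 (equalising rates only in
specified trials already makes rates differ between conditions). After
normalising and deduplicating the 64 raw flag vectors, 46 distinct designs
remain, ordered by number of active features and then by feature index:
design 1 is the feature-free base model, designs 2–5 are the four
single-feature models, and design 4 (rate modulation, repetition-only
scope) is the repetition-suppression model of principal interest.

Nominal parameter counts: 11 for the base model, +3 per-accumulator start
ranges (feature 1), +3 ratios per modulated parameter (features 2–4), and
+1 shared specified-condition mean (feature 5). Treating feature 5 as one
*additional* shared parameter (rather than a merge that lowers the count)
keeps the count monotone in the features; the specified-condition mean is
otherwise not a separate parameter that could be merged away.

## Fitting

Each participant's responded trials are reduced, per condition, to RT
quantiles at levels 0.1/0.3/0.5/0.7/0.9 (linear interpolation of the
empirical CDF) and, for choice conditions, selection counts. The fit
statistic is the likelihood-ratio chi-square

    G^2 = 2 * sum_i O_i ln(O_i / E_i)

summed over (a) the six RT bins delimited by the observed quantiles of each
condition, with expected proportions read from the model's simulated RT
distribution (default 100,000 simulations per condition), and (b) the
selection categories of the choice conditions. Selection categories are the
four fingers in the repetition-absent condition; in the
repetition-available condition responses are categorised as repetition vs.
non-repetition-by-finger (five categories). The plain finger marginal is
nearly invariant to the repetition ratio, because the repetition finger's
identity varies from trial to trial; the repetition-relative
categorisation keeps the suppression signal in the statistic.

Numerical details:

- Expected proportions are floored at `1 / (2 n_sim)` and renormalised, so
  simulation-empty bins cannot produce infinite terms; zero-observed bins
  contribute zero. Degenerate predictions yield a large finite penalty the
  optimiser can traverse.
- Simulated trial configurations (previous action, valid set) are resampled
  with replacement from the observed responded trials of the condition, so
  predictions marginalise over previous actions exactly as the data do.
- Common random numbers: within one restart the same standard-normal and
  uniform draws are reused for every objective evaluation, making the
  stochastic objective a fixed deterministic surface for the simplex.
- Parameters are searched on an unconstrained scale: log for rates, SDs,
  threshold and ratios; a logit of `c0 / b` (keeping the start range below
  threshold); a scaled logit for `t0` on `(0, min observed RT)`.
- Random-start ranges: `mu in [0.5, 5]`, `sigma in [0.2, 2]`,
  `b in [0.5, 3]`, `c0/b in [0.05, 0.95]`, `t0 in [0.05, ~min RT)`,
  ratios in `[0.3, 3]`.
- Optimisation: per restart (default 20), the best of `n_candidates`
  (default 100) random parameter sets seeds a Nelder–Mead simplex run to
  convergence (relative tolerances 1e-4) or the 10,000-iteration cap,
  followed by `n_polish` (default 1) fresh-simplex reruns from the
  endpoint — the simplex tends to collapse along ridges of this
  14-dimensional surface, and re-expanding it recovers progress cheaply.
  The restart with the lowest final G^2 wins. Everything is reproducible
  from a single seed.

Model fit is scored by `BIC = G^2 + k ln(n)` with `k` the nominal
parameter count and `n` the participant's responded, fitted trial count;
this is the multinomial-deviance form of the criterion. Group-level
comparison sums BIC over participants; ties break by fewer parameters,
then design order. Post-hoc comparisons use the exact two-sided binomial
sign test (zeros dropped) and the one-sample Wilcoxon signed-rank test
(zeros dropped, midranks for ties, exact p for n <= 25 without ties,
otherwise a continuity-corrected normal approximation).

## Expected accumulated activity (EAA)

For a responded trial with RT `t`, write `T = t - t0`. The winner travelled
from its expected start `c0/2` to `b` in `T` seconds, so its expected
realised rate is `E[mu_W] = (b - c0/2) / T`, and its expected area under
the trajectory is the trapezoid `EAA_W = (b + c0/2) T / 2`. Losing
accumulators had not reached threshold by `T`, so their realised rates are
normal distributions upper-truncated at `E[mu_W]`, with mean
`mu_L - sigma_L * phi(z)/Phi(z)`, `z = (E[mu_W] - mu_L)/sigma_L`
(evaluated in the log domain for far truncation). Each loser contributes
the signed trapezoid `(c0/2) T + E[mu_L] T^2 / 2`; the trial EAA is the sum
over active accumulators, which for specified trials is just `EAA_W`.

Choices made here: the loser area is the signed area under the expected
linear trajectory starting at `c0/2` — negative expected rates are allowed
and flagged, not floored at zero; trials with `t <= t0` (possible because
`t0` is fitted per participant) are excluded and counted, never silently
zeroed; and each trial uses its condition-specific effective parameters,
including the repetition-accumulator modulation. A quadrature oracle
(numeric integration of the expected trajectories) pins the closed forms
to 1e-8.

For fMRI use the per-trial EAA is exported as a BIDS-style events table
with `eaa` and `eaa_residual` parametric-modulator columns, where the
residual removes the least-squares projection of EAA on [intercept, RT]
(mean-zero, orthogonal to RT). Mean-centring of the modulators is a flag;
orthogonalisation beyond RT is left to the GLM software.

## Synthetic sessions and behaviour

The session generator reproduces the task structure: 1008 trials per
session — 50% choice, 25% specified, 25% null events — in randomised order
with at most four consecutive trials of the same type (sequential weighted
sampling with restart on dead ends), 2.4 s trials with a 1 s cue, and exact
50/50 repetition splits within choice and within specified trials. Valid
action sets depend on the participant's actual previous response, so the
generated session is a plan of trial types and condition labels;
behavioural generation walks the session maintaining the realised response
stream, rebuilds each valid set online (repetition-available includes the
previous finger and drops one of the other three at random;
repetition-absent excludes it; specified trials cue the previous or a
uniformly drawn other finger), and simulates the race. Omitted trials leave
the previous-response state unchanged. The first action trial receives a
uniformly drawn pseudo-previous action and is flagged for exclusion from
condition-based summaries. An omission rate above 35% (the
participant-exclusion rule) raises a warning.

Default generating parameters (`default_group_params`,
`default_modulations`) were chosen so that simulated behaviour lands in the
reported group regime — repetition rate near 19% in repetition-available
choice trials, specified responses some 50 ms faster than choices, and
repetition cueing fastest — with choice ratio 0.8 and specified ratios
1.6 / 1.45 relative to the repetition-absent baseline.

What the generator deliberately does **not** emulate: commission errors
(pressing an invalid finger — excluded from the original analyses),
sequential dependencies beyond the most recent action, attention or
strategy drift over the session, and within-session parameter
non-stationarity. Passing recovery tests therefore demonstrates internal
consistency of the pipeline under the model's own assumptions, not that
real behaviour satisfies them.

## Recovery experiments

Parameter- and model-recovery harnesses generate synthetic cohorts
(participant-level heterogeneity: log-normal jitter with SD 0.1 on the mean
rates, normal jitter with SD 0.02 s on `t0`, floored at 0.05 s), fit the
listed designs to each participant, and rank designs by summed BIC. All
designs fitted to one participant share the same fit seed, hence identical
simulation noise — common random numbers across designs — so BIC
differences reflect the designs rather than simulation noise.

Problem sizes used by the shipped experiments: 16 participants for ratio
recovery (design 4 only) and 3 cohorts of 4 participants for design
recovery over designs {1, 3, 4, 5}, both fitted with 20,000-simulation
predictions, 5 restarts and a few hundred simplex iterations per stage.
These are reduced-scale versions of the full estimation procedure (100,000
simulations, 20 restarts, 10,000-iteration cap) chosen to keep a complete
recovery study at desk scale; the reduction leaves the ratio estimates
noisier but unbiased enough that the cohort median recovers the generating
ratio closely.

## Known limitations

- The LBA scale non-identifiability means individual `mu`, `sigma`, `b`,
  `c0` estimates are only interpretable up to a common factor.
- Per-accumulator rate SDs are weakly identified from a single ~750-trial
  session; fitted SD vectors can be heterogeneous without materially
  changing predictions. Ratios and `t0` are well identified.
- Threshold modulation (design 3) mimics rate modulation (design 4)
  closely; distinguishing them reliably needs either more participants or
  better-converged fits than the desk-scale defaults.
- The fitting objective is a simulated (noisy) surface; with common random
  numbers it is deterministic per restart but still a biased estimate of
  the infinite-simulation objective at finite `n_sim`.
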
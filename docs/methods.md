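# Methods

`affectrl` implements a complete, self-contained analysis loop for a
dynamic probabilistic reward task with affective primes: task simulation,
Q-learning choice modelling, hierarchical Bayesian parameter estimation,
behavioral summaries, and feedback-locked ERP (FRN) analysis. Everything
can be exercised on synthetic data with known ground truth, so every
stage is testable by parameter or amplitude recovery.

## Task model

Two deck pairs ("Up" = A/B, "Down" = C/D) are interleaved randomly trial
by trial, one pair per prime condition (affective / neutral). Each
condition runs through six blocks of 70–90 trials (480 trials per
condition, 960 total at full scale). Within a block the pair's reward
probabilities follow one of the ratios 6:1, 3:1, 1:3 or 1:6 and sum to
60%; for 6:1 this gives exactly 36/70 vs 6/70, computed with rational
arithmetic before any float conversion. Block transitions are
un-signaled and always move the higher probability to the other deck of
the pair, so the ratio sequence is drawn uniformly subject to the rich
side alternating.

Design points that the task description leaves open, resolved here once:

- **Reward draws are independent Bernoulli per deck per trial** — no
  baiting or reward persistence, the simplest scheme consistent with the
  task description (ancestral foraging tasks baited rewards; this one is
  not documented to).
- **All experimental ratios share the 60% pair total** (stated explicitly
  only for the 6:1/1:6 training phase); the experimental ratios are read
  as generalizing the training ratios.
- **Each condition's block/ratio sequence is sampled independently**; the
  pairing of ratios across the two simultaneous deck pairs is not
  coordinated.
- **Deck-pair ↔ condition assignment is fixed per subject** and
  counterbalanced across simulated subjects (even/odd subject index).
- Block lengths are a uniform composition of the per-condition trial
  count, found by rejection sampling within the allowed range (with a
  constructive fallback for near-degenerate configurations).

## Choice model

Values update by the delta rule, Q ← Q + α(R − Q), with the reward
prediction error δ = R − Q for the chosen deck only; rewards are 0/1.
Choice follows Boltzmann exploration, P(A) = e^{βQ_A}/(e^{βQ_A}+e^{βQ_B}),
computed as a logistic of β(Q_A − Q_B) so it is stable for arbitrarily
large β. α ∈ [0,1] is the learning rate, β ≥ 0 the choice perseveration
(inverse-temperature-like) parameter; β = 0 yields random choice.

- `q_init = 0.5` for every deck — the midpoint of the 0/1 reward range —
  and configurable. With rewards in {0,1} and α ∈ [0,1] every Q then
  stays in [0,1].
- Q values are maintained per deck pair and carried across block
  transitions without reset (transitions are invisible to the agent).
- The likelihood replays the value trajectory from `q_init` using the
  observed choices and rewards; it never trusts stored Q columns.
- Fits share one (α, β) per subject across both prime conditions by
  default; per-condition fits are obtained by fitting each condition's
  trials as separate data sets (the trial-log format carries the
  condition column for exactly this subsetting).

## Hierarchical Bayesian estimation

Subject parameters are drawn from group-level normals truncated to their
supports: α_i ~ N(μ_α, σ_α) on [0,1], β_i ~ N(μ_β, σ_β) on [0,∞).
Truncation is required for a well-defined density at the bounds; the
truncated-normal normalizing constants are included in all group-level
updates. Hyperpriors are non-informative uniforms: μ_α, σ_α ~ U(0,1),
μ_β ~ U(0,10), σ_β ~ U(0,5). The σ priors bound the standard deviation
(not the precision).

The sampler is random-walk Metropolis within Gibbs with Gaussian
proposals:

- one vectorized sweep over all subjects' α, one over all β per
  iteration — elementwise accept/reject across subjects is exact because
  subjects are conditionally independent given the hypers;
- scalar updates of μ_α, σ_α, μ_β, σ_β against the truncated-normal
  subject prior (the data term cancels);
- proposal scales adapt every 50 iterations during burn-in toward ~30%
  acceptance and are frozen afterwards, preserving detailed balance of
  the retained draws;
- initialization at coarse grid-search ML estimates per subject
  (jittered per chain) with hypers at the estimates' mean/SD — this
  avoids −∞ starting densities, which otherwise raise an explicit
  initialization error.

Default bookkeeping is 3 chains × 16,000 iterations, 6,000 burn-in,
thinning interval 5 — i.e. 30,000 post-burn-in points thinned to exactly
6,000 retained draws. The retained count is `ceil((iterations − burnin)
/ thin)` per chain, which reduces to the exact identity whenever the
span is divisible by the thinning interval (as in the defaults). Reduced
settings (e.g. 3 × 2,000–4,000) are used throughout the test suite;
statistical checks there are scaled to those settings' posterior widths.

The per-subject likelihood kernel is numba-compiled (with a pure-Python
fallback if numba is unavailable); a 20-subject × 480-trial fit at
3 × 4,000 iterations runs in a few seconds on one core.

Convergence is monitored with the Gelman–Rubin potential scale reduction
factor in its classic between/within-chain variance form (constant
chains are defined as R-hat = 1 with a warning; a single chain is
rejected with a pointer to split-chain diagnosis). Group contrasts use
Wald tests on the retained draws: z = (m₁ − m₂)/√(s₁² + s₂²) with a
two-sided normal p-value.

## ERP pipeline

All ERP processing operates on microvolt arrays at 1 kHz (configurable).

- **Filtering**: 4th-order Butterworth bandpass (default 0.1–40 Hz),
  applied forward-backward (zero phase) as second-order sections. The
  pad length scales with the low cutoff (~3/low seconds, capped at the
  signal length) because the 0.1 Hz pole settles over ~4 s and the
  default reflection pad would leak drift transients. For the same
  reason the bandpass is meaningful only on continuous signals; an
  800 ms epoch cannot represent 0.1 Hz, so pipelines that generate
  epochs directly rely on baseline correction for offset removal and
  skip the highpass.
- **Epoching**: windows are inclusive of both endpoints at integer-ms
  sampling (−100..700 ms at 1 kHz → 801 samples); events whose window
  leaves the recording are dropped with a warning.
- **Baseline correction**: per epoch and channel, subtract the mean over
  [window start, 0) ms.
- **Artifact rejection**: an epoch is removed when any channel at any
  sample exceeds ±50 μV (threshold configurable); the scan is joint
  across channels. The report carries per-label rejection rates, and a
  fully-rejected set is flagged so downstream averaging refuses rather
  than fabricates. Eye-blink correction is deliberately not modelled;
  threshold rejection is the only artifact control. Re-referencing to
  averaged mastoids is available as a continuous-stage operation and is
  a no-op on reference-free synthetic data.
- **Outcome classes**: the choice's expectation status (rich vs poor
  deck) crossed with the outcome gives expected-delivery,
  expected-omission, unexpected-delivery, unexpected-omission.
- **FRN difference waves**: General = all non-reward − all reward;
  Expected = expected-omission − expected-delivery; Unexpected =
  unexpected-omission − unexpected-delivery. Each is quantified as the
  negative peak in 200–400 ms at Fz/FCz/Cz (windows and channels
  configurable); N170 (negative, 110–200 ms, P7/P8) and EEP (positive,
  120–180 ms, Fz/Cz/Pz) use the same peak extractor. Ties break to the
  earliest latency. Peaks are measured on the difference wave by
  default; `peak_mode="sides"` instead measures each side's raw average
  and subtracts the peaks.
- Cells with fewer than 10 epochs on either side (configurable) are
  reported as missing.

## Synthetic data

The generator emulates the study's structure with known truth:

- **Cohorts**: α_i, β_i from the truncated group normals, each subject
  simulated on an independent schedule realization. Degenerate σ ≤ 0
  falls back to a point mass with a warning.
- **EEG**: additive noise (white by default, SD 5 μV; a 1/f option for
  more realistic spectra) plus a Gaussian-shaped negativity (center
  280 ms, SD 40 ms — the shape and latency are modelling choices; only
  the measurement window and peak amplitude are externally constrained)
  added to non-reward epochs. The component is scaled per channel by a
  fronto-central topography (gain 1.0 at FCz/Cz) so that the noise-free
  difference-wave peak at a gain-1.0 channel equals the target amplitude
  exactly. Prime-locked epochs analogously embed a right-lateralized
  N170 at P7/P8 and a positive EEP at Fz/Cz/Pz (both at 150 ms).
- Epochs can be generated directly (`synth_epochs`,
  `synth_feedback_epochs`) or as a continuous recording with event
  times (`synth_feedback_recording`) for the filter-then-epoch path.
- Group amplitude defaults follow the reference group-mean General FRN
  values (NN −6.50, AN −7.33, HN −7.23 μV); per-class amplitudes default
  to the general value. N170/EEP defaults (−6, +4 μV) are plausible
  magnitudes for these components.

What the generator does *not* emulate — and therefore what passing
round trips do not establish about real recordings: volume conduction
and realistic topographies, ocular/muscle artifacts beyond amplitude
outliers, overlapping ERP components, non-stationary noise, response
times, or any subject-level coupling between model parameters and ERP
amplitudes.

## Problem sizes and numerical choices

- Test-suite simulations run at desk scale: 2 blocks × 40–80 trials per
  condition (120/condition) and cohorts of 2–20 subjects; MCMC at
  3 × 2,000–6,000 iterations. Full-scale settings (960 trials,
  16,000 iterations, 22 subjects/group) are one flag away
  (`--paper-settings`, `paper_run_config`, `paper_settings`).
- The amplitude-recovery round trip uses 200 epochs/side at noise SD
  5 μV; across seeds the recovered FCz peak is within ~±0.3 μV of the
  embedded −7.22 μV (small negative extreme-value bias plus filter
  shaping), comfortably inside the ±0.5 μV acceptance band.
- Seeds: all generators are pure functions of (spec, seed); multi-stage
  pipelines derive per-stage substreams from one root seed via
  `SeedSequence.spawn`, so studies are byte-reproducible.
- Oracle tolerances in the tests: likelihood vs brute-force product
  1e−12; joint density vs term-by-term sum 1e−10; peak extraction vs
  exhaustive scan exact; MCMC vs dense grid integration 0.02 on the
  posterior mean of α.

## Known limitations

- The random-walk sampler is adequate for the ~2(N+4)-dimensional
  posterior here but mixes slowly for strongly correlated hypers at very
  small N; R-hat is reported everywhere and should be checked.
- Non-reward run statistics depend on the run definition; both variants
  (streaks terminated by a shift only, or all maximal streaks) are
  provided because the field's usage varies. Note that higher choice
  perseveration *lengthens* mean runs under this model — near-random
  agents truncate streaks by chance switches.
- The epoch-bundle format stores float32; round trips through it are
  exact only to single precision.
- Alternative learning models (actor–critic, dual learning rates) and
  model-comparison criteria are out of scope.
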
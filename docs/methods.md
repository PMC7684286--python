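# Methods

`pitchsub` has two halves: a behavioral-statistics pipeline for closed-loop
operant pitch conditioning with a visual (light-off) reinforcer, and a
discrete reinforcement-learning model of why the same reinforcer is
appetitive for deaf birds and aversive for hearing ones. This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## The paradigm and its statistics

A singing bird's targeted syllable is measured once per rendition (16-ms
pitch window). Whenever the pitch falls beyond a threshold on the targeted
side, the chamber light is briefly switched off (LO). Every morning the
threshold resets to the previous day's median pitch, so the *neutral*
expectation of the LO contingency — the fraction of renditions triggering
LO — is 50% each day; sustained deviations from 50% are produced only by the
bird shifting its pitch distribution day over day.

Effect sizes are normalized pitch changes between days *i* and *j*:

d′_{i,j} = (p̄_j − p̄_i) / √(½(σ²_i + σ²_j))

with day means p̄ and sample (n−1) variances σ². All derived statistics are
built from this quantity:

* **Daily change**: d′_{i−1,i}; averaged over reinforcement days (from the
  second LO day) or over the last four baseline days.
* **Direction and magnitude**: δ = sign(d′_{b,l}) with *b* the last baseline
  and *l* the last reinforcement day; the aligned magnitude
  ā′ = δ·⟨d′_{i−1,i}⟩ is nonnegative whenever the global shift dominates
  daily noise. δ is defined as +1 (with a logged warning) in the
  measure-zero case d′_{b,l} = 0.
* **Stability criteria**: reinforcement begins only after five stable
  baseline days (|d′_{i−4,i}| < 0.5, strict inequality) and ends when the
  cumulative shift exceeds 2.5 d′ or stabilizes near zero by the same
  criterion.
* **Threshold conventions**: the even-count median is the mean of the two
  central order statistics; "high"-side reinforcement triggers on pitch
  strictly above the threshold (equality never triggers); days without data
  (recording crashes) carry the previous threshold forward.
* **Direction-count argument**: the probability that *k* of *n* birds drift
  the same way under a fair-coin null is exposed with an explicit tail
  convention (`greater`, `less`, `two-sided`), because one-number claims
  about 9-of-10-type outcomes depend on the convention: P(X ≥ 9 | n = 10) =
  11/1024 ≈ 1.07% one-sided and ≈ 2.15% equal-tailed two-sided. The package
  asserts only the enumerable values.

Inference follows two mixed models with a Gaussian random intercept per
bird, fitted by maximum likelihood (ML rather than REML so that nested
model variants are comparable on likelihood):

* daily pitch change: d′^j_{i−1,i} = b·ϑ_i + a·θ_i + d·φ_i + r_j, where ϑ
  flags baseline day pairs, θ flags post-baseline pairs in control birds and
  φ = ±1 flags reinforcement pairs of high/low-targeted treated birds. There
  is no global intercept beyond the indicators; pairs straddling the
  baseline/reinforcement boundary are dropped.
* singing rate: n^j_i = c + a·deaf_j + b·lo_j + d·(deaf_j·lo_j) + r_j on the
  last three reinforcement days' counts relative to the last three baseline
  days.

Reported p-values use the residual-df Student-t convention
(df = observations − fixed effects). Per-bird screening uses uncorrected
two-tailed pooled-variance t-tests against time-matched control daily
changes, and population effects are re-checked over 1000 random
control–treated pairings drawn by a scarcity-first greedy matcher (controls
with the fewest permissible partners matched first; surplus controls matched
with replacement).

## The synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, for
five cohorts: deaf substituted (subs), deaf control (unsubs), hearing
light-off (LO), hearing control (noLO), and deaf random-delivery
(subs-rand). Per bird-day, pitches are i.i.d. Gaussian around a daily mean;
within-day distribution shape and autocorrelation are not modeled (the
analyses are day-level). Defaults are the study conditions:

| parameter | default | basis |
|---|---|---|
| baseline mean pitch | 700 Hz | typical harmonic-syllable fundamental |
| baseline sd | 7 Hz | CV ≈ 1% of the mean |
| baseline days / reinforcement days | 5 / 11 | start criterion; mean reinforcement duration |
| subs response | +0.19 d′/day toward the zone | reported deaf fixed effect |
| LO response | 0.08 d′/day away from the zone | reported hearing fixed effect |
| renditions/day | 200 (Poisson, floored at 1) | above the 100-rendition inclusion bar |
| singing trends/day | subs +2.1%, unsubs −3.7%, LO −0.9%, noLO +0.7%, subs-rand −5.5% | per-day rates matching the reported relative changes (+25%, −34%, −9%, +8%, ≈−50%) over 11 days |

The stimulus flag is assigned by the same threshold controller the analysis
uses (median morning reset, closed loop with yesterday's simulated pitches);
subs-rand birds get a fair coin per rendition. The response is applied to
the daily mean only and does not feed back from the stimulus flags. Two
emergent checks come out at the measured values rather than being injected:
a +0.19 d′/day response against a median threshold yields ≈57% daily
contingency (Φ(0.19)), and 0.08 d′/day away yields ≈47%.

Per-bird seeds derive from the master seed via `SeedSequence([seed, index])`
so appending birds never perturbs existing ones.

What passing tests on these cohorts do *not* show: robustness to misdetected
renditions (none are simulated), to non-Gaussian or autocorrelated
within-day pitch, or to bird-level heterogeneity beyond the random
intercept. In particular the generator gives every bird in a cohort the same
singing trend, so the synthetic singing-rate model finds a significant LO
main effect at the cohort-mean conditions, where noisier real cohorts need
not.

## The syllable-world model

A syllable is three consecutive notes; each note offers six motor variants,
so 18 actions in all. Action *a* (home state *a*) stochastically triggers
one of three adjacent sensory states with kernel (0.25, 0.5, 0.25); edge
actions shift the 3-state window inward so every row keeps exactly three
adjacent nonzero entries. States 13–16 (1-based labels) switch the light
off; they straddle the note-2/note-3 boundary, so the last note-2 variant
can trigger LO (probability 0.25) and four of six note-3 variants are partly
or wholly inside the zone. The exact emission probabilities of the source
figure are not recoverable, so the kernel and LO set are configuration
parameters and every model-level claim is a sign/ordering property, not a
point value.

The agent's per-action reward is R = E + M + r:

* **Exploration bonus E**: Bayesian expected information gain about the
  action's outcome distribution under a Dirichlet model (pseudocount 1 per
  symbol): E = Σ_k (α_k/α₀)[log(α₀/α_k) + ψ(α_k+1) − ψ(α₀+1)]. Positive,
  strictly decreasing in experience, vanishing asymptotically. The outcome
  alphabet is the action's *realizable* consequences — the binary light
  state for deaf agents, the three action-relative sensory outcomes for
  hearing agents. (The agent knows its motor-sensory topology; what it
  learns is the contingency within it. A naive alphabet over all 18 states
  would keep E large for thousands of trials and leave behavior
  exploration-dominated at the run lengths used here.)
* **Manipulation bonus M**: the impact of an action, M = D_KL(θ̂₀ ‖ θ̂_j) in
  nats, between the no-action sensory distribution θ̂₀ and the
  Laplace-smoothed estimate θ̂_j after the action. The baseline percept is
  silence-with-light-on, so θ̂₀(off) = 0. For deaf agents the alphabet is
  binary and M reduces exactly to the Shannon surprise −log θ̂_j(on): it
  grows as an action reliably produces light-off, which is the appetitive
  engine of the model, and it is capped at log 2 when light-off is an
  unpredictable fair coin (the subs-rand protocol). For hearing agents every
  action yields a reliable, distinct percept, so the impact is large but
  identical across actions; a constant reward offset only shifts the Q zero
  (and, against zero-initialized Q, slows learning), so the common hearing
  impact is absorbed into the reward baseline (`hearing_impact`, default 0).
* **Extrinsic punishment r ≤ 0**, delivered only on light-off events.

Learning is tabular SARSA. Because an action's outcome depends only on the
action, the note index is a sufficient state and Q is 3×6. Defaults:
learning rate α = 0.1, ε-greedy ε = 0.1 with uniform tie-breaks, discount
γ = 0.9 within the three-note episode, episodes independent, Q initialized
at 0. The contingency sign pattern is robust across ε ∈ {0.05, 0.1, 0.2}
(tested). "Converged" quantities are computed over the last 20% of trials.
The motivation index is the visit-weighted mean Q over that window, so
unvisited state-actions do not dilute it.

The sweep protocol runs 8 log-spaced punishments from −0.01 to −2 nats, 20
agents per cell, 2000 trials per agent — sized to complete in a few minutes
on one CPU while leaving Monte-Carlo error well below the effect sizes.
Controls for the motivation comparison are identical agents in a world whose
LO state set is empty (light never off). The subs-rand ceiling check uses a
200k-trial run and estimates the common asymptotic impact by pooling
observation counts across actions (light-off is action-independent there,
so pooling is the minimum-variance estimator of the shared limit; note that
the three within-syllable observations share one coin flip, so the
effective sample size is the trial count).

Fixed-policy SARSA is validated against exact dynamic programming on the
same world (uniform policy, extrinsic rewards only, harmonic step sizes,
agreement within 10⁻²).

## Acoustic features

For feature extraction on 32-kHz mono recordings: spectrograms use a 512-
sample Hamming window with 128-sample hop; the log-power spectrogram is the
natural log of linear power plus an offset of 0.1; the lowest 10 bins
(cutoff 625 Hz) are discarded for robustness to low-frequency noise. The
power normalization before the offset is unspecified territory, so a toggle
(`normalize`) scales linear power to put its 75th percentile at the offset.
Pitch uses the Harmonic Product Spectrum over H = 5 harmonics (H exposed in
config) on a 16-ms window, zero-padded to 8192 points, searched in
300–3000 Hz; accuracy is better than one 62.5-Hz analysis bin across
400–1200 Hz fundamentals, including missing-fundamental stacks. Entropy
features are per-frame Wiener entropy (log ratio of geometric to arithmetic
mean power — the standard songbird definition; ≈0 for noise, strongly
negative for tones), summarized by the mean and variance over frames.
Day-to-day spectral change decomposes into bias (Euclidean distance between
day-mean spectrograms, after cropping all renditions to the shortest) and
variance (mean pixel-wise across-rendition variance).

## Numerical notes and limitations

* Mixed models fall back across optimizers (L-BFGS → Powell → Nelder-Mead)
  because boundary variance estimates can break a single optimizer; with the
  random-effect variance at the zero boundary the fit coincides with OLS.
* d′ is undefined when both day variances are zero; the package raises
  rather than returning a sentinel.
* The manipulation bonus is infinite when θ̂₀ has mass where θ̂_j has none;
  this raises unless explicitly allowed (smoothed estimates never trigger
  it).
* At the weakest punishment on the default grid (−0.01 nats) the per-note
  punishment differentials are ~5×10⁻³ nats, at the edge of what 2000
  constant-α trials resolve; hearing cell means stay below 50% but with
  visibly larger agent-to-agent spread there.
* The model makes no claim about absolute learning rates or about fitting r
  to the birds' quantitative behavior; the deliverable is the sign/ordering
  pattern and the discovered plausible-r interval.
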
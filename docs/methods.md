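# Methods

## Task model

The environment is a two-armed bandit with *baited* rewards. Once per
trial, before the choice, each unbaited port independently becomes baited
with its scheduled probability; a baited port stays baited until chosen,
at which point the bait is collected and cleared. Consequences: the
first-visit payoff probability after *k* skipped trials is
1 − (1 − *p*)*^k*, and bait flags persist across reversals (only the
probability assignment swaps — the simplest rule consistent with rewards
remaining available until collected). In the non-baited head-fixed
variant the flags are cleared every trial, which reduces to a fresh
Bernoulli draw per port.

Reversal logic, evaluated after every completed trial on the current
block's trials only:

- **cap rule** — block ends when the trial count reaches
  `block_length_cap` (80 in the default full task; 100 in training);
- **performance rule** (training only) — block ends once ≥ 9 of the last
  10 within-block choices were to the high-probability port. Because the
  window never spans a reversal, the earliest trigger is trial 10 of a
  block, which is why an always-correct agent sees exactly 10-trial
  blocks. "Correct" means choosing the high-probability port regardless
  of reward receipt (in 0/100 training the two coincide).
- **head-fixed rule** — after 10 cumulative (not necessarily consecutive)
  high-side choices within the block, a delay L is drawn from a truncated
  geometric distribution and the block switches L trials later.

Trials with no response count toward block length and session caps but
carry no choice information; 20 consecutive no-responses end a head-fixed
session.

## Timing distributions

**No-lick period.** Each draw is a truncated exponential (rate 0.3333
s⁻¹, support [1, 5] s) sampled by inverse CDF restricted to the support,
so every draw is bounded without rejection sampling. A premature lick
adds another draw, up to 5 draws total (the initial draw counts toward
the maximum) — giving the hard 25 s ceiling; the closed-form truncated
mean used in tests is lo + 1/λ − (hi − lo)(1 − Z)/Z with
Z = 1 − e^(−λ(hi−lo)).

**Block-transition delay.** Geometric on {0, 1, 2, …} with success
probability 1/(μ + 1), i.e., μ is interpreted as the *untruncated* mean,
renormalized over the support [0, 30] and sampled from the explicit pmf.
Interpreting μ as the post-truncation mean would require solving for the
success probability numerically; the untruncated reading is the simpler
convention and the truncation shifts the realized mean only slightly
(≈ 9.8 rather than 11).

**Inter-trial intervals.** Latencies are log-normal with an
outcome-conditional median — location ln(median | previous outcome),
scale `dispersion` (log-sigma, default 0.4) — because the published
summaries are medians and IQRs of a positive, right-skewed quantity.
Defaults are calibrated to the wild-type medians (1.8 s after a rewarded,
1.1 s after an unrewarded trial). Trial *t*'s latency is attributed to
the outcome of trial *t − 1*.

## Agents

Agents are synthetic stand-ins, not fitted models of mice: no generative
model of the animals' behavior is claimed. Win-stay/lose-switch (with a
uniform-lapse rate `eps`), biased-random, and a value-learning agent with
per-side values updated by Δv = α(r − v) and softmax choice with inverse
temperature β. First trials of history-dependent policies are uniform
random, drawn from the session RNG. Two deterministic reference agents —
strict alternation and an oracle that always chooses the current high
side — exist to pin the task rules down in tests. All stochastic draws
(baiting, choice, lapse, latency, no-lick, block delay) consume a single
per-session generator in a fixed documented order, so a session is a pure
function of (agent parameters, task config, seed).

## Synthetic cohorts

A cohort crosses genotype (WT/HET) with sex (M/F), `n_per_cell` subjects
per cell (default 12, i.e., 24 per genotype — the scale of the motivating
study), each run through an ordered curriculum of task presets.
Per-session seeds are spawned from the master seed via `SeedSequence`, so
any sub-stream is reproducible in isolation. A genotype effect, when
requested, is a single multiplicative perturbation of one named agent
parameter in HET subjects (default: the learning rate α scaled by
1 − effect_size); at the default `effect_size = 0` the genotypes are
identically parameterized and every metric is exchangeable between groups
by construction. That null matches the motivating study's finding and is
what the type-I-error calibration consumes. A seizure metadata flag can
be set on a random HET subset; it has no behavioral consequence.

What the generator does *not* emulate: within-session fatigue or
satiation drifts, slow cross-session learning of the full task,
individual-animal parameter heterogeneity beyond the genotype
perturbation, side biases, and any physiological covariates. Passing
tests therefore demonstrate correctness of the task rules, metrics and
statistics — not that real mice behave like these agents.

## Metrics conventions

- No-response trials are excluded from all choice-based numerators and
  denominators; a day or condition with an empty denominator yields a
  missing value, never zero.
- The reversal-aligned curve counts, for post-reversal trial *k*, the
  fraction of blocks whose *k*-th trial chose the new high side; blocks
  shorter than *k* leave trial *k*'s denominator. Group curves pool
  blocks within subject first and average across subjects (a
  `per_subject=False` flag pools all blocks instead).
- Win-stay/lose-switch transitions are consecutive valid-choice trial
  pairs, including pairs spanning a reversal.
- Quartiles use linear interpolation (`numpy.percentile` default), so
  IQRs are bit-reproducible.
- The moving-average choice trace is a trailing window (default 10) over
  valid choices, averaging the available history before the window fills.

## Statistics

The mixed-design two-way ANOVA uses the classical split-plot
decomposition (total = group + subject(group) + level + group×level +
residual) with subject(group) as the error term for the group effect and
the residual for the within and interaction effects. No
Greenhouse–Geisser sphericity correction is applied — a documented
limitation, configurable only by pre-transforming the data. The
implementation is cross-checked against `pingouin.mixed_anova` in the
test suite. Because a single p-value "for group and level" is ambiguous,
all three effects are reported and the interaction is treated as the
headline term in pipeline reports.

Mann–Whitney U reports the first sample's U (rank sum minus its minimum).
For min(n₁, n₂) ≤ 8 with no ties the two-sided p doubles the exact tail
probability from full enumeration of the null rank distribution (a
subset-sum dynamic program over pooled ranks); otherwise the normal
approximation with midranks, tie-corrected variance and a 0.5 continuity
correction is used, matching `scipy.stats.mannwhitneyu` on both paths.
Bonferroni adjustment is min(1, p·m) with family size m ≥ the number of
tests. α = 0.05 package-wide, configurable per call.

## Problem sizes and calibration checks

The type-I-error calibration generates 1,000 replicate null cohorts of 8
subjects per genotype (4 per genotype × sex cell), each subject running
one 200-trial full-task session with WSLS-lapse agents (`eps = 0.15`),
then applies the Bonferroni-corrected Mann–Whitney family over
{win_stay, lose_switch}. 200 trials keeps both fractions estimated from
~90–100 transitions each, ample for rank tests, while the 1,000
replicates complete in well under a minute on one CPU. Because the two
metrics are correlated within subject, Bonferroni control is conservative
and the observed family-wise rate sits at or just below the nominal 0.05.

Monte-Carlo tolerances in tests are three standard errors of the
estimator in question; deterministic rule checks (block lengths 100, 10
and 80) are exact equalities. Degenerate inputs are errors, not silent
defaults: probabilities outside [0, 1], empty samples, incomplete ANOVA
designs and invalid agent outputs all raise typed exceptions.
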
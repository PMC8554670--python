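# Methods

## The intervention model

The engine implements a stepped-care, just-in-time adaptive messaging
protocol as a deterministic state machine per participant. Its state is
the schedule (`next_checkin_day`), the ordered check-in history, a
counter of consecutive "flagged" check-ins (suboptimal emotional-health
rating together with low self-efficacy), outstanding-prompt bookkeeping,
and the active/quit flags. All transitions are pure in the sense that the
emitted action stream is a function of (state, input, clock); the engine
holds no randomness, so replaying a recorded event stream reproduces the
action stream exactly. Transition functions mutate the passed state and
return it; `ParticipantState.copy()` gives a snapshot when needed.

Assumptions built into the model:

- **Whole-day clock.** Day 0 is enrollment; sub-day timing is not
  modelled. The "reprompt after 24 h" policy becomes day + 1 and the
  "missed 48 h after the reprompt" policy day + 3.
- **Cadence.** The first check-in is on the enrollment day; positive
  ratings and high self-efficacy step the next check-in to +30 days,
  low self-efficacy to +7. These intervals are configurable
  (`monthly_interval_days`, `weekly_interval_days`).
- **Missingness is treated as potential need**: a missed text or web
  check-in reschedules at +7 days from the prompt day rather than +30.
  A missed web check-in records no content and never feeds the
  escalation counter.
- **Escalation.** "Suboptimal" in the safety rule means {fair, poor}, the
  same partition that triggers the web check-in; a strict variant
  (`escalation_rating: poor`) restricts it to "poor". Consecutiveness is
  operationalised as the two most recent check-ins both qualifying and
  ≤ `escalation_window_days` (14) apart; the safety prompt fires at most
  once per qualifying pair. The care-seeking prompt for *repeated* low
  self-efficacy keys on the consecutive-flag counter reaching 2 and is
  emitted alongside (not instead of) the skill message.
- **Declining the weekly consent ask does not alter scheduling**; the
  protocol description gives no decline branch, so the reply is treated
  as log-only.
- **Horizon.** The program runs 90 days; a check-in that would fall at or
  after the horizon deactivates the participant (active = False,
  quit = False). Texting "quit" is absorbing: no action is ever emitted
  afterwards.
- **Reply parsing** is a case-insensitive, whitespace-tolerant exact
  match on the five rating words (accepting both "very good" and
  "very_good") plus "quit"; anything else is unparseable and consumes
  the single reprompt.

## Messages

Message content is configuration, not code: each action kind has one or
more templates with named placeholders; comparison-tailored feedback
receives `{resolved_list}` / `{persisting_list}` / `{new_list}` built
from the set comparison of consecutive web check-ins (resolved phrased as
improvement, persisting and newly reported items as still unresolved).
Skill messages rotate round-robin without repetition until the library is
exhausted, then recycle; the shipped three-skill library is illustrative
(positive-psychology, cognitive-behavioral, and dialectical-behavioral
flavored one-liners) and is replaced via the config file. Rendering fails
loudly, naming any placeholder with no value.

## Instrument scoring

CCAPS-62, MHSES, and PSSUQ are scored as unweighted means of answered
items. The CCAPS map is structural — subscale sizes 13/9/7/5/9/6/7/6 laid
out as contiguous 0-based index blocks — because item text and
reverse-scoring are instrument-licensed content; no normative cut-points
or distress index are computed. PSSUQ follows the published item→factor
mapping (system usefulness 1–8, information quality 9–15, interface
quality 16–18, overall 1–19). A scale or subscale is scored only when at
least two-thirds of its items are answered, otherwise the score is
missing (None); this tolerance is a package choice, applied uniformly.

## The simulator

`BehaviorProfile` is the generative model of one participant: a
categorical distribution over the five ratings, independent per-item
Bernoulli endorsements for the 6 stressors and 9 negative effects,
P(low self-efficacy | completed web check-in), and per-check-in
nonresponse probabilities. Two features matter for fidelity:

- **Nonresponse semantics.** `p_text_nonresponse` / `p_web_nonresponse`
  are the probabilities that a check-in is missed *outright* (original
  prompt and its reprompt both ignored). Each prompt event is ignored
  independently with probability √p, so two independent chances compound
  to the stated whole-check-in miss rate. The default web value 0.22
  reproduces the ~78% completion the pilot cohort showed.
- **Within-person persistence.** Marginal endorsement rates alone would
  make consecutive reports nearly independent, starving the
  resolved/persisting/new feedback branches. Items therefore follow a
  two-state Markov chain with carry-over c = 0.5:
  P(endorse | previously endorsed) = p + c(1−p) and
  P(endorse | not) = p(1−c), which leaves the stationary marginal at p,
  so long-run frequencies still match the profile. The true within-person
  correlation is unknowable from printed marginals; c is an assumption,
  exposed in the profile.

The default cohort is a two-component mixture: an *at-risk* profile
(suboptimal ratings 60% of check-ins, low self-efficacy 91%, endorsement
rates at the published per-check-in frequencies) with weight 0.62, and a
*mostly-well* profile (suboptimal 5%) with weight 0.38. The weights and
rating distributions were chosen once so that roughly 21 of 34 program
participants report at least one suboptimal rating and the median
per-participant check-in count sits near 5 within the feasible range
[3, 13] (3 = pure monthly cadence on days 0/30/60; 13 = uninterrupted
weekly cadence). Text nonresponse is 0 (the behavior the engagement data
showed). The control arm receives only enrollment and the video-library
link. Per-participant RNGs are spawned from a master `SeedSequence`, so
cohorts are reproducible byte-for-byte and participants independent.

What the simulator does **not** emulate: symptom trajectories or any
treatment effect (scores are out of its scope), time-varying behavior
(profiles are stationary), dependence between rating and endorsements
beyond the shared profile, and sub-day response latencies (all replies
land the day of the prompt or its reprompt). Passing tests therefore
certify the *protocol machinery* — branching, scheduling, escalation,
comparison feedback, analytics — under plausible engagement behavior,
not clinical outcomes in real cohorts.

## Analytics

All summaries are descriptive. Percentages are integers rounded half-up,
matching the reporting style of trial tables; completions never exceed
prompts and a reprompt is part of the same check-in, never a second
prompt. Engagement medians/ranges are computed over participants with at
least one prompt of that channel. Endorsement frequencies use completed
web check-ins as the denominator. Longitudinal score tables report
per-cell mean and sample SD (n−1); a single-observation cell has a
missing SD, an empty cell is absent rather than an error. Inferential
models (GEE/mixed-effects), imputation, and effect sizes are deliberately
out of scope: they are off-the-shelf elsewhere and require
individual-level outcome data this package does not model.

## Numerical and design choices

- Half-up integer rounding for percentages (`floor(100·n/d + 0.5)`).
- Event logs are JSONL with sorted keys, making byte-identity a valid
  determinism check.
- The exhaustive comparison-algebra check runs over all 2⁶ × 2⁶ stressor
  subset pairs; the escalation rule is checked against a brute-force
  oracle over enumerated and randomly generated histories.
- The law-of-large-numbers check of the endorsement generator uses
  ~8,000 completed web check-ins so the ±2-percentage-point band is a
  ≥4σ test per item rather than a coin flip at the 2,000 minimum.
- Problem sizes in the test suite (10⁴ fuzzed streams, 3,000-participant
  LLN cohort) complete in seconds; they were sized for statistical
  resolution, not machine limits.

## Known limitations

- The engine models one participant at a time; cross-participant
  features (e.g., shared counselor load) are out of scope.
- Message templates are plain `str.format` substitution; no NLG, no
  localisation.
- The CCAPS scorer cannot produce clinically interpretable scores
  without the licensed item map (reverse scoring, norms).
- Care-use tables consume externally supplied indicator data; the
  simulator does not generate care-seeking behavior.
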
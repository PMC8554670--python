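# mostmh

An adaptive text-message mental-health check-in engine — a faithful,
testable implementation of a just-in-time adaptive intervention (JITAI)
for young adults with mental-health diagnoses transitioning to college —
together with a behavior-calibrated cohort simulator, scorers for the
standard self-report instruments, and descriptive engagement analytics.
It is written for digital-health researchers and engineers who want to
replay, stress-test, or power-plan this class of stepped-care messaging
protocol without a live SMS gateway.

## The protocol

Each enrolled participant is a small deterministic state machine driven
by a whole-day clock over a 90-day horizon:

1. **Text check-in** (first one on the enrollment day): *"How would you
   rate your emotional health this past week?"* with rating
   r ∈ {excellent, very good, good, fair, poor}.
2. **Branch.** r ∈ {excellent, very good, good} → positive feedback plus
   a psychoeducation video link, and the next check-in is **stepped down**
   to t + 30 days. r ∈ {fair, poor} → a **web check-in** link.
3. **Web check-in**: checklists of 6 stressors and 9 negative effects and
   one self-efficacy item s ∈ {completely, somewhat, a little, not at
   all}. s = completely behaves like a positive rating (t + 30);
   s ≠ completely delivers a coping-skill message (round-robin from a
   configurable library), the video link, a consent ask for a weekly
   follow-up, and **steps up** to t + 7.
4. **Tailoring.** From the second completed web check-in on, feedback
   carries the set comparison against the prior report: resolved
   (prior ∖ current), persisting (prior ∩ current), new (current ∖ prior).
   A second consecutive low-self-efficacy report adds a care-seeking
   prompt.
5. **Safety escalation.** Two consecutive qualifying check-ins
   (suboptimal rating ∧ low self-efficacy) ≤ 14 days apart trigger a
   formal care-seeking safety prompt.
6. Every prompt is reprompted once (next day); still unanswered two days
   later it is marked missed and the participant is re-approached in
   7 days. Texting *Quit* is absorbing.

The simulator closes the loop: a `BehaviorProfile` (rating distribution,
per-item endorsement probabilities, P(low self-efficacy), nonresponse
rates) answers the engine's prompts day by day, producing protocol-valid
JSONL event logs. The default two-profile mixture is calibrated to the
engagement behavior of a published 34-participant pilot cohort: 100% text
completion, ~78% web completion, low self-efficacy on 91% of completed
web check-ins, and published per-check-in endorsement rates (school 51%,
feeling worn out 65%, ...).

Instrument scorers cover CCAPS (62 items, 8 subscales, 0–4), MHSES
(6 items, 1–10), and PSSUQ (19 items, 1–7, overall + 3 factors); all
scores are unweighted means of answered items with a ≥ 2/3 answered rule.

## Worked example

```
most simulate --n 52 --arm-ratio 2:1 --horizon 90 --seed 7 --out cohort.jsonl
most report --events cohort.jsonl --out report/
```

prints (seed 7):

```
participants: 52
text check-ins prompted: 167, completed: 167 (100%)
web check-ins prompted: 84, completed: 62 (74%)
text check-ins per participant: median 4.0, range 3-10
web check-ins per prompted participant: median 3.0, range 1-10
stressors per check-in: median 2.0, range 0-5
negative effects per check-in: median 4.0, range 0-6
self-efficacy: high 16%, low 84%
```

Reading this: all 167 text prompts across the 34 program-arm participants
were answered (the 18 control-arm logs contain only the video-library
link, so they contribute no prompts); 74% of triggered web check-ins were
completed, near the 78% calibration point; per-participant check-in
counts span 3 (a participant who always rated positively: days 0, 30, 60)
up to weekly cadences; and participants report fewer stressors than
negative effects per check-in, with low self-efficacy dominating.

`most run --events cohort.jsonl --config examples/config.yaml --out
actions.jsonl` replays any recorded inbound stream through the engine
deterministically and renders every outbound message.

The same workflow is available as a library:

```python
import mostmh as m

logs = m.simulate_trial(n_mostmh=34, n_euc=18, seed=7)
summary = m.engagement_summary(logs)
print(summary.web_completion_pct)          # integer percent, half-up
print(m.endorsement_frequencies(logs).negative_effects["feeling_worn_out"])
```

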
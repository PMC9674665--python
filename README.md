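# ecoach

Personalized physical-activity eCoaching analytics for wearable data.

`ecoach` is for digital-health researchers and engineers who want to turn
daily wearable summaries (step counts and low / moderate / vigorous
physical-activity minutes — LPA / MPA / VPA) into five-class daily
activity levels, train and personalize classifiers on those levels, and
generate rule-based weekly recommendation messages that are explainable
and exportable as an RDF knowledge graph.

## What it computes

**Daily activity level.** Each day receives a level and score from a
deterministic rule table built on the WHO moderate-equivalent convention
(1 vigorous minute = 2 moderate minutes). With
W = (2·VPA + MPA)·7 (the weekly moderate-equivalent projection of one day):

| level | rule | score |
|---|---|---|
| sedentary | steps < 5000 | 0 |
| low active | (steps > 4999 ∧ 90 ≤ W < 210) ∨ 4999 < steps < 7500 | 1 |
| active | (steps > 4999 ∧ 210 ≤ W < 300) ∨ 7499 < steps < 10000 | 2 |
| medium active | (steps > 4999 ∧ 300 ≤ W < 360) ∨ 9999 < steps < 12500 | 3 |
| highly active | (steps > 4999 ∧ W ≥ 360) ∨ steps > 12499 | 4 |

Overlapping rules resolve to the highest matching score. Per-minute
sensor streams are supported too: IMA counts band into LPA (0–400),
MPA (401–800) and VPA (≥ 801), every minute honours a strict 60-second
budget, and minutes aggregate to hours and days.

**Learning protocol.** Candidate classifiers (SVC, naive Bayes, decision
tree, random forest, k-NN, dummy baseline) are ranked by repeated
stratified 5-fold cross-validation with grid search; the best model is
pretrained globally, transferred per participant (refit of the selected
architecture + tuned hyperparameters on the pooled global + personal
data), and updated incrementally each day from its own predictions, with
a monthly global rebuild.

**Recommendations.** Weekly goal score = the sum of the seven daily
scores, compared against a preference-defined target (default 21 =
medium active every day). A propositional rule base — five activity rules
plus an exactly-one satisfiability rule, checked by exhaustive
enumeration — maps outcomes to formal/informal messages with a
binary-tree evaluation trace. Everything exports to RDF/Turtle and is
queryable with SPARQL.

## Worked example

```python
from ecoach import ActivityLevel, Preferences, weekly_evaluate, render_notification

levels = [ActivityLevel(x) for x in (1, 1, 3, 2, 1, 1, 1)]
report = weekly_evaluate(levels, Preferences(), participant_id="P-1")
print("achieved   :", report.achieved)
print("difference :", report.difference)
print("formal     :", report.formal_message)
```

prints

```
achieved   : 10
difference : 11
formal     : You are 11 points behind to reach your weekly goal. Work hard on the following week.
```

The participant scored 10 of the 21-point weekly target (scores
1+1+3+2+1+1+1 over the seven predicted daily levels), so the shortfall
is 11 points, the emoji category is *improve* and
`render_notification(report)` shapes the message into a text push
notification scheduled at the preferred 08:00 delivery time.

The same flow is available from the shell:

```bash
ecoach simulate --format fitbit --participants 5 --days 30 --out daily.csv
ecoach label --in daily.csv --out labeled.csv
ecoach recommend --levels 1,1,3,2,1,1,1
ecoach check-rules
ecoach export-rdf --in daily.csv --out graph.ttl
```

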
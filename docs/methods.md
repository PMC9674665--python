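# Methods

This note documents the models and procedures implemented in `ecoach`,
the assumptions behind them, and the design choices made where the
problem was genuinely open.

## Daily activity scoring

The scoring core is a deterministic five-class rule table over a day's
step count and intensity minutes. Intensity is expressed as the weekly
moderate-equivalent projection W = (2·VPA + MPA)·7, using the convention
that one vigorous minute counts as two moderate minutes; the thresholds
90 / 210 / 300 / 360 weekly minutes and the step cut-points 5,000 /
7,500 / 10,000 / 12,500 separate the levels sedentary (0) through highly
active (4).

The printed rules are disjunctions of a step clause and an intensity
clause and they overlap (e.g. 6,000 steps with W = 250 satisfies both
the low-active step clause and the active intensity clause). No
precedence is stated with the rules themselves, so the labeler evaluates
levels from the highest score down and returns the first match,
crediting the stronger activity evidence. Under this resolution the
rules are total: any day below 5,000 steps is sedentary regardless of
intensity, and the step clauses tile [5,000, ∞). The vacuous "LPA ≥ 0"
conjunct of the sedentary rule is kept as written. The label score is
non-decreasing in steps when intensity is held at zero, and the labeler
is property-tested against an independently coded literal transcription
of the five rules on boundary grids and random days.

Activity minutes are stored as floats: mean imputation produces
fractional minutes, and fractional minutes are also needed to realise
arbitrary weekly-equivalent values (W is otherwise restricted to
multiples of 7). Step counts stay integral and are rounded after
imputation.

Per-minute IMA counts band into LPA (0–400), MPA (401–800) and VPA
(≥ 801 counts/min), a partition of the non-negative axis. Each sensor
minute must satisfy the 60-second budget — sedentary + weight-bearing +
standing + LPA + MPA + VPA seconds = 60 — exactly; violating rows are
rejected at ingest with their row index. Aggregation sums seconds over
the whole day before integer-dividing by 60, avoiding per-minute
truncation bias; an hourly intermediate is exposed for inspection.
Participants with fewer than 30 distinct days are dropped by the
retention filter (configurable).

## Synthetic data

The generator emulates both supported data shapes with known ground
truth, so the full pipeline is testable without external data. For daily
data, each participant-day draws a target level from a configurable
class mix (default 0.30/0.25/0.20/0.15/0.10, skewed toward
sedentary/low-active as cohort wearable data typically is), then samples
steps uniformly inside the level's step band and intensity minutes
uniformly below the next level's weekly threshold (daily
moderate-equivalent caps 12/29/42/51). This makes the labeler recover
the target exactly for every day — a construction invariant, tested over
many seeds — and makes the label a deterministic function of the
features. Uniform within-class draws are the least committal choice
given that the rule table specifies boundaries, not distributions; the
ranges are configurable. Sedentary time is the 1,440-minute day minus
active minutes minus a uniform non-wear allowance of up to 4 hours.

Minute streams fill each day with single-category minutes whose counts
realise the day's target level after aggregation; IMA is drawn from the
minute's band and the day's step total is spread over active minutes
with intensity-proportional multinomial weights. A fully sedentary day
is all sedentary minutes with zero steps. The generator does not attempt
physiological realism: no heart rate, gait, circadian structure or
within-day behavioural patterns. Consequently, passing tests demonstrate
the correctness of the pipeline mechanics and the by-construction
separability of rule-derived labels — not classifier performance on real
wearables, where labels are noisy functions of measured features.

Missingness is injected independently per numeric cell at a configurable
rate; mean imputation replaces each gap with the per-participant mean of
the observed values of that field and errors out if a field is entirely
missing for a participant.

## Evaluation metrics

Metrics derive from a 5×5 confusion matrix (rows actual, columns
predicted) via one-vs-rest cells per class, combined by support-weighted
averaging, and are reported on the 0–100 scale. Two printed formulas in
the source tables are internally inconsistent and the standard forms are
implemented instead: specificity is TN/(TN+FP) (not 1 − sensitivity,
which is not an identity), and MCC uses the standard multiclass R_k
generalisation (scaled ×100), since the printed MCC expression contains
a spurious leading TP factor. Both choices are cross-checked against
scikit-learn in the test suite. A class that is never predicted gets
precision 0 with a warning. Weighted one-vs-rest recall coincides with
accuracy by construction; the tests assert this identity.

Normality screening runs Shapiro–Wilk, D'Agostino K² and
Anderson–Darling at α = 0.05 (for Anderson–Darling, the critical value
at the tabulated level closest to α); constant samples are flagged
degenerate. Feature pruning computes the pairwise Spearman matrix and
greedily removes one feature from each pair with |r| ≥ 0.72, dropping
the member with the larger mean absolute correlation to the remaining
features (alphabetical tie-break); the threshold comparison carries a
1e-9 closeness guard so the inclusive boundary survives floating-point
rank-correlation round-off. Constant features are excluded from pruning
decisions. The final feature set is the intersection of two candidate
sets minus an exclusion list (default: `calorie`), yielding
{sedentary, LPA, MPA, VPA, steps} for the canonical inputs.

## Learning protocol

Ranking uses shuffled stratified 5-fold cross-validation (default
`seed = 7`) repeated 5 times; within every outer training split a grid
search (3-fold inner CV — the outer k is prescribed, the inner split is
an economy choice) tunes the spec's hyperparameters, the held-out fold
is scored, fold confusion matrices pool into one per-repetition report
and reports average over repetitions. The decision-tree grid is
criterion ∈ {gini, entropy} × max_depth ∈ {2, 4, 6, 8, 10, 12}. The
best model is chosen by mean accuracy with MCC as tie-break. Everything
is deterministic under a fixed seed.

Transfer for classical estimators cannot reuse gradient state, so what
transfers is (a) the globally selected architecture, (b) its globally
tuned hyperparameters and (c) the global training pool: the local model
is a refit on global-pool ∪ personal rows. This follows the
combined-dataset reading of the protocol; `include_global_data=False`
gives the narrower refit-on-personal-only variant. The from-scratch
baseline used in the transfer comparison applies the same grid-search
protocol to the personal rows alone. Local models are disjoint across
participants.

Incremental updating predicts day n with the current local model, then
appends the day's features with the *predicted* label (as the protocol
states; `use_true_label=True` switches to the rule-derived label as a
safe mode) and refits for day n + 1, bumping the local version. The
monthly rebuild refits the global model on the union of all active
participants' accumulated pools; ended participants are excluded via an
active flag, and local models are untouched.

Stores persist with joblib under a JSON manifest carrying a schema
version and the feature-set signature; loads with a mismatched signature
or schema version are rejected.

On synthetic data the labels are an exact function of the features, so a
sufficiently deep decision tree reaches ≥ 99% held-out accuracy; this
separability property is what the test suite and acceptance checks
assert. Problem sizes used there: a pretraining cohort of 20
participants × 60 days, and a transfer comparison of 50 seeds × (10
personal + 30 evaluation days) with a one-sided sign test at α = 0.05.

## Recommendation rules

Antecedents are propositional formulas over named variables with NOT,
AND, OR and IMPLIES (precedence in that order, IMPLIES
right-associative), parsed by a small recursive-descent parser. The
default base holds one activity rule per level — antecedent the one-hot
level variable, consequent a daily proposition A-1…A-5 — plus one
satisfiability rule ("Rule-6"). Rule-6's printed form is narrative, so
it is implemented as a meta-constraint: exactly one "once a day"
proposition may fire per input, verified by exhaustively enumerating the
truth assignments reachable from the five-level input domain (bounded at
20 variables). Daily evaluation returns the fired proposition, its bound
message and a binary-tree trace — (rule, decision) edges ending at the
message leaf — for explainability.

Weekly evaluation sums the seven daily scores, compares against the
preference target (default 21; capped at 28 = 7×4) and reports
difference = target − achieved, which may be negative; the exceeded case
renders as "ahead by N points" (only the behind case is illustrated in
the source material). Emoji banding has no printed thresholds; the
implemented monotone banding is well-done at ≥ 100% of target,
satisfactory at ≥ 80%, improve below — consistent with the worked
example (10/21 → improve) — and is configurable. The guideline
constraints (weekly moderate-equivalent minutes > 150, daily floor
≥ 21.45 as printed — slightly above 150/7, kept as stated — daily score
≥ 3, weekly score ≥ 21) are reported as booleans, not optimized. The
weekly outcome propositions map to A-9/A-10/A-11; the full A-code
catalog lives in an appendix artifact that is not part of the main text,
so the defaults here are a reconstruction consistent with the codes that
do appear (A-2 low active, A-3 active, A-4 medium active, A-11 improve),
and identifiers are remappable. Co-fired auxiliary codes seen in the
worked table (A-7…A-9 on daily rows) have no printed definitions and are
not reconstructed.

## Knowledge graph

The RDF export is a data projection, not a reasoning artifact: rule
logic executes natively in the recommendation engine, and no OWL-DL
reasoning is performed. Participants link to status, preferences,
recommendations and a personal activity-data container; the container
node is typed as both PersonalData and ActivityData because the printed
object properties provide Participant→PersonalData and
ActivityData→ActivityDataValue links but no direct
Participant→ActivityData property. Daily observations carry their
measured quantities, derived level and score, and a time-stamped
temporal entity. Data properties (steps, scores, message text, …) are
package-defined schema extensions, as the source property table lists
only object properties. Every emitted triple is validated against the
schema (declared predicate, compatible domain/range for object
properties); cardinality annotations (Some/Only) are recorded as
metadata and enforced only as minimum counts where decidable at the
data level. IRIs are minted under a configurable base namespace with
pseudonymous participant ids. Turtle serialization round-trips the
triple set exactly, and SPARQL SELECT/ASK queries are answered by
rdflib.

## Known limitations

- Within-class uniform sampling understates the boundary density of real
  behaviour; real data would yield lower classifier accuracy than the
  by-construction separable synthetic cohorts.
- The transfer benefit is demonstrated directionally on synthetic data;
  its magnitude is not comparable to results on real wearables.
- The rule engine covers the propositional fragment only; no
  description-logic reasoning, and the monthly goal maximization is
  exercised as constraint checking, not solved as an optimization.
- Weight-bearing and standing seconds are retained in minute records but
  excluded from the classification feature set, matching the scoring
  scope (age, gender and weight adjustments are likewise out of scope).
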
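# Methods

## The instrument and its scoring model

ACTE-MTB grades the maturity of a molecular tumor board (MTB) on a
five-level capability-maturity scale in four domains — Access,
Consultation, Technology, Evidence. The survey has 59 questions in seven
categories; 56 are required multiple-choice and the final three are
optional free text. The first question gates participation: a respondent
who answers "no" to taking part in an MTB exits the survey, and the reader
drops such rows with a logged reason.

Twenty questions are scored, five per domain. Each scored question
distributes at most 5 points over its answer options, graded 1–5 along the
question's natural ordering (increasing percentages, quantities or
complexities; binary questions map to {1, 5} so the per-question budget is
preserved). A domain therefore attains at most 25 points, divided by 5 to
give a continuous maturity score in [0, 5]. The maturity level is the
integer band of the score: score in ((n−1), n] → level n, with everything
at or below 1 mapped to level 1; the boundary convention (a score of
exactly n belongs to level n) is fixed and tested. The overall score is
the arithmetic mean of the four domain scores, carried at full floating
precision.

### Option→point mappings

The published instrument does not enumerate its per-option point values,
only the grading principles and worked examples. The shipped
`acte_mtb_v1` rubric therefore encodes each of the twenty scored questions
with a monotone 1–5 mapping over its stated response type. The engine
treats the rubric purely as data — questions, options, points and
aggregation rules all live in one validated YAML file — so a different
mapping drops in without code change, and several tests run on small
synthetic rubrics built programmatically.

### Multi-select aggregation

The instrument does not state how multi-select answers aggregate. Three
rules are supported, declared per question in the rubric, all preserving
the 5-point budget:

- `max` (default): the best selected option counts;
- `sum_capped`: selected option points sum, capped at 5 (used for the
  structured-documentation question, whose parts are worth 1.5/1.5/2);
- `count_banded`: min(5, number of selections) (used for the
  participating-roles question — breadth of attendance is the signal).

Rubric validation is rule-aware: the *attainable* per-question maximum
must equal 5 under the declared rule (for `sum_capped` that is the capped
total, for `count_banded` the capped option count), which generalizes the
plain "best option is worth 5" requirement to the two set-valued rules.

### Missing answers

The study normalized a domain with one skipped question "over a
denominator of 25". Two readings exist; the default here rescales the
answered sum by 5/n_answered — equivalently, the domain score is the mean
per-question points of the answered questions — so a skipped question does
not depress the score. The literal missing-as-zero reading is available
as `missing_policy="zero"`. A domain with no answered scored question is
not assessable: NaN in permissive mode, an error naming the domain in
strict mode. Unanswered questions are a distinct missing marker
everywhere; they are never silently worth 0 points.

### Reporting precision

Scores are computed and stored at full precision; presentation rounds
half-up to one decimal (therefore 3.85 → 3.9, 3.075 → 3.1). Rounding is
implemented over the decimal representation, not binary floats, so values
that print as x.x5 round up as a reader would expect. p-values print at
the precision of the published comparisons (3 and 2 decimals).

## Cohort statistics

Boards stratify into academic (academic medical centers) vs. non-academic
(community hospitals, specialized cancer clinics, private practices).
Group summaries report mean ± standard error with the n−1 sample standard
deviation. Group differences use the two-sided two-sample Student's
t-test with pooled variance and df = n₁+n₂−2 (scipy's equal-variance
test; Welch via a flag). Pooled, not Welch, is the default because the
published headline comparison (t ≈ 2.59, df 18, p = .018 on 9 vs. 11
overall scores) is a pooled-variance result. Degenerate zero-variance
input is handled explicitly: equal means give t = 0, p = 1; unequal means
would be an infinite statistic and raise. The hand-written textbook
formula appears only in the tests, as an independent oracle against the
scipy-backed implementation (agreement to 1e-10 on random inputs).

Therapy implementation rates come from the Access-domain implementation
question: each percentage band carries a representative value (25, 50,
75, 100) declared as `numeric_value` in the rubric, and an "I'm not sure"
answer is imputed at 25%, the convention the validation table states in
its footnote. The values are rubric data, not constants in code.

The per-category dispersion summary expresses each value's squared
deviation as a percentage of the category's mean squared deviation
(population convention), making the per-category average exactly 100% by
construction; constant input is flagged rather than divided by zero. This
is one consistent reading of the published "% variance from the mean"
figure, which is not fully defined; its printed summary numbers are
deliberately not asserted anywhere.

## The packaged validation fixture

The fixture transcribes the published per-board validation table: 20 rows
of institution type, country, overall and four domain scores, and therapy
implementation rate, checksum-pinned (sha256) at load. It stores
*scores*, not raw answers — the raw responses were never published — so
fixture-based commands start at the assessment layer while raw-answer
workflows use simulated cohorts. Two print inconsistencies are carried as
metadata rather than corrected: the South Korea academic row prints
overall 3.0 while its printed domains average 3.1 (the overall was
evidently computed from unrounded domain scores), and the third Germany
community row prints 3.9 against a domain mean of 3.65, inconsistent
beyond rounding. Four rows carry the "I'm not sure" implementation-rate
imputation flag.

## Radial stoplight charts

One chart has 20 wedges, contiguous per domain, clockwise from 12 o'clock
in the order Access → Consultation → Technology → Evidence with questions
in rubric order (configurable). Each wedge stacks five unit segments
colored by the five-class red–yellow–green ColorBrewer RdYlGn palette
(level 1 red … level 5 green; an RdYlBu colorblind-safe variant is
bundled and any five-color scale can be supplied). Segments fill
bottom-up to the attained points, with fractional points partially
filling the top segment; unanswered questions render as hatched empty
wedges. One or two assessments render per document (the two-panel form is
the highest-vs-lowest comparison). Output is SVG (canonical) or PNG; the
SVG backend runs with a fixed hash salt and dateless metadata, so
rendering is a pure function of (assessments, options, palette) and
byte-identical across runs. Wedge labels paraphrase the question prompts
as short phrases stored in the rubric (`short_label`).

## Synthetic cohorts

The generator emulates the study design — two strata of sizes 9 and 11
with academically higher latent maturity — without claiming to reproduce
real answer distributions. Each respondent draws a latent maturity m from
a Normal(μ, σ) truncated to [0, 5]; each scored answer draws from the
question's attainable point grid with probability ∝
exp(−(points − m)²/(2τ²)). As τ → 0 the nearest-point option is chosen
almost surely; large τ approaches uniform choice. For set-valued rules
the sampled point target is realized by a concrete selection (a k-subset
for `count_banded`, the smallest subset summing to the target for
`sum_capped`), keeping the latent→points link exact under every rule.
Unscored questions fill uniformly (the gating answer is always "yes";
institution type comes from the stratum), giving complete, round-trippable
59-column records.

Defaults: τ = 0.6 and σ = 0.5 give overall-score spreads comparable to
the validation cohort's (SE ≈ 0.2 at n ≈ 10); stratum means 3.7/3.1
mirror the published group means, and the null configuration pins both
strata at the grand mean 3.3. Reproducibility uses one master seed with
per-respondent substreams keyed by (stratum label CRC, respondent index),
so cohorts are byte-stable and invariant to stratum reordering.

`recovery_experiment` estimates the power (or, with equal stratum means,
the type-I error) of the pooled t-test on overall scores across seeded
replicates, reporting the rejection rate with its binomial Monte-Carlo
standard error. It uses a vectorized sampler implementing the same kernel
law (unit-tested against `sample_answer` by a two-sample chi-squared
test, and its p-values against `students_t_test` analytically), which
makes 2000 replicates run in well under a second. Limitations worth
noting: the latent-to-answer law is a modeling device — passing tests
show the pipeline is correct and the design calibrated under this law,
not that real respondents behave this way; answers are independent across
questions given m, with no role- or country-specific response styles.

## Problem sizes and numerical choices

The test suite runs the full property checks at hypothesis defaults, the
convergence check at n = 5000 respondents (mean overall within 0.05 of μ
at τ = 0.25, σ = 0.3), and the null calibration at 2000 replicates of the
9-vs-11 design (rejection rate within 3 Monte-Carlo SEs of α = 0.05) —
the whole suite completes in well under a minute. Equality tolerances:
exact float identity where the computation is literally the same
expression (overall = mean of domains), 1e-12 for algebraically equal
rearrangements, 1e-10 for the t-test oracle. The acceptance script's
fixture statistics are fully deterministic; only the null-calibration
replicates consume the seed.
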
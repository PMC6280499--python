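# Methods

## Problem setting

Adverse drug events (ADEs) — harm from the use or misuse of a medication —
are a leading cause of emergency department visits and unplanned
admissions. Whether an ADE was *preventable* is a judgment call, and the
judgment depends heavily on the instrument used to make it. `adeprev`
implements the quantitative machinery of a dual-reviewer preventability
study: two clinicians (a pharmacist and a physician) independently rate
every event on a three-level scale (definitely / probably / not
preventable) under three instruments — a best-practice definition, an
error-based definition, and the modified Schumock–Thornton algorithm —
discordant pairs are reconciled by discussion or third-reviewer
adjudication, and agreement is summarised with Cohen's kappa and binomial
proportions.

The two definition-based instruments are human-judgment definitions; their
ratings enter the pipeline as data. Only the algorithm is mechanised,
because it *is* a mechanical instrument: eighteen yes/no/uncertain
questions whose affirmative answers force the rating.

## The rule engine

The modified Schumock–Thornton algorithm has 18 top-level questions plus
two nested follow-ups. Two questions are pure gates: Q1 (history of
allergy or previous reaction) enables Q1a (was the re-exposure
inappropriate?), and Q9 (preventative measures not given) enables Q9a
(were they not contraindicated?). Every non-gate question is a trigger:

- **definite triggers** (force "definitely preventable"):
  1a, 2, 3, 4, 5, 10, 12, 13, 14, 15, 17, 18;
- **probable triggers** (force "probably preventable"):
  6, 7, 8, 9a, 11, 16.

Classification is `DEFINITELY` if any definite trigger fires, else
`PROBABLY` if any probable trigger fires, else `NOT_PREVENTABLE`. A
trigger fires when its answer is YES and its gate (if any) is YES.
Three choices the instrument's published form leaves open:

- **UNCERTAIN never fires.** The instrument specifies consequences only
  for YES answers; treating UNCERTAIN as NO is the conservative reading
  and makes UNCERTAIN↔NO substitution a provable no-op (property-tested).
- **Definite dominates probable regardless of count.** Implied by the
  footnote structure; made explicit so that multi-trigger forms are
  well-defined.
- **Follow-up answers are dead while their gate is not YES.** Forms may
  carry any value there; the engine ignores it.

Question polarity follows the canonical instrument wording (Q1a asks
whether the re-exposure was *inappropriate*, so YES fires). Collection
forms written in the opposite dialect ("was the re-exposure appropriate?")
are normalised at read time via `read_forms(..., invert=("1a",))`, which
swaps YES/NO for the named columns and logs the normalisation.

`attribute` returns every fired trigger with its severity; the maximum
severity reproduces the classification (invariant, tested on random
forms), and `criterion_frequency` tabulates how often each criterion
contributed. The percent denominator is a policy: `all_events` (every
attribution supplied) or `definite_events` (events classified definitely
preventable) — published frequency tables of definite triggers are
naturally reported over the latter subset, but both readings are exposed
because source reports do not always state which was used.

## Consensus

Consensus outcomes are **inputs**, never computed: discussion between
raters and adjudication by a third reviewer are human processes, and
fabricating them algorithmically would misrepresent the design. A
resolutions table carries `discussion_rating` and `adjudication_rating`
per discordant (event, method); discussion takes precedence, adjudication
is consulted only when discussion is absent, and a discordant pair with
neither is a hard error naming the events. The discussion outcome is not
constrained to equal either original rating. Concordant pairs are final
as-is.

## Agreement statistics

Cohen's kappa on a k×k contingency table uses
κ = (p_o − p_e)/(1 − p_e), with the asymptotic standard error
SE = √(p_o(1 − p_o) / (n(1 − p_e)²)) and CI κ ± z·SE truncated to
[−1, 1]; z is the normal quantile at the configured confidence (default
0.95), never a hard-coded 1.96. This SE is the classical large-sample
form; when the underlying cross-tabulations of a published study are
unavailable its kappas cannot be re-derived, so the implementation is
validated against an independently coded oracle and sklearn's point
estimate instead.

Binomial proportions use the Wald normal approximation
p̂ ± z·√(p̂(1−p̂)/n), clipped to [0, 1] (computed via
`statsmodels.stats.proportion.proportion_confint`); the Wilson score
interval is available as an option but is not the default because the
Wald form is what reproduces published preventability tables from their
counts at cohort sizes in the hundreds-to-thousands.

Two inter-rater analyses are provided per method: **binary** (definitely +
probably collapsed to "preventable", all events) and
**definitely-vs-probably** on a preventable subset. The subset policy is
genuinely open in retrospective reports, so both readings are exposed:
`consensus_preventable` (default: events whose consensus rating under the
method is preventable — matches the n's published alongside such tables;
events where an original rating is NOT_PREVENTABLE are then dropped with a
logged count, since a two-level cross-tab cannot hold them) and
`both_raters_preventable` (a pre-consensus reading needing no consensus
table). Between-method agreement uses binary-collapsed consensus ratings
restricted to common events.

### Percent formatting

Report percents are rounded half-up **sequentially**: to two decimals,
then to one. Published tables in this literature are typically assembled
from spreadsheets displaying hundredths of a percent, and the printed
one-decimal figure is the rounding of that intermediate (e.g. 144/508 =
28.3465% → 28.35 → 28.4, where one-step rounding would give 28.3).
Sequential rounding reproduces every row of the criterion-frequency table
and 33 of 36 consensus-proportion values from their counts. The three
exceptions are irreproducible under *any* single convention and are
documented, not imitated: 930/1356 prints as 68.5 (computes 68.6),
873/1356 prints as 64.3 (computes 64.4), and the lower bound of 426/1356
prints as 28.9 (28.9453 computes to 29.0 through hundredths).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, so
the whole pipeline is testable with no chart-review data:

1. **latent category** per event from `category_prevalence` — default
   (0.359, 0.577, 0.064) over (not / probably / definitely), the
   consensus mix of a best-practice assessment in an emergency-department
   cohort;
2. **method truth** per (event, method) through a per-method 3×3 confusion
   matrix — identity for best-practice, near-identity (0.985 diagonal) for
   error-based, and a definite-shifted matrix for the algorithm (most
   latent "probably" events become "definitely"), reproducing both the
   algorithm's over-calling of definite preventability and the
   high-but-imperfect between-method agreement regime (κ ≈ 0.8–0.95);
3. **observed ratings**: each rater draws independently from the method
   truth through their own 3×3 confusion matrix. Conditional independence
   of raters given the truth is a known simplification — real rater errors
   are likely positively correlated (shared records, shared training), so
   empirical kappas on real data would sit above what the same marginal
   error rates produce here;
4. **criterion forms** (algorithm method only): one firing trigger sampled
   from `definite_trigger_mix` (default: the observed attribution
   frequencies of an emergency-department cohort — re-exposure and toxic
   drug levels dominate) or `probable_trigger_mix` (uniform; no published
   data), gate set YES for nested triggers, everything else NO or
   UNCERTAIN with probability 0.05. Every generated form classifies back
   to exactly the rating it was built for (invariant, tested at 100%);
5. **resolutions**: discussion outcome = method truth; with probability
   0.1 the case escalates to adjudication instead.

Defaults: n_events = 1356 (the study-scale cohort), a single
`numpy.random.default_rng(seed)` stream with the draw order fixed as
listed, so a seed pins the dataset byte-for-byte across runs and releases.

**Calibration.** The default rater confusion is symmetric (accuracy *a* on
the diagonal, errors split evenly) with *a* solved by Brent's method so
the *analytic* inter-rater binary kappa — computed exactly by enumerating
the latent × observed-pair probability table, no sampling — equals 0.55,
the middle of the inter-rater range such studies report. Parameter
recovery is then a real test: the empirical kappa at n = 1356 must fall
within ±3 asymptotic SEs of the analytic value in ≥ 95% of 200 seeded
replicates. The generator is deliberately *not* calibrated to reproduce
published kappa tables as outputs — those would be inputs, not
validations.

What the generator does **not** emulate: correlated rater errors,
event-level covariates (drug class, severity), multiple ADEs per patient,
rater drift over time, and any relationship between the two
definition-based instruments' criteria and the algorithm's questions
beyond the shared latent category. Passing tests therefore demonstrate
the pipeline's correctness on data with the assumed structure, not the
clinical validity of any instrument.

## Pipeline and reports

`run()` produces five tables: consensus proportions with CIs per method,
binary inter-rater kappas, definitely-vs-probably kappas,
between-method kappas, and criterion frequencies (computed from the
pharmacist's forms, matching the convention of attributing criteria via
the pharmacist's assessment). Every cell carries a full-precision value
plus its formatted string; the machine-readable `summary.json` can
regenerate the formatted CSVs byte-identically (`adeprev report`).
Reports contain no timestamps — a repeat run on the same inputs (or seed)
is byte-identical, and file-mode metadata records input SHA-256 digests so
any report is traceable to exact inputs.

In file mode, ALGORITHM ratings present in the ratings file are taken as
recorded (they are the raters' own instrument applications); `validate`
flags any that contradict the engine's classification of the
corresponding form. When ALGORITHM rows are absent entirely, they are
derived from the forms by the engine.

Degenerate cases: a contingency table with all mass in one diagonal cell
has p_e = 1 and p_o = 1 and is reported as κ = 1 with a point CI; p_e = 1
with p_o < 1 raises (unreachable for real tables but guarded); an empty
definitely-vs-probably subset and n = 0 proportions raise informative
errors rather than returning NaN.

## Problem sizes

Unit and property tests run at n ≤ 2000 events (full truth-table
enumeration is 3⁷ = 2187 reduced forms); the acceptance checks run the
parameter-recovery study at the full cohort scale of n = 1356 × 200
replicates and the end-to-end determinism check at n = 1356.
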
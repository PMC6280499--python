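# adeprev

Adverse drug event (ADE) preventability analysis: a rule engine for the
modified Schumock–Thornton algorithm, a dual-reviewer consensus workflow,
agreement statistics, and a synthetic rater-cohort generator.

## Who this is for

Pharmacoepidemiology and patient-safety groups running (or re-analysing)
chart-review studies in which two clinicians — typically a pharmacist and
a physician — independently rate each ADE as **definitely**, **probably**
or **not preventable** under one or more instruments, reconcile
discordant ratings by discussion (with third-reviewer adjudication as a
fallback), and report agreement. The package mechanises everything in
that design that *is* mechanical; the human judgments (definition-based
ratings, discussion outcomes) enter as data.

## The core methods

**Rule engine.** The modified Schumock–Thornton algorithm poses 18
yes/no/uncertain questions (two with nested follow-ups behind gate
questions). Each non-gate question is a trigger: YES on a *definite*
trigger (ids 1a, 2, 3, 4, 5, 10, 12–15, 17, 18) forces "definitely
preventable"; YES on a *probable* trigger (6, 7, 8, 9a, 11, 16) forces
"probably preventable"; definite dominates probable; no fired trigger
means "not preventable". UNCERTAIN never fires.

**Agreement.** Cohen's kappa κ = (p_o − p_e)/(1 − p_e) with the
asymptotic standard error √(p_o(1 − p_o)/(n(1 − p_e)²)) and a 95% CI;
binomial proportions with Wald intervals p̂ ± z·√(p̂(1−p̂)/n). The
three-level scale can be collapsed to preventable vs not (definitely +
probably merged), which is both how headline preventability rates are
reported and the more reliable scale between raters.

**Synthetic cohorts.** A seeded generator draws a latent preventability
category per event, passes it through per-method and per-rater confusion
matrices, and emits criterion forms that the engine classifies back to
exactly the generated ratings — so the whole pipeline is testable end to
end with no patient data. An exact (enumeration-based) expected-kappa
routine lets you calibrate rater noise to a target agreement level.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from adeprev import (classify, attribute, ResponseForm,
                     wald_proportion_ci, cohens_kappa, ContingencyTable)
from adeprev.algorithm import ALL_IDS

# one rater's completed algorithm form: allergy history with an
# inappropriate re-exposure, plus a drug interaction
responses = {cid: "NO" for cid in ALL_IDS}
responses.update({"1": "YES", "1a": "YES", "7": "YES"})
form = ResponseForm("E0001", "pharm-1", responses)

print(classify(form).name)          # DEFINITELY
print(attribute(form).fired)        # (('1a', DEFINITE_TRIGGER), ('7', PROBABLE_TRIGGER))

# headline preventability: 869 of 1356 events preventable
print(wald_proportion_ci(869, 1356))        # 869 (64.1, 61.5–66.6)

# inter-rater agreement on a binary cross-tab (rows = pharmacist)
table = ContingencyTable(("not", "prev"), [[319, 168], [113, 756]])
print(cohens_kappa(table))                  # 0.54 (0.49–0.59), n=1356
```

The form classifies as definitely preventable because the inappropriate
re-exposure (1a, a definite trigger) dominates the drug interaction (7, a
probable trigger). The proportion line reads: 869 events, 64.1% of the
cohort, 95% CI 61.5–66.6%.

## Command line

```sh
adeprev simulate --seed 1 --n-events 1356 --out data/       # synthetic cohort
adeprev validate --ratings data/ratings.csv --forms data/forms.csv
adeprev run --ratings data/ratings.csv --forms data/forms.csv \
            --resolutions data/resolutions.csv --out report/
adeprev report --summary report/summary.json --out report2/  # regenerate tables
```

`run` writes five CSV tables (consensus proportions with CIs, binary and
definitely-vs-probably inter-rater kappas, between-method kappas,
criterion frequencies) plus a full-precision `summary.json`. Reports are
deterministic: same inputs (or same seed in `--simulate` mode), same
bytes. Exit codes: 0 success, 2 validation failure, 3 unresolved
discordant cases.

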
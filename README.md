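# rollrisk

Self-refreshing disease-risk prediction from real-world clinical event
tables. Given tidy event-level data (encounters, diagnoses, procedures,
medications, labs, flowsheets, vitals, chief complaints) plus a demographics
table, `rollrisk` runs an autonomous pipeline each validation month:

1. **Patient-month time-series** — cohort filters, one row per calendar
   month with at least one encounter, a binary endpoint outcome over the
   following L months, and censoring at the endpoint.
2. **Empirical predictor retention** — every candidate binary predictor is
   screened at the patient level with an exact Fisher test (criterion 1) and,
   for risk factors, a cumulative-binomial generalizability check
   (criterion 2).
3. **Three-way encoding** — past-and-present indicators for diagnoses,
   historical + contemporaneous indicators for other binaries, paired
   presence/value columns for a fixed numeric set (trimmed to the
   0.1/99.9 percentiles and standardized on the analytic data only),
   one-hot demographics with missing indicators, and a single standardized
   age column.
4. **Shallow regularized network** — one hidden layer of 32 logistic units,
   L2 = 1e-4 on the weight matrices, binary cross-entropy, Adamax, and a
   two-phase batch-size schedule (2^7 with patience 2, then 2^14 with
   patience 4) with best-weights restoration.
5. **Rolling pseudo-prospective validation** — fit strictly on data before
   month T, score the month-T cohort, observe the follow-up window, and
   report AUROC, AUPRC, top-rank PPV/odds-ratio bands, threshold
   sensitivity/specificity, and risk-distribution descriptives.

A synthetic EHR generator with planted risk/protective factors, correlated
clinical-journey chains and a known monthly hazard makes every stage
testable without patient data, including Bayes-optimal AUROC baselines.

## CLI

Generate a synthetic cohort and run the rolling loop over it:

```sh
rollrisk simulate --config sim.yaml --seed 3 --out cohort/
rollrisk roll --events cohort/events.csv --demo cohort/demographics.csv \
    --from 2017-07 --to 2017-12 --seed 5 --out results/
```

`roll` writes `monthly_summary.csv` (one row per validation month with
AUROC/AUPRC/PPV bands), per-month predictor-decision and score tables, and
a JSON bundle with OLS trend slopes. Event tables may be CSV or Parquet
with columns `patient_id, category, code, event_date, numeric_value`;
demographics use `patient_id, attribute, value, effective_date` (empty
`effective_date` marks a time-invariant attribute; `birth_date` is
required, `death_date` optional).

## Python API

```python
import rollrisk as rr
from rollrisk.synthetic import reference_config, generate_cohort

events, demo, truth = generate_cohort(reference_config(master_seed=0))
result = rr.run_month(events, demo, T=rr.parse_month("2018-03"), seed=0)
print(result.auroc, result.retained_predictors)
```

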
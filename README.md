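# recurve

Fitting and evaluating prediction models for **recurrent clinical events**
(repeated seizures, asthma exacerbations, disease flares, ...).

Four model families are implemented and compared on per-subject predicted
event counts at a horizon:

| model | data view | fitted by |
|---|---|---|
| NB | per-subject counts + exposure offset | direct MLE (NB2, analytic gradients) |
| ZINB | counts with a logit structural-zero mixture | joint MLE, warm-started |
| Andersen-Gill (AG) | counting-process `(start, stop]` rows | Newton-Raphson stratified partial likelihood, Breslow ties |
| PWP total-time | counting-process rows stratified by event number | same machinery, per-stratum baselines |

Both Cox-type fits report naive and subject-clustered robust (infinitesimal
jackknife) standard errors, with an exact leave-one-subject-out jackknife as a
small-sample cross-check. Predicted counts come from `exposure * exp(x beta)`
(NB/ZINB, times `1 - pi(x)` for ZINB), `H0(tau) exp(x beta)` (AG), and either
Monte-Carlo path sampling through the stratified hazards or a plug-in sum
(PWP).

Performance is evaluated with the numerical measures **RMSPE**, **MAPE**
(mean absolute error) and **prediction bias** (mean of predicted − observed;
positive = over-prediction), subgroup-bias tables, count-adapted
**calibration curves** (observed on x, predicted on y, loess-style smoother +
subject-bootstrap band), and **Bland–Altman** agreement data with limits at
1.96 SD around the mean difference.

A synthetic cohort simulator (gamma frailty ⇒ NB marginal counts, optional
structural zeros, piecewise or event-number-dependent intensities, visit-
interval reporting) makes everything testable without clinical data; presets
emulate a low-rate/high-zero ("asthma-like") and a high-rate/heavy-tail
("epilepsy-like") cohort shape.

## Library quick start

```python
from recurve import (
    SimulationConfig, simulate_cohort, to_counting_process,
    fit_nb, fit_zinb, fit_cox_counting, evaluate_all, AG, PWP_TT,
)
from recurve.survival_models import pool_sparse_strata

cfg = SimulationConfig(
    n_subjects=1000,
    covariate_spec={"x": ("bernoulli", 0.5), "z": ("normal", 0.0, 1.0)},
    beta={"x": 0.4, "z": -0.2},
    baseline_rate=0.006, frailty_variance=0.5, follow_up=365.0, seed=1,
)
cohort = simulate_cohort(cfg).cohort
horizon = 365.0
fits = [
    fit_nb(cohort, ["x", "z"], horizon),
    fit_zinb(cohort, ["x", "z"], None, horizon),
    fit_cox_counting(to_counting_process(cohort, AG, horizon)),
    fit_cox_counting(pool_sparse_strata(to_counting_process(cohort, PWP_TT, horizon))),
]
report = evaluate_all(cohort, fits, horizon, seed=2)
print(report.rows)        # RMSPE / MAPE / bias per model
print(report.best)        # best model per metric (smallest absolute value)
```

## CLI

The `recurve` command wires the pipeline
`simulate → preprocess → fit → predict → evaluate → plot` from one YAML
config; each subcommand runs the pipeline up to its stage (`run` does
everything). Identical config + seed gives byte-identical CSV outputs.

```bash
recurve run --config config.yaml
```

```yaml
# config.yaml
seed: 1
out_dir: out
horizon: 365.0
formula: [x, z]
models: [nb, zinb, ag, pwp]
simulate:
  n_subjects: 500
  covariate_spec: {x: [bernoulli, 0.5], z: [normal, 0.0, 1.0]}
  beta: {x: 0.4, z: -0.2}
  baseline_rate: 0.006
  frailty_variance: 0.4
  follow_up: 365.0
preprocess: {merge_window: 14}         # drop events within 14 d of the last retained one
evaluation: {pwp_draws: 500, n_boot: 200}
```

To analyse real data instead, replace `simulate:` with

```yaml
input:
  subjects: subjects.csv   # subject_id,follow_up_end,<covariates>
  events: events.csv       # subject_id,event_time
  schema: {x: {kind: binary}, smoke: {kind: categorical, levels: [non, current, ex]}}
```

Outputs: cohort CSVs, counting-process tables, per-model coefficient
summaries and predictions, `report.json` / `report_rows.csv`, calibration and
Bland–Altman plot data (CSV) and figures (PNG), and a `manifest.json` with
config hash, seed, versions and surfaced warnings.

## Conventions

- Time is in days from each subject's entry (time 0); events live in
  `(0, follow_up_end]` and an event exactly at the censoring instant counts.
- An event at `t` contributes to the count over `(0, tau]` iff `t <= tau`.
- Counting-process risk sets are left-open/right-closed: at risk at `t` iff
  `start < t <= stop`; ties are handled by the Breslow approximation.
- CSV files are comma-separated, UTF-8, RFC-4180 quoting, header required.
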
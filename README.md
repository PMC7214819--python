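# teicopk

Population pharmacokinetics of teicoplanin in children with differing renal
function: a two-compartment IV-infusion model with weight/eGFR covariates,
FOCE estimation with stepwise covariate selection, bootstrap/NPDE/VPC
validation, and Monte Carlo dose-regimen optimization against a 10–30 mg/L
trough target. The original clinical dataset is not public, so everything
runs on synthetic cohorts that emulate its structure (136 children, median
weight 10 kg, eGFR 30–280 ml/min/1.73 m² split across four renal strata,
1–3 sparse samples per child).

## Layout

| module | contents |
|---|---|
| `teicopk.pk_core` | closed-form two-compartment infusion kinetics, superposition, secondary parameters |
| `teicopk.covariates` | Schwartz eGFR, renal strata, maturation CL candidates, covariate inclusion forms, final covariate model |
| `teicopk.popmodel` | lognormal IIV, the four residual-error forms, observation simulation with assay-floor censoring |
| `teicopk.estimation` | vectorized FOCE(-interaction) objective, BFGS outer search, AIC/BIC, shrinkage, forward/backward covariate selection |
| `teicopk.diagnostics` | GOF/CWRES residual tables, nonparametric bootstrap, NPDE, VPC (+plots) |
| `teicopk.dosing` | regimen schedules, Monte Carlo trough simulation per renal stratum, regimen ranking |
| `teicopk.synthetic_data` | virtual cohorts and sparse event-record datasets |
| `teicopk.data`, `teicopk.config`, `teicopk.cli` | event-record CSV dialect, YAML config, command line |

## CLI

```sh
teicopk generate --n 136 --seed 1 --out runs/gen        # cohort + dataset CSV
teicopk fit      --data runs/gen/dataset.csv --out runs/fit
teicopk select   --data runs/gen/dataset.csv --out runs/sel
teicopk bootstrap --data runs/gen/dataset.csv --n-rep 1000 --seed 2 --out runs/bs
teicopk npde     --data runs/gen/dataset.csv --seed 3 --out runs/npde
teicopk vpc      --data runs/gen/dataset.csv --stratify --seed 4 --out runs/vpc
teicopk simulate-dose --stratum moderate --regimen 6x3q12h+5qd --seed 5 --out runs/sim
teicopk optimize --stratum normal --seed 6 --out runs/opt
```

Every command writes a `manifest.json` (inputs, seeds, version, wall clock)
into its output directory. Regimen shorthand is `<load>x<n>q<h>h+<maint>qd`
in mg/kg.

## Dataset dialect

One CSV row per dose or observation event: `ID, TIME, EVID (1=dose/0=obs),
AMT (mg), DUR (h), DV (mg/L), BLQ` plus per-subject covariate columns
(`AGE, SEX, WT, HT, BSA, SCR, BUN, UA, EGFR, ALT, AST, TBIL`). Observations
under the 2.0 mg/L quantification floor are flagged and excluded from
estimation with a logged count. See `teicopk/data.py` for the full
column-by-column description.
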
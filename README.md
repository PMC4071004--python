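# timecarry

Tools for studying trial-to-trial carryover in temporal bisection:
first-order counterbalanced trial sequences, an ideal-observer model with
an adaptive leaky memory prior and a per-trial uncertainty threshold,
psychometric/chronometric analysis, carryover indices, and grid-based
parameter fitting. Everything runs on simulated or synthetic data — no
external datasets are required.

## What's inside

| module | purpose |
| --- | --- |
| `timecarry.sequences` | path-guided de Bruijn style sequences: every ordered pair of the 8 labels (7 log-spaced durations + null) occurs exactly `multiplicity` times cyclically |
| `timecarry.observer` | ideal observer: noisy scalar percepts, weighted-geometric-mean memory prior with exponential decay (window `M`), half-normal uncertainty threshold (`theta`), repeat-previous-response under uncertainty; four reduced variants |
| `timecarry.psychometrics` | RT-cutoff / first-trial filtering, binomial ML logistic fits (BP, DL, CV), bias-corrected bootstrap threshold CIs, chronometric curves, session exclusion (CV ≥ 1) |
| `timecarry.carryover` | prior-response and prior-duration splits, decision-bias index, perceptual slope, RT matrices, cohort correlations, repetition check, central tendency |
| `timecarry.fitting` | Monte Carlo (M, theta) grids, standardized-RMSE fitting, variant comparison |
| `timecarry.synthetic` | synthetic participant cohorts (observer responses + parametric RT model) with ground-truth manifests |
| `timecarry.workflow` | configuration, session CSV round-tripping, end-to-end pipeline |

## CLI

```sh
timecarry generate-sequence --tmin 300 --tmax 900 --levels 7 --multiplicity 8 --seed 1 --out seq.csv
timecarry simulate --seq seq.csv --m 13 --theta 49 --cv 0.16 --variant full --seed 1 --out session.csv
timecarry analyze --session session.csv --rt-cutoff 1000 --bootstrap 1999 --out fit.json
timecarry carryover --session session.csv --out profile.json
timecarry run-grid --n 500 --seed 1 --out grid.json
timecarry fit --profile profile.json --grid grid.json --out fitres.json
timecarry cohort --n 40 --modality auditory --seed 1 --outdir cohort/
timecarry pipeline --seed 1 --outdir run/
```

Sessions are plain CSV (one row per trial; empty numeric fields on null
trials) with a `<name>.csv.meta.json` sidecar holding provenance; fits,
profiles and grids are JSON.

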
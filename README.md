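# freshshelf

Kinetic shelf-life modelling for fresh-cut produce storage trials.

Fresh-cut vegetables spoil fast: microbes grow, colour browns, tissue
softens, ascorbic acid oxidises.  A storage trial samples these quantities
over a few days; the question is *when does the product stop being
acceptable*, and which cheap quality measurement can stand in for plate
counting.  `freshshelf` answers both by fitting kinetic models to the trial
time series and inverting them against acceptability limits.

## Models

**Microbial growth** (counts on the log10 CFU/g scale) is described by the
four standard primary models, each parameterised by the initial count N0,
the maximum count Nmax, the maximum specific growth rate mu_max (1/d) and
the lag time lambda (d):

- modified Gompertz: `N(t) = N0 + (Nmax−N0)·exp(−exp(mu_max·e/(Nmax−N0)·(λ−t)+1))`
- modified Logistic: `N(t) = Nmax / (1 + (Nmax/N0 − 1)·exp(mu_max(λ−t)))`
- Baranyi–Roberts, with adjustment function `A(t)` and `h0 = λ·mu_max`
- Huang, with smooth lag transition `B(t)`

**Quality attributes** follow zero-order (`A(t) = A0 + k·t`) or first-order
(`A(t) = A0·e^{k·t}`) kinetics with a signed rate k (negative = decline).

**Fitting** is bounded multi-start nonlinear least squares on per-day
replicate means; performance is reported as R², RSS and
`RMSE = sqrt(RSS/(n−p))`.

**Indicator selection** screens each quality attribute by its Pearson
correlation with the total bacterial count (within each treatment arm,
averaged across arms); attributes with |r| > 0.9 become shelf-life
indicators.

**Shelf life** is the time at which a fitted curve crosses a limit:
5 log10 CFU/g for safety, panel score 3 for sensory, and data-derived
cut-offs (the attribute's mean value on the sensory shelf-life day) for
quality attributes.  The overall shelf life per treatment is the minimum
across bases.

A seeded synthetic-trial generator (`default_trial_config` /
`simulate_trial`) emulates a 10-day refrigerated trial with three
treatment arms (untreated control, hypochlorite wash, photodynamic
treatment), six sampling days and three replicates.

## Worked example

```python
import freshshelf as fs

cfg = fs.default_trial_config(seed=7)
ds = fs.simulate_trial(cfg)                      # tidy replicate-level trial
an = fs.analyze_trial(ds, growth_model="all")    # fit, select, invert

print(an.growth_fits["PDT"][0].summary())
print("selected:", an.correlation.selected)
print({k: round(v, 2) for k, v in fs.overall_shelf_life(an.report).items()})
```

prints

```
Primary growth model: huang
  n_obs 6   n_params 4   converged True   starts 3
  N0         2.4385  log10 CFU/g
  Nmax       7.4261  log10 CFU/g
  mu_max     0.7505  1/d
  lag        0.7556  d   (h0 = 0.5670)
  R^2    1.0000   RSS    0.00085   RMSE   0.0206
selected: ['weight_loss_pct', 'firmness_n', 'ascorbic_mg_kg', 'tpc_mg_kg']
{'CK': 0.81, 'NaClO': 1.93, 'PDT': 4.29}
```

The best-ranked growth fit for the photodynamic arm recovers a curve close
to the generating truth (N0 2.26, Nmax 7.73, mu_max 0.76, lag 0.62); four
attributes pass the |r| > 0.9 screen at this noise level; and the overall
shelf life per treatment is the safety basis (the bacterial count crosses
5 log10 CFU/g before any quality cut-off), with the treated arms lasting
markedly longer than the control.

The same pipeline is available from the shell:

```sh
freshshelf simulate --seed 42 --out trial.csv
freshshelf fit-growth trial.csv --model all
freshshelf select-indicators trial.csv
freshshelf predict-shelf-life trial.csv --limit-tbc 5 --sensory-limit 3
freshshelf report trial.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it simulates the default trial with the given seed, fits all four
growth models per treatment, screens indicators, predicts shelf life under
every basis, and writes the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Progress (best model per arm, selected indicators, overall shelf lives)
is logged to stderr.
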
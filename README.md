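# trapnet

Optimal subset selection for insect trap monitoring networks.

Given weekly trap counts at `L` candidate locations, `trapnet` answers: which
`K` locations should stay in operation so that a Bayesian spatial logistic
growth model trained on them best predicts cumulative pest counts at the
remaining sites?

The pipeline:

1. **trap_data** — weekly count records (in hundreds of pests), cumulative
   transform, donor-mean imputation of missing cells, planar-km coordinates.
2. **growth_model** — cumulative counts follow a logistic curve
   `beta(s) / (1 + exp(-(week - gamma(s))/k))` with Gaussian-process layers
   (exponential correlation over site distances) on the asymptote and midpoint
   fields; fit by a blocked Gibbs/Metropolis sampler; out-of-sample prediction
   by simple kriging per posterior draw.
3. **loss_functions** — mean log error `mean(log(|Y - Yhat| + 1))` over
   held-out cells; optional additive cost penalty `+ lambda * C(subset)`.
4. **bayes_opt** — surrogate-guided search over binary inclusion vectors with
   row sum K: Bayesian linear surrogate without intercept, acquisition by the
   K smallest coefficients, plus a brute-force enumerator for small instances.
5. **experiment** — Monte-Carlo K-sweep with a random-subset baseline,
   test-year evaluation, per-site inclusion proportions and the tile table of
   top sites.
6. **synthetic_data** — generator from the model's own generative process,
   emulating the reference schedule (21 sites, 4 years with 6/7/10/11 weeks,
   one absent site-year, one flagged-missing cell), with ground truth saved
   for recovery tests.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end checks (oracle equivalence of
the optimizer against brute force, BO-vs-random dominance on a synthetic
study-schedule dataset, parameter recovery, structural invariants); the
dominance test takes a couple of minutes, the rest of the suite well under a
minute each.

## CLI

```sh
trapnet simulate --seed 1 --out runs/sim                # counts.csv, sites.csv, truth.json
trapnet fit      --counts runs/sim/counts.csv --sites runs/sim/sites.csv \
                 --profile fast --seed 1 --out runs/fit
trapnet optimize --counts runs/sim/counts.csv --sites runs/sim/sites.csv \
                 --k 5 --n0 10 --b 10 --seed 1 --out runs/opt
trapnet sweep    --counts runs/sim/counts.csv --sites runs/sim/sites.csv \
                 --seed 1 --out runs/sweep --config sweep.yaml
trapnet report   --run runs/sweep
```

`simulate` accepts a YAML scenario file (any `SimScenario` field); `sweep`
accepts a YAML with `ExperimentConfig` fields plus `profile: fast|full`.
Sites files use planar km (`site_id,x_km,y_km`) or lon/lat with `--lonlat`.
Counts files are `year,site_id,week,count` with `NA` for missing cells.

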
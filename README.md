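# tradeflow

Analysis toolkit for longitudinal directed weighted trade networks.

Given bilateral trade matrices (long-format CSV: sender, receiver, year,
quantity in tonnes) plus country-level and dyad-level covariates, the
package:

- **reconciles and assembles** exporter- and importer-reported flows into a
  dense trade tensor (exporter reports take precedence; unreported
  dyad-years are zero-filled; countries with missing covariates or a
  zero-trade year are excluded iteratively to a fixed point);
- **builds gravity-style design matrices** — log(1 + flow) response;
  intercept, trade-agreement indicator, log centroid distance and logged
  sender/receiver blocks of GDP per capita, population, pasture area and
  dietary-energy-supply adequacy;
- **fits a Bayesian dyadic mixed-effects model** by a blocked Gibbs
  sampler: per-year coefficient vectors, latent sender/receiver effects
  with stationary VAR(1) dynamics (2×2 transition Φ, innovation covariance
  Σ_ε), and AR(1) dyadic residual pairs with reciprocity correlation ρ and
  lag coefficient φ_gg;
- **summarises posteriors** — coefficient means with 95% HPD intervals and
  significance flags, Φ medians with equal-tail 95% quantile intervals,
  posterior-mean sender/receiver effects, autocorrelation-adjusted
  (time-series) standard errors;
- **clusters each year's network** by directed weighted modularity (exact
  branch-and-bound at small n, deterministic greedy agglomeration with
  local refinement at full scale, walktrap-style random-walk communities,
  k-core levels, adjusted-Rand comparison across algorithms);
- **quantifies robustness of inference** — the fraction of cases that
  would have to be replaced with null-hypothesis (zero-effect) cases to
  invalidate a significant coefficient;
- ships a **synthetic-data generator** that draws country/dyad panels and
  trade tensors from the same generative model with known parameters, so
  the whole pipeline is testable end-to-end without any external data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter
recovery at N=30/T=10, null coverage over 20 replicates, modularity/HPD/
time-series-SE oracles, robustness closed forms, I/O rules); the full
suite runs in a few minutes on one CPU.

## CLI

```sh
# merge exporter- and importer-reported matrices (exporter wins)
tradeflow io merge --exports E.csv --imports I.csv --out M.csv

# generate synthetic data from a YAML config (keys mirror SyntheticConfig)
tradeflow simulate --config syn.yaml --out-dir data/

# fit the model
tradeflow fit --trade data/trade.csv --countries data/countries.csv \
  --coords data/coords.csv --agreements data/agreements.csv \
  --iters 11000 --burn 1000 --thin 10 --seed 1 --out draws.npz

# cluster one year
tradeflow cluster --trade data/trade.csv --year 2000 --method greedy --out part.csv

# robustness of a fitted coefficient
tradeflow robustness --draws draws.npz --coef agreement --year 2000 --n-cases 17822

# full pipeline from a run config (synthetic or file inputs)
tradeflow run --config run.yaml
```

A minimal `run.yaml`:

```yaml
out_dir: out/
synthetic:
  n_countries: 20
  n_years: 5
  beta: [6.0, 1.0, -0.3, 0, 0, 0, 0, 0, 0, 0, 0]
  phi_matrix: [[0.8, 0.0], [0.0, 0.6]]
  phi_gg: 0.3
  rho: 0.5
  sigma2_gamma: 0.5
  sigma_eps: [[0.3, 0.0], [0.0, 0.3]]
fit: {iterations: 2000, burn_in: 500, thin: 1}
cluster_method: greedy
seed: 1
```

## Layout

```
src/tradeflow/
  trade_io.py    flow records, tensor assembly, merge/filter/write
  design.py      panels, haversine distances, gravity design matrices
  synthetic.py   generative model with known parameters
  netmodel.py    Gibbs sampler, HPD intervals, time-series SE, summaries
  netcluster.py  modularity, exact/greedy/walktrap partitions, k-core, ARI
  robustness.py  replacement-of-cases robustness of inference
  pipeline.py    simulate/load -> cluster -> fit -> robustness -> report
  cli.py         `tradeflow` console entry point
```
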
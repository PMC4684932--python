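# nestpower

Simulation and statistical analysis of **two-level nested experimental
designs** with two conditions (control / experimental). The package
quantifies — by Monte-Carlo experiment and in closed form — the
false-positive-rate inflation and the power loss that arise when
cluster-related variation in the intercept and/or in the experimental effect
is ignored by the analysis.

Two layouts are supported:

* **Design A** — condition is a cluster-level variable: every observation in
  a cluster shares one condition (e.g. genotype of an animal).
* **Design B** — both conditions occur within each cluster: condition is an
  observation-level variable (e.g. treated and untreated cells from the same
  animal).

## What is inside

| Module | Purpose |
| --- | --- |
| `nestpower.params` | `DesignSpec`, `PopulationParams`; ICC arithmetic, mapping of user settings (`d`, ICC) to variance components, normal-range dispersion of cluster-specific effects |
| `nestpower.datagen` | Seed-reproducible generators for design A, design B (random intercept + random slope), and design B with a cluster-level covariate that explains part of the slope variance |
| `nestpower.estimators` | The competing analyses, all returning a uniform `FitResult`: t test on individual observations, paired t test on cluster means, t test on design-A cluster means, random-intercept LMM, random-intercept+slope LMM, OLS with cluster dummies, covariate-extended LMM |
| `nestpower.analytic` | Closed-form SEs of the overall effect, normal-approximation power curves over (N, nc), and the asymptotic type-I error of the naive t test |
| `nestpower.montecarlo` | Rejection-rate tables per (parameter cell × method) with Wilson CIs, the canned study grids 1a/1b/2a/2b, power differences |
| `nestpower.cli` / `io` / `config` / `fixtures` | CLI, CSV dataset I/O, YAML config, programmatic test fixtures |

The mixed models are REML fits with Wald z tests of the condition effect.
On balanced design-B data they use exact closed-form REML (the classical
balanced-ANOVA identities), which makes 10,000-replicate mixed-model
simulations run in seconds; unbalanced data, ML estimation, and constrained
random-effects covariances fall back to `statsmodels.MixedLM`. The closed
form is validated against `MixedLM` in the test suite.

## Command line

```bash
# one synthetic design-B dataset
nestpower simulate --design B --n-clusters 10 --nc 5 --d 0.5 --icc 0.25 \
    --var-u1 0.05 --seed 1 --out data.csv

# one estimator on a dataset (JSON record on stdout)
nestpower fit --method lmm_intercept_slope --alpha 0.05 data.csv

# replicate a simulation study (rejection-rate CSV)
nestpower replicate --study 2a --reps 2000 --seed 7 --out study2a.csv

# analytic power grid over N and nc
nestpower power --d 0.2,0.5,0.8 --var-u1 0,0.05,0.15 --out power.csv
```

All subcommands accept `--config <file.yaml>` with flat keys
(`design, n_clusters, n_per_condition, d, icc, var_u1, cov_u0u1, var_e,
gamma00, alpha, reps, seed, out, ...`); explicit flags override the file.
Dataset CSVs are long format with header `cluster,condition,y[,w]`.
Exit codes: 0 ok, 2 usage, 3 invalid parameter/file, 4 convergence
threshold.

## Python API

```python
import nestpower as npw

params = npw.resolve_params(d=0.0, icc=0.50, var_u1=0.15)
spec = npw.DesignSpec("B", n_clusters=50, n_per_condition=105)
data = npw.generate_design_b(spec, params, seed=1)
npw.ttest_individual(data).p_value        # anticonservative: ignores clustering
npw.lmm_intercept_slope(data).p_value     # correct model

table = npw.rejection_rate((params, spec),
                           ["ttest_individual", "paired_ttest_means"],
                           n_reps=2000, master_seed=1)
```

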
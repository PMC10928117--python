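# hwle — healthy working life expectancy from multi-state models

How many years, from age 50, can people expect to spend both healthy and
in paid work?  That quantity — healthy working life expectancy (HWLE) — is
the yardstick policy analysts use when retirement ages rise faster than
population health improves.  `hwle` is a Python package for estimating it
from panel data: cohort studies that interview people every couple of
years, record whether they are healthy (no limiting long-standing illness)
and working, and learn exact death dates from registry linkage.

The package implements the full estimation pipeline:

* **Continuous-time multi-state survival models** on the age scale.  With
  states healthy-and-working (HW), not-healthy-and/or-not-working (nHW)
  and dead (a 5-state variant splits the four health × work combinations),
  each permitted transition r → s has intensity

      q_rs(a, x) = exp(α_rs + γ_rs (a − 50) + Σ_k β_rsk x_k),

  a Gompertz-type log-linear age effect anchored at age 50 plus
  proportional covariate effects (hazard rate ratios, HRRs).  States are
  interval-censored at interviews; deaths contribute exactly, integrating
  over the unknown pre-death state.  Effects can be constrained to HRR = 1
  per transition (e.g. workplace factors on non-working exits).
* **Expectancy integration**: state-occupancy probabilities are chained
  from age 50 to 120 and integrated, giving HWLE, years not healthy
  and/or not working, and life expectancy, conditional on a covariate
  profile and marginalized over a modelled initial-state distribution;
  uncertainty comes from resampling the MLE's asymptotic distribution.
  By construction HWLE + non-HW years = LE.
* **Multiple imputation** of missing interview cells by predictive mean
  matching across all waves, with Rubin's-rules pooling
  (Barnard–Rubin degrees of freedom) and exclusion of non-converged
  imputation fits.
* **A synthetic cohort generator** with known ground truth emulating an
  English ageing-cohort panel (baseline age mix, ~27% healthy-and-working
  at baseline, realistic covariate prevalences, 2-yearly jittered waves,
  registry-window deaths, MCAR/MAR missingness), so every stage is
  testable end to end with parameter recovery.

## Worked example

```python
from hwle import (MultiStateModel, hazard_ratio_table, format_hrr_table,
                  initial_state_distribution, expectancy_uncertainty,
                  load_scenario, true_model_from_scenario,
                  config_from_scenario, simulate_cohort)

scenario = load_scenario("elsa_like")            # packaged study conditions
panel, truth = simulate_cohort(true_model_from_scenario(scenario),
                               config_from_scenario(scenario), seed=1)

fit = MultiStateModel(
    covariates=("osteoarthritis",),
    constraints=[("HW-dead", "osteoarthritis"),
                 ("nHW-HW", "osteoarthritis"),
                 ("nHW-dead", "osteoarthritis")],
).fit(panel)
print(format_hrr_table(hazard_ratio_table(fit)))

init = initial_state_distribution(panel, at_age=50.0)
for oa in (0, 1):
    est = expectancy_uncertainty(fit, init, {"osteoarthritis": oa},
                                 n_draws=1000, seed=2024 + oa)
    lo, hi = est.ci["state:HW"]
    print(f"OA={oa}: HWLE {est.marginal[0]:.2f} ({lo:.2f}, {hi:.2f})  "
          f"non-HW years {est.marginal[1]:.2f}  LE {est.total_le:.2f}")
```

Output:

```
effect                   age    osteoarthritis
transition
HW-dead     1.03 (0.89,1.19)      1.00 (fixed)
HW-nHW      1.07 (1.06,1.08)  1.38 (1.15,1.66)
nHW-HW      0.86 (0.84,0.88)      1.00 (fixed)
nHW-dead    1.10 (1.09,1.11)      1.00 (fixed)
OA=0: HWLE 7.12 (6.45, 7.75)  non-HW years 22.03  LE 29.15
OA=1: HWLE 5.85 (5.08, 6.57)  non-HW years 23.07  LE 28.91
```

Reading this: each extra year of age raises the risk of leaving the
healthy-working state by 7% (HRR 1.07, CI 1.06–1.08 — the fit recovers
the generating value exactly), and osteoarthritis raises it by 38%
(generating value 1.32).  The HW-death and nHW-exit effects of
osteoarthritis are constrained to 1 in this specification.  People with
osteoarthritis at 50 can expect 5.85 years healthy and in work versus
7.12 without — a 1.3-year gap — while total life expectancy differs far
less, because most of the difference is displaced into years not healthy
and/or not working.

The same pipeline is scriptable from the shell:

```bash
hwle simulate --seed 1 --out run/            # panel.csv + truth.json
hwle fit --config run.yaml --seed 1 --out run/      # fit.json + hrr.csv
hwle expectancy --config run.yaml --seed 1 --out run/  # expectancy.csv
```

Every command writes a manifest (config, seed, version, input hashes)
sufficient to reproduce its outputs bit for bit.

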
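# gxevar

Bayesian variance-component analysis of family-by-environment phenotypic
variation during early fish ontogeny — with a synthetic study generator, so
the entire pipeline is testable without access to field data.

## The scientific problem

How much of the phenotypic variation among larvae reared under different
thermal regimes is genetic, and do genotypes (families) *respond
differently* to the same regime?  The motivating design is a common-garden
experiment on early-life lake sturgeon: half-sib families split across four
egg-incubation treatments (constant cold 10 °C, constant warm ~18 °C, a
naturally fluctuating ambient regime, and a strongly fluctuating
"anthropogenic" regime), measured at hatch (body length, body area,
yolk-sac area) and again at emergence from the substrate (emergence length,
growth, days to emergence), with per-larva thermal covariates (mean
temperature and cumulative degree-days over the chamber-residence
interval).

The core model for a hatch trait is the Gaussian mixed model

    y_ijk = μ + Treatment_i + Family_j + (Family×Treatment)_ij + ε_ijk

with `Family_j ~ N(0, σ²_F)`, `(Family×Treatment)_ij ~ N(0, σ²_FS,i)`
independent across treatments (zero cross-treatment covariance — the "idh"
structure), and heteroscedastic residuals `ε_ijk ~ N(0, σ²_ε,i)`.
Emergence traits add Mean T, Degree Days, and Raceway as fixed effects.  A
treatment-specific family variance *is* the genotype-by-environment signal:
if σ²_FS(warm) ≫ σ²_FS(cold), families fan out in the warm regime.

Everything is fitted by a blocked Gibbs sampler written for this model
family (joint multivariate-Gaussian update of all location effects, then
conjugate inverse-gamma updates for every variance component and residual
group; near-flat IG(0.001, 0.001) variance priors).  On top of the sampler:

* **posterior summaries** — KDE posterior modes, exact shortest-window 95%
  HPD intervals, Heidelberger–Welch stationarity diagnostics, ESS;
* **DIC model selection** — DIC = D̄ + p_D with p_D = D̄ − D(θ̄); models
  within two DIC units are equivalent and the simplest wins, fixed effects
  whose 95% credible interval spans zero are flagged for pruning;
* **posterior F-ratio variance comparison** — iteration-wise ratio profile
  of two variance components; the one-tailed empirical tail-area
  probability is `1 − (#ratios > 1)/N`;
* **broad-sense heritability** — per-draw `H² = 2σ²_F / (σ²_F + σ²_ε + …)`,
  reported as mode with 95% HPD;
* **reaction norms** — conditioned family means per treatment with
  family-level intervals;
* **thermal covariates** — cumulative degree-days
  `Σ max(daily mean − T₀, 0)` and time-weighted mean temperature over a
  residence interval.

## Worked example

```python
from gxevar import (SimConfig, ModelSpec, PriorSpec, McmcSettings,
                    simulate_hatch_phenotypes, build_design, gibbs_sample,
                    posterior_mode, hpd_interval, variance_ratio_test)

table = simulate_hatch_phenotypes(SimConfig(), seed=1)   # 1,200 larvae
design = build_design(table, ModelSpec("body_length_mm"))
draws = gibbs_sample(design, PriorSpec(), McmcSettings(20_000, 2_000, 10, seed=2))

warm = draws.get("var[family_by_treatment[warm]]")
cold = draws.get("var[family_by_treatment[cold]]")
print("warm family variance mode:", round(posterior_mode(warm), 2))
print("95% HPD:", tuple(round(v, 2) for v in hpd_interval(warm)))
comp = variance_ratio_test(warm, cold, "warm", "cold")
print("tail area warm vs cold:", round(comp.tail_area, 3),
      f"({comp.n_exceeding_one}/{comp.n_total} ratios > 1)")
```

Output:

```
warm family variance mode: 0.43
95% HPD: (0.17, 1.36)
tail area warm vs cold: 0.001 (1799/1800 ratios > 1)
```

The generator drew this dataset with a true warm family variance of 1.10
and a cold one of 0.18.  With only ten families the per-dataset estimate is
naturally scattered (here the mode lands at 0.43 but the 95% HPD reaches
1.36 and covers the truth), yet the comparison is unambiguous: in 1,799 of
1,800 retained draws the warm family variance exceeds the cold one
(tail-area probability 0.001) — families diverge when incubated warm.

The same analysis runs end-to-end from a shell:

```bash
gxevar simulate --seed 1 --out sim/
gxevar select sim/hatch_phenotypes.csv --trait body_length_mm --out selection.csv
gxevar run-all --seed 1 --out results/
```

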
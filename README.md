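# mhecosim

Monte Carlo DEA assessment of workforce policies on mental-health care
ecosystems.

Regional mental-health systems balance hospital (inpatient) and community
(outpatient) care across catchment areas. Planners who want to move or hire
outpatient professionals need to know, *before* acting, how the change will
ripple through the system: more professionals → more outpatient visits →
changed inpatient stays and discharges — and whether the ecosystem as a
whole becomes more or less efficient. `mhecosim` implements that
decision-support analysis end to end for anyone studying health-services
efficiency:

1. **Structural regression** — expert-identified relationships between care
   variables are fitted with log-linearizable exponential
   (`y = α·e^{β·z}`) and product-unit (`y = α·x₁^{β₁}·…·x_p^{β_p}`) base
   functions, with 95% confidence/prediction intervals, R² and F statistics.
2. **Causal network** — a time-layered DAG (decisions → frequentation →
   stay/discharges/readmissions) carries the fitted models.
3. **Policy propagation** — FTE deltas per area are applied and propagated
   into per-(area, variable) uniform uncertainty distributions whose limits
   are the models' prediction intervals.
4. **Monte Carlo DEA** — replicates sample the distributions and score every
   area with variable-returns-to-scale (BCC) envelopment analysis, input-
   and/or output-oriented; scores aggregate into five indicators: mean
   relative technical efficiency (RTE), P(RTE > 0.75), RTE error,
   stability (%) and Shannon entropy (%), compared pre vs post policy.

A synthetic-ecosystem generator (calibrated to the 13 catchment areas of
Gipuzkoa, Spain) makes the whole pipeline runnable and testable with no
external data. The shipped default policy is the Gipuzkoa outpatient
rebalancing: −0.5 FTE psychiatrist in Tolosa, +0.5 in Azpeitia, +1.0 hired
in Andoain.

## Worked example

```sh
mhecosim simulate --seed 1 --replicates 100 --out runs/demo
```

generates the default 13-area ecosystem, fits the six structural models,
applies the shipped policy, simulates 100 replicates pre and post under the
15 default scenarios, and prints the comparison (excerpt):

```
== input-oriented pre -> post (variation %) ==
                               mean_rte            prob_above                 rte_error           stability_pct             entropy_pct
Andoain             0.84 -> 0.79(-5.26)  0.83 -> 0.64(-22.03)   0.0023 -> 0.0032(40.01)  85.87 -> 77.07(-10.25)    27.15 -> 28.52(5.05)
Azpeitia             0.96 -> 0.98(1.41)    0.97 -> 0.99(1.72)   0.0042 -> 0.0040(-5.46)   70.20 -> 83.67(19.18)   12.37 -> 16.21(31.01)
Tolosa               0.97 -> 0.97(0.76)   0.98 -> 0.98(-0.27)  0.0018 -> 0.0013(-25.51)   90.93 -> 90.33(-0.66)     7.19 -> 7.96(10.66)
...
GLOBAL              0.87 -> 0.86(-0.79)   0.85 -> 0.83(-1.55)   0.0005 -> 0.0006(13.37)   89.86 -> 88.81(-1.17)    10.29 -> 11.25(9.25)
```

Each cell is `pre -> post(percent variation)`; variations are computed on
unrounded values. Here the reinforced area Azpeitia gains efficiency (mean
RTE 0.96 → 0.98) and stability (70 → 84%), while the global mean RTE of this
particular synthetic draw is essentially flat (0.87 → 0.86) — policies that
add resources can *lower* input-oriented efficiency elsewhere because DEA
measures resource use relative to peers. The output directory holds the
pre/post tables, fitted models (JSON), uncertainty distributions, raw
replicate scores, per-orientation reports, the comparison CSV and a
`manifest.json` from which the run is reproducible bit-for-bit.

The same fit, as printed by `mhecosim fit` on the seed-1 table:

```
professionals            exponential  alpha=   2.4460 beta=  0.0190 R2=0.9732 F= 399.70
frequentation            exponential  alpha=   4.8549 beta=  0.0236 R2=0.9627 F= 283.67
stay_composite           exponential  alpha= 436.8184 beta=  0.0198 R2=0.9509 F= 212.98
stay_availability        product_unit alpha=1367.2762 beta= -0.3592 R2=0.0763 F=   0.91
discharges_composite     product_unit alpha=   4.3324 beta=  0.6194 R2=0.9813 F= 576.70
discharges_availability  product_unit alpha=  89.7633 beta= -0.3183 R2=0.0445 F=   0.51
```

CLI subcommands: `generate`, `fit`, `simulate`, `compare`; common flags
`--seed`, `--replicates` (default 500), `--orientation {input,output,both}`,
`--scenarios FILE`, `--policy FILE`, `--out`, `--force`, `--verbose`.
Policies and scenarios are JSON/YAML, e.g.

```json
{"label": "my-policy",
 "interventions": [
   {"area_id": "Andoain", "variable": "psychiatrists", "delta": 1.0}]}
```

Generator parameters serialize the same way (`GeneratorParams.to_json`);
keys are the constructor fields (`n_areas`, `population_range`,
`noise_sigma`, structural `alpha_*`/`beta_*` coefficients, …).

See `docs/methods.md` for the model, its assumptions and all numerical
conventions.

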
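# cacoflux

Analysis toolkit for **bidirectional Caco-2 monolayer transport
assays** — the standard in-vitro model of intestinal drug absorption —
with a mechanistic simulator that makes every stage of the pipeline
verifiable against known ground truth.

It is written for people who run or analyze Transwell permeability
experiments: given receiver-compartment concentration time courses per
well, it computes the dilution-corrected cumulative transported amount,
apparent permeability coefficients, efflux ratios with mechanism
classification, monolayer-integrity TEER, bioanalytical calibration/QC
statistics, and inhibitor/co-administration effect contrasts.

## The quantities

With receiver concentrations Cₙ (μg·mL⁻¹) measured at the scheduled
times, receiver volume V_R, per-sample replaced volume V_S, membrane
area A and donor concentration C₀:

* corrected cumulative amount  ΔQₙ = Cₙ·V_R + V_S·Σ_{i<n} Cᵢ  (μg) —
  adds back the mass removed by earlier samples that were replaced
  with blank buffer;
* transport rate v (μg·s⁻¹): OLS slope of ΔQ versus time;
* apparent permeability  **Papp = v / (A·C₀)**  (cm·s⁻¹);
* efflux ratio  **ER = Papp(BL→AP) / Papp(AP→BL)**; ER > 1.5 flags
  likely transporter-mediated (P-gp/MRP2-type) efflux;
* TEER = (R₁ − R₀)·A (Ω·cm²) for monolayer integrity.

The simulator is a two-compartment ODE with passive diffusion plus a
saturable, apically directed Michaelis–Menten efflux term, exact
sample-and-replace events, and multiplicative lognormal measurement
noise — see `docs/methods.md` for the model and all defaults.

## Worked example

```python
from cacoflux import (DEFAULT_SCHEDULE, analyze_well, efflux_params,
                      simulate_condition, summarize_group)

params = efflux_params(noise_cv=0.05)          # efflux substrate, 5% noise
ds = simulate_condition(params, DEFAULT_SCHEDULE, c0_list=[100.0],
                        n_wells=6, seed=7)
g = summarize_group([analyze_well(w) for w in ds.wells], condition="drug-100")
print(f"Papp(AP->BL) {g.papp_ab_mean_e6:.3f}, Papp(BL->AP) {g.papp_ba_mean_e6:.3f}  "
      f"(x10^-6 cm/s)  ER {g.er:.3f}  {g.classification}")
```

prints

```
Papp(AP->BL) 1.001, Papp(BL->AP) 2.897  (x10^-6 cm/s)  ER 2.895  active-transport-likely
```

The secretory permeability is almost three times the absorptive one, so
the efflux ratio exceeds the 1.5 rule-of-thumb and the condition is
labelled as likely transporter-mediated — exactly the behaviour the
generating model (passive 2×10⁻⁶ cm·s⁻¹ plus saturable efflux) encodes.
Re-running with `efflux_params(inhibition=0.8)` collapses the ER to
about 1.25, the signature of co-incubation with a potent efflux
inhibitor. The `examples/` directory has one short script per
capability (bidirectional Papp, calibration/QC, inhibitor contrasts,
published-table checks), each printing the numbers it computes and a
line on what they mean.

## Command line

A thin CLI wraps the same library calls:

```sh
cacoflux simulate --seed 4 --out simdata          # wells.csv + truth.csv + manifest
cacoflux analyze --wells simdata/wells.csv --out report
cacoflux reproduce-tables
cacoflux qc --standards standards.csv --split-at 2.5
```

Exit codes: 0 success, 2 malformed input file, 3 invalid values.

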
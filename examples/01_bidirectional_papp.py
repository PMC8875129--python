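"""Simulate one bidirectional condition and compute Papp and the efflux ratio.

An efflux-substrate compound (passive permeability 2e-6 cm/s plus a
saturable apically directed transporter) is run at 100 ug/mL in both
directions with 6 replicate wells and 5% measurement noise, then pushed
through the full analysis: dilution-corrected cumulative amounts, rate
fits, Papp per well, and the group summary.
"""

from cacoflux import (
    DEFAULT_SCHEDULE,
    analyze_well,
    efflux_params,
    simulate_condition,
    summarize_group,
)

params = efflux_params(noise_cv=0.05)
ds = simulate_condition(params, DEFAULT_SCHEDULE, c0_list=[100.0],
                        n_wells=6, seed=7, compound="drug")
results = [analyze_well(w) for w in ds.wells]
g = summarize_group(results, condition="drug-100")

print(f"condition          : {g.condition} (n={g.n_ab}/direction)")
print(f"Papp(AP->BL)       : {g.papp_ab_mean_e6:.3f} +/- {g.papp_ab_sd * 1e6:.3f} x10^-6 cm/s")
print(f"Papp(BL->AP)       : {g.papp_ba_mean_e6:.3f} +/- {g.papp_ba_sd * 1e6:.3f} x10^-6 cm/s")
print(f"efflux ratio (ER)  : {g.er:.3f}")
print(f"mechanism          : {g.classification}")
print()
print("ER well above 1.5 means basolateral-to-apical transport outpaces")
print("absorption: the signature of transporter-mediated efflux. The")
print("absorptive Papp sits below the passive 2.0 because the transporter")
print("pumps part of the absorbed drug back out.")
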
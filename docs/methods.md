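# Methods

## The assay and what the package computes

A bidirectional monolayer transport experiment grows an epithelial cell
monolayer (typically Caco-2, a human intestinal model) on a permeable
Transwell insert separating an apical (AP) and a basolateral (BL)
chamber. Drug is dosed into one chamber (the donor) at concentration
C₀ and its appearance in the other (the receiver) is followed over
time. Two quantities summarize a condition:

* the apparent permeability coefficient
  **Papp = v / (A·C₀)** (cm·s⁻¹), where *v* (μg·s⁻¹) is the slope of the
  cumulative transported amount versus time and *A* (cm², default 1.12)
  is the membrane area;
* the efflux ratio **ER = Papp(BL→AP) / Papp(AP→BL)**. ER near 1 is
  consistent with passive diffusion; ER strictly above 1.5 (the
  conventional rule of thumb, configurable) suggests transporter-
  mediated efflux such as P-gp or MRP2.

Because each receiver sample (volume V_S, default 0.2 mL) is replaced
with blank buffer, later concentrations under-report the transported
mass. The corrected cumulative amount is

    ΔQₙ = Cₙ·V_R + V_S · Σ_{i=0}^{n−1} Cᵢ ,   C₀ ≡ 0,

i.e. current receiver content plus everything already withdrawn. This
is exact bookkeeping, not an approximation; a property test checks it
against an explicit event-by-event ledger to 1e−12 relative.

The transport rate is an ordinary least-squares slope of ΔQ versus time
with a free intercept (absorbing any lag phase), over a configurable
time window (default: all points; a sink-phase window such as ≤ 90 min
can be selected when high donor concentrations saturate transport late
in the run). Input times are minutes and are converted to seconds, so
Papp is reported on the conventional 10⁻⁶ cm·s⁻¹ scale.

Monolayer integrity is tracked as TEER = (R₁ − R₀)·A (Ω·cm²). The
300 Ω·cm² flag threshold is advisory only and configurable; negative
TEER (reference exceeding measurement) is flagged as monolayer failure
but never silently dropped.

Group summaries report mean ± SD Papp per direction (sample SD, n−1)
and the **ratio-of-means ER** as the primary statistic — this is the
quantity that reproduces published group-level ERs computed from mean
Papp values. When wells are paired across directions, the mean ± SD of
per-well ratios is reported alongside, since published ER ± SD entries
imply per-replicate ratios. A condition lacking the BL→AP arm gets a
missing ER (rendered as an em dash), never an imputed one.

## Effect analysis

Treatment effects (efflux inhibitors, co-administration) are quantified
as signed percent changes, (treated − baseline)/baseline × 100, on
Papp in each direction and on ER, plus a two-sample test on per-well
Papp values. Welch's t is the default (small transport groups rarely
have equal variances); Student's t is selectable. With both groups
degenerate and equal, p = 1 by convention. No multiplicity correction
is applied by default — a bidirectional study makes only a few
contrasts — but Holm adjustment is available.

## Calibration and QC

Wide-span HPLC quantitation uses two linear segments sharing a boundary
standard; the boundary is included in both segments (the natural
reading of a shared range edge). Fits are unweighted OLS by default —
the near-unity correlation coefficients such data show are consistent
with unweighted fits — with 1/x and 1/x² weighting available. The
LLOQ is the lowest standard of the low segment. Back-calculation uses
the segment whose inverse lands inside its own range (lower segment
wins on the boundary); signals mapping below zero are flagged
non-quantifiable, out-of-range signals are assigned to the nearest
segment and flagged extrapolated, and sub-LLOQ values are flagged but
returned, never censored. QC statistics follow standard bioanalytical
practice: intra-day RSD (mean of within-day SD/mean), inter-day RSD
(SD of daily means over their mean), relative recovery (grand mean /
nominal × 100); the RSD ≤ 10% and 85–115% recovery bands are
report-only.

## The simulator

The generator is a lumped two-compartment ODE. Net donor→receiver flux
density is

    J = P·(C_d − C_r) − s·(1 − inhibition)·V_max·C_d/(K_m + C_d),

with s = +1 for AP→BL (apically directed efflux opposes absorption) and
s = −1 for BL→AP (efflux adds to secretion). This is the simplest model
exhibiting both the directionality and the saturation that efflux
substrates show; an intracellular compartment is deliberately omitted
because the assay observes only donor and receiver, leaving a third
compartment unidentifiable. Sampling is an instantaneous event:
withdraw C_r·V_S, then restore the volume with blank buffer. Between
events the integrator (adaptive LSODA, rtol 1e−11) advances a single
state — the receiver mass — with the donor mass computed as
total-minus-receiver, so donor + receiver + withdrawn equals the
initial dose to machine precision by construction, not by integrator
tolerance. Non-finite states abort with a hard error.

Measurement noise is multiplicative lognormal with mean 1 and a given
CV, applied to the pre-withdrawal receiver concentration: HPLC error
scales with concentration, and the lognormal keeps concentrations
positive. Replicate wells share the (cached) noiseless trajectory and
differ only in independent noise streams spawned deterministically from
the master seed, so datasets are bit-reproducible.

### Default conditions

| parameter | default | rationale |
|---|---|---|
| area | 1.12 cm² | 12-well Transwell insert |
| vol_ap / vol_bl | 0.5 / 1.5 mL | 12-well convention; receiver volume is direction-dependent |
| schedule | 30–180 min every 30 min, V_S = 0.2 mL | 180-min runs with periodic replaced sampling |
| p_passive | 2×10⁻⁶ cm·s⁻¹ | mid-range of reported Papp magnitudes for moderately permeable compounds |
| K_m | 25 μg·mL⁻¹ | well below the 100–200 μg·mL⁻¹ donor range, so saturation is visible |
| V_max (efflux preset) | 1.25×10⁻⁴ μg·cm⁻²·s⁻¹ | gives ER ≈ 3 at C₀ = 100 μg·mL⁻¹ falling to ≈ 1.8 at 200 — the saturating, strongly directional pattern |
| noise_cv | 0.05 | typical HPLC replicate scatter |
| replicates | 6 per direction | common assay design; published SDs imply n ≥ 3 |

The sink-regime preset for parameter-recovery checks uses
p_passive = 1×10⁻⁶ cm·s⁻¹: over 180 min the donor-side driving force
decays ~3%, so the free-intercept OLS slope underestimates the true
permeability by ~1.6%, inside the 2% recovery band; faster compounds
or longer runs need a restricted fit window instead.

### What the simulator does and does not emulate

It reproduces the statistical and mechanistic structure the analysis
assumes: passive + saturable directional efflux, inhibitor attenuation,
sample-and-replace dilution, concentration-proportional noise, and
replicate variability. It does not emulate paracellular leak pathways,
intracellular accumulation or metabolism, transporter expression
variability between passages, TEER drift during a run, chromatographic
interference, or carryover. Tests passing on simulated data therefore
validate the *estimators and bookkeeping*, not the biology of any
particular compound; absolute published Papp values cannot be
regenerated because the underlying per-well time courses were never
published, and the reproduction layer instead checks the group-level
ratio and percent-change arithmetic against the printed means.

## Numerical and design choices

* Rounding: published-table checks compare the **unrounded**
  ratio-of-means against the printed ER within one unit in the third
  printed decimal. Double rounding would spuriously fail a row whose
  ratio sits near a half-ulp boundary (one row's ratio, 2.6535, rounds
  away from the printed 2.654); one row (ratio 3.5323 vs printed 3.531)
  genuinely differs — evidently computed upstream from unrounded
  per-well values — and is reported as a documented exception, never
  forced to match.
* Two published percent-decrease figures (76.11%, 38.22%) recompute to
  76.13% / 38.23% from the printed ERs; the reproduction table shows
  both numbers rather than asserting equality. One published statement
  attaches the 76% figure to a Papp that only fell 11.6%; the figure
  matches the ER drop and is treated as a misplaced referent, not
  reproduced as a Papp claim.
* ER classification uses strict inequality at the threshold (exactly
  1.5 is passive-consistent).
* Missing concentrations poison all later ΔQ values (the prefix sum is
  unknown from that point on) rather than being interpolated.
* CSV dialect: UTF-8, header row, "." decimal separator, em dash or
  empty field for missing; report writers round floats to 10 decimals
  so identical inputs give byte-identical outputs.

## Known limitations

* The Michaelis–Menten efflux term acts on the donor-side concentration
  in both directions — a deliberate simplification; real efflux acts on
  intracellular drug, which this two-compartment model does not track.
* The free-intercept OLS rate estimator is biased low once the receiver
  leaves the sink regime; the configurable window mitigates but does
  not remove this for highly permeable compounds.
* Per-well ER statistics require a pairing of wells across directions;
  the default in-order pairing is a convention, not biology.
* The statistical test applied to published-style contrasts is a
  package choice (Welch); the original group comparisons' exact test is
  not recoverable from the published summary statistics.
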
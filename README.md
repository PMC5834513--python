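# n15rates

¹⁵N tracer rate calculation and calibration for the marine nitrogen cycle:
nitrification (ammonium oxidation) and NH₄⁺/NO₃⁻ uptake from stable-isotope
incubation experiments, Michaelis–Menten substrate kinetics, and
water-column feature detection for stratified stations.

## Who it is for

Marine biogeochemists running ¹⁵N tracer incubations in oligotrophic water,
where ambient NH₄⁺ is a few tens of nmol L⁻¹ and even a 10–20 nmol L⁻¹
tracer spike is a substantial substrate enrichment that stimulates the
measured rate. The package computes the standard tracer rates, calibrates
them back to in-situ conditions, and quantifies how severe the bias would
have been without the calibration.

## The model

An incubation adds ¹⁵N-labelled substrate (atom fraction 0.98) to a sample
and measures the product pool (NOₓ for nitrification, PON for uptake) at
the start and end. With product concentrations C₀, Cₜ, product ¹⁵N atom
fractions n₀, nₜ, substrate labelling f¹⁵ and duration t:

- bulk rate at the spiked concentration: R_bulk = C₀ (nₜ − n₀) / (t f¹⁵)
- atom accumulation rates: R₁₅ = (Cₜ nₜ − C₀ n₀)/t, R₁₄ = R₁₅ (1 − n)/n
- in-situ calibration (first-order regime, total substrate ≪ Kₛ):
  R_in situ = (R₁₅ + R₁₄) · Ci/(Ci + Ct)

Substrate dependence is Michaelis–Menten, R(S) = V_max S/(Kₛ + S), fitted
by nonlinear least squares to multi-level tracer additions; the substrate
affinity α = V_max/Kₛ (the initial slope) ranks competitive ability at
limiting concentrations. Detection limits take 3σ of the ±0.2‰ δ¹⁵N
analytical accuracy (0.6‰) as the minimum reliable product enrichment.
Profile utilities locate the mixed layer (0.8 °C temperature offset),
nitracline (steepest NO₃⁻ gradient range and midpoint), euphotic depth
(0.1% surface PAR via an exponential attenuation fit), PNM/DCM, and the
depth where nitrification overtakes NH₄⁺ uptake.

## Worked example

```python
import numpy as np
from n15rates import (IncubationTruth, MichaelisMentenModel, mm_rate,
                      compare_estimators, simulate_incubation)

# a first-order nitrification incubation: 20 nmol/L ambient NH4+,
# 20 nmol/L tracer spike, Ks = 1000 nmol/L
truth = IncubationTruth(ks=1000.0, ambient_substrate_conc=20.0)
records, ground = simulate_incubation(truth, spike_conc=20.0,
                                      duration_h=12.0, replicates=1,
                                      noise=False, light="dark")

s = np.array([10., 100., 500., 2000.]) + 20.0
fit = MichaelisMentenModel(s, mm_rate(truth.vmax, truth.ks, s)).fit()
print(fit.summary())
comp = compare_estimators(records[0], fit)
print(f"bulk/true factor   {comp.overestimation_factor:.4f}")
print(f"in-situ rate       {comp.r_in_situ:.4f} nmol N/L/h")
print(f"true ambient rate  {ground.rate_ambient:.4f} nmol N/L/h")
```

prints

```
Michaelis-Menten kinetic fit
==============================================
n points                                     4
converged                                 True
...
bulk/true factor   1.9615
in-situ rate       0.4231 nmol N/L/h
true ambient rate  0.4314 nmol N/L/h
```

i.e. the uncalibrated bulk rate overestimates the true ambient rate by a
factor of ~1.96 (the closed form (Ci+Ct)(Kₛ+Ci)/[Ci(Kₛ+Ci+Ct)]), while the
linear in-situ calibration lands within 2% of the truth.

The command line mirrors the library:

```bash
n15rates simulate --seed 1 --out-dir demo/      # synthetic CSVs + truth
n15rates rates demo/incubations.csv demo/rates.csv
n15rates kinetics demo/kinetics.csv demo/fits.csv
n15rates profile demo/station.csv demo/features.csv
```

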